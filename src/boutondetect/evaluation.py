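"""Box-based evaluation of bouton detections.

Ground truth is a set of axis-aligned boxes (nominally 25 x 25 px)
around labelled boutons.  The matching protocol is point-in-box with one
true positive allowed per box:

* a detection whose (x, y) lies inside an unmatched box is a TP and
  claims that box; a second detection in the same box is an FP;
* a detection inside no box is an FP;
* a box containing no detection is an FN;
* true negatives are only defined under the pixel-population convention
  (``tn_mode="pixel"``): every frame pixel outside the 25 x 25 exclusion
  zones around TPs, FPs and FNs counts as one TN.  Because the frame
  dwarfs the handful of boutons, TN is enormous and ROC-style FPR values
  come out around 1e-5; precision/recall is the headline metric and
  ``tn_mode="none"`` (tn = 0) the default.

Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F1 = 2 * precision * recall / (precision + recall).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging_io import BoxSet

#: Side of the square exclusion zone used for pixel-population TNs.
EXCLUSION_SIDE = 25


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EvaluationReport:
    """Per-image counts and metrics with mean/std aggregates."""

    counts: list[MatchCounts] = field(default_factory=list)
    n_boutons: list[int] = field(default_factory=list)

    @property
    def per_image_metrics(self) -> list[tuple[float, float, float]]:
        return [metrics(c) for c in self.counts]

    def aggregate(self) -> dict[str, float]:
        """Column means and sample standard deviations."""
        m = np.array(self.per_image_metrics, dtype=float)
        if len(m) == 0:
            return {}
        out = {
            "mean_precision": float(m[:, 0].mean()),
            "mean_recall": float(m[:, 1].mean()),
            "mean_f1": float(m[:, 2].mean()),
        }
        if len(m) > 1:
            out.update(
                std_precision=float(m[:, 0].std(ddof=1)),
                std_recall=float(m[:, 1].std(ddof=1)),
                std_f1=float(m[:, 2].std(ddof=1)),
            )
        return out

    def write_csv(self, path: str | Path) -> None:
        """Per-image metrics table with Average/STD footer rows."""
        m = self.per_image_metrics
        agg = self.aggregate()
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image", "n_boutons", "precision", "recall", "f1"])
            for i, ((p, r, f), n) in enumerate(zip(m, self.n_boutons), start=1):
                w.writerow([i, n, f"{p:.4f}", f"{r:.4f}", f"{f:.4f}"])
            if agg:
                w.writerow(
                    ["Average", f"{np.mean(self.n_boutons):.2f}",
                     f"{agg['mean_precision']:.4f}", f"{agg['mean_recall']:.4f}",
                     f"{agg['mean_f1']:.4f}"]
                )
            if "std_f1" in agg:
                w.writerow(
                    ["STD", "", f"{agg['std_precision']:.4f}",
                     f"{agg['std_recall']:.4f}", f"{agg['std_f1']:.4f}"]
                )


def match_detections(
    points: list[tuple[int, int]],
    boxes: BoxSet,
    scores: list[float] | None = None,
    tn_mode: str = "none",
) -> MatchCounts:
    """Count TP/FP/FN (and optionally TN) under the point-in-box protocol.

    Points are visited in descending score order (ties by (row, col)) so
    the strongest detection in a box claims the TP; box membership is
    edge-inclusive.  ``tn_mode``: ``"none"`` leaves tn = 0, ``"pixel"``
    counts frame pixels outside all exclusion zones.
    """
    if tn_mode not in ("none", "pixel"):
        raise ValueError(f"unknown tn_mode {tn_mode!r}")
    rows, cols = boxes.frame_shape
    for r, c in points:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"point {(r, c)} outside frame {(rows, cols)}")
    if scores is None:
        scores = [0.0] * len(points)
    order = sorted(range(len(points)), key=lambda i: (-scores[i], points[i]))

    matched: set[int] = set()
    tp = fp = 0
    for i in order:
        r, c = points[i]
        hit = next(
            (b for b in boxes.contains(r, c) if b not in matched), None
        )
        if hit is None:
            fp += 1
        else:
            matched.add(hit)
            tp += 1
    fn = len(boxes) - tp

    tn = 0
    if tn_mode == "pixel":
        tn = _pixel_tn(points, boxes)
    return MatchCounts(tp, fp, fn, tn)


def _pixel_tn(points: list[tuple[int, int]], boxes: BoxSet) -> int:
    """Frame pixels outside the union of all exclusion zones."""
    excl = boxes.to_mask().astype(bool)
    rows, cols = boxes.frame_shape
    h = EXCLUSION_SIDE // 2
    for r, c in points:
        excl[max(0, r - h) : r + h + 1, max(0, c - h) : c + h + 1] = True
    return int(rows * cols - excl.sum())


def metrics(counts: MatchCounts) -> tuple[float, float, float]:
    """(precision, recall, f1) with the 0/0 -> 0 convention."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def threshold_sweep(
    scored_points: list[tuple[int, int, float]],
    boxes: BoxSet,
    n_thresholds: int = 1000,
) -> dict[str, np.ndarray | float]:
    """Re-match at evenly spaced score thresholds over [-1, 1].

    For each threshold only detections with score >= threshold are kept
    and the full matching re-runs.  Returns the threshold grid,
    precision/recall samples, FPR samples (pixel-population TNs), and
    the precision-recall AUC by the trapezoid rule over recall-ordered
    samples.
    """
    thresholds = np.linspace(-1.0, 1.0, n_thresholds)
    precision = np.zeros(n_thresholds)
    recall = np.zeros(n_thresholds)
    fpr = np.zeros(n_thresholds)
    for i, t in enumerate(thresholds):
        pts = [(r, c) for r, c, s in scored_points if s >= t]
        sc = [s for _, _, s in scored_points if s >= t]
        counts = match_detections(pts, boxes, sc, tn_mode="pixel")
        precision[i], recall[i], _ = metrics(counts)
        denom = counts.fp + counts.tn
        fpr[i] = counts.fp / denom if denom else 0.0
    order = np.argsort(recall, kind="stable")
    auc_pr = float(np.trapezoid(precision[order], recall[order]))
    auc_roc = float(np.trapezoid(recall[np.argsort(fpr, kind="stable")],
                                 np.sort(fpr)))
    return {
        "thresholds": thresholds,
        "precision": precision,
        "recall": recall,
        "fpr": fpr,
        "auc_pr": auc_pr,
        "auc_roc": auc_roc,
    }


def write_curve_csv(path: str | Path, sweep: dict) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["threshold", "precision", "recall", "fpr"])
        for t, p, r, f in zip(
            sweep["thresholds"], sweep["precision"], sweep["recall"], sweep["fpr"]
        ):
            w.writerow([f"{t:.6f}", f"{p:.6f}", f"{r:.6f}", f"{f:.6f}"])
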