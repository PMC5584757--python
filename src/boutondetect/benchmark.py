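"""Reference per-image benchmark scores for metric-arithmetic validation.

The table below holds per-image precision/recall/F1 of the tracing-free
bouton detector and of a tracing-based baseline tool on a 20-image
two-photon test set (345 boutons total).  It is used to validate the
evaluation module's arithmetic: column averages, standard deviations and
the recomputation of each row's F1 from its precision and recall.

All values are stored exactly as printed, at 2 decimal places.  Because
precision and recall were themselves rounded before printing, an F1
recomputed from a row can differ from the printed F1 by one unit in the
last digit (0.01); the validation helpers account for that.
"""

from __future__ import annotations

import numpy as np

from .evaluation import MatchCounts, metrics

#: Columns: image id, n boutons, detector (precision, recall, F1),
#: tracing-based baseline (precision, recall, F1).
REFERENCE_TABLE: list[tuple[int, int, float, float, float, float, float, float]] = [
    (1, 10, 0.71, 1.00, 0.83, 1.00, 0.20, 0.33),
    (2, 8, 1.00, 1.00, 1.00, 1.00, 0.25, 0.40),
    (3, 27, 0.73, 1.00, 0.84, 0.70, 0.26, 0.38),
    (4, 40, 0.85, 0.98, 0.91, 0.83, 0.13, 0.22),
    (5, 26, 0.74, 1.00, 0.85, 0.80, 0.77, 0.78),
    (6, 16, 0.56, 0.94, 0.70, 1.00, 0.75, 0.86),
    (7, 11, 0.91, 0.91, 0.91, 0.70, 0.64, 0.67),
    (8, 7, 1.00, 1.00, 1.00, 0.00, 0.00, 0.00),
    (9, 4, 0.67, 1.00, 0.80, 0.50, 0.25, 0.33),
    (10, 10, 0.91, 1.00, 0.95, 1.00, 0.20, 0.33),
    (11, 11, 0.92, 1.00, 0.96, 0.57, 0.36, 0.44),
    (12, 9, 0.78, 0.78, 0.78, 1.00, 0.22, 0.36),
    (13, 25, 0.78, 0.84, 0.81, 0.71, 0.20, 0.31),
    (14, 49, 0.66, 0.88, 0.75, 1.00, 0.08, 0.15),
    (15, 31, 0.88, 0.90, 0.89, 0.73, 0.35, 0.48),
    (16, 12, 0.71, 1.00, 0.83, 1.00, 0.50, 0.67),
    (17, 17, 0.45, 1.00, 0.62, 1.00, 0.47, 0.64),
    (18, 9, 0.53, 0.89, 0.67, 0.67, 0.22, 0.33),
    (19, 8, 0.89, 1.00, 0.94, 0.50, 0.13, 0.20),
    (20, 15, 0.64, 0.93, 0.76, 1.00, 0.13, 0.24),
]


def columns() -> dict[str, np.ndarray]:
    """Table columns as arrays keyed by name."""
    arr = np.array(REFERENCE_TABLE, dtype=float)
    return {
        "image": arr[:, 0],
        "n_boutons": arr[:, 1],
        "precision": arr[:, 2],
        "recall": arr[:, 3],
        "f1": arr[:, 4],
        "baseline_precision": arr[:, 5],
        "baseline_recall": arr[:, 6],
        "baseline_f1": arr[:, 7],
    }


def column_means() -> dict[str, float]:
    """Mean of every metric column (the table's Average row)."""
    cols = columns()
    return {
        name: float(cols[name].mean())
        for name in (
            "precision",
            "recall",
            "f1",
            "baseline_precision",
            "baseline_recall",
            "baseline_f1",
        )
    }


def recompute_f1_rows() -> list[tuple[float, float]]:
    """(recomputed F1, stored F1) per detector row.

    Recomputation routes each row's precision/recall through the
    evaluation module's harmonic-mean formula, using synthetic counts
    with the stated rates, so the metric code itself is exercised.
    """
    out = []
    for _, _, p, r, f1, *_ in REFERENCE_TABLE:
        # Counts realizing the printed rates to high precision.
        tp = 10_000_000
        fp = int(round(tp * (1 - p) / p)) if p > 0 else 0
        fn = int(round(tp * (1 - r) / r)) if r > 0 else 0
        p2, r2, f2 = metrics(MatchCounts(tp=tp, fp=fp, fn=fn))
        assert abs(p2 - p) < 1e-6 and abs(r2 - r) < 1e-6
        out.append((f2, f1))
    return out
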