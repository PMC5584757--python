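"""Candidate bouton detection: Hessian keypoints and non-maximum suppression.

Candidates are local maxima of the determinant of the Hessian across
position and scale (the fast-Hessian / SURF family of detectors),
computed on the LoG-enhanced projection.  The detector deliberately
over-fires; a two-window non-maximum suppression then (1) relocates each
candidate to the brightest pixel in its local W1 window and (2) greedily
removes all but the brightest candidate within a W2 neighbourhood, so a
single bouton yields a single candidate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix_det

from .imaging_io import Image2D


@dataclass(frozen=True)
class Keypoint:
    """A candidate bouton location.

    row, col are 0-based pixel coordinates, ``scale`` the detector scale
    estimate (pixels) and ``response`` the determinant-of-Hessian
    strength at the maximum.
    """

    row: int
    col: int
    scale: float
    response: float


@dataclass
class NmsConfig:
    """Two-window non-maximum suppression parameters.

    w1
        Full side, in pixels, of the square relocation window (the
        candidate moves to the brightest pixel within ±w1//2).
    w2
        Chebyshev suppression radius: of any two surviving candidates,
        the Chebyshev distance exceeds w2.
    """

    w1: int = 20
    w2: int = 10

    def __post_init__(self) -> None:
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("NMS window parameters must be positive")


def detect_interest_points(
    image: Image2D,
    threshold: float = 5e-4,
    n_octaves: int = 3,
    n_scales: int = 4,
    base_sigma: float = 2.0,
) -> list[Keypoint]:
    """Determinant-of-Hessian keypoints across a scale pyramid.

    The image is min-max normalized to [0, 1] so ``threshold`` is
    intensity-scale-free, then the box-filter (integral image)
    approximation of the Hessian determinant is evaluated at
    ``n_octaves * n_scales`` geometrically spaced scales.  Keypoints are
    3D local maxima of the response cube (position x scale) above
    ``threshold``, returned sorted by descending response.
    """
    pix = image.pixels
    if not np.all(np.isfinite(pix)):
        raise ValueError("image contains non-finite values")
    lo, hi = pix.min(), pix.max()
    if hi == lo:
        return []
    norm = (pix - lo) / (hi - lo)

    sigmas = [
        base_sigma * 2.0 ** (o + s / n_scales)
        for o in range(n_octaves)
        for s in range(n_scales)
    ]
    cube = np.stack([hessian_matrix_det(norm, sigma=s) for s in sigmas])

    local_max = ndimage.maximum_filter(cube, size=3, mode="nearest") == cube
    peaks = np.argwhere(local_max & (cube > threshold))
    points = [
        Keypoint(int(r), int(c), float(sigmas[k]), float(cube[k, r, c]))
        for k, r, c in peaks
    ]
    points.sort(key=lambda p: (-p.response, p.row, p.col))
    return points


def relocate_to_local_max(
    points: list[Keypoint], image: Image2D, cfg: NmsConfig | None = None
) -> list[Keypoint]:
    """Move each candidate to the brightest pixel in its W1 window.

    The window is the square of half-width ``w1 // 2`` centred on the
    point, clipped at the borders.  Ties go to the first maximum in
    row-major order.  The image value at the output never falls below
    the value at the input.
    """
    if cfg is None:
        cfg = NmsConfig()
    h = cfg.w1 // 2
    rows, cols = image.shape
    out = []
    for p in points:
        if not (0 <= p.row < rows and 0 <= p.col < cols):
            raise ValueError(f"point {(p.row, p.col)} outside image {image.shape}")
        r0, r1 = max(0, p.row - h), min(rows, p.row + h + 1)
        c0, c1 = max(0, p.col - h), min(cols, p.col + h + 1)
        window = image.pixels[r0:r1, c0:c1]
        flat = int(np.argmax(window))
        dr, dc = divmod(flat, window.shape[1])
        out.append(Keypoint(r0 + dr, c0 + dc, p.scale, p.response))
    return out


def suppress_duplicates(
    points: list[Keypoint], image: Image2D, cfg: NmsConfig | None = None
) -> list[Keypoint]:
    """Greedy suppression: keep the locally brightest candidate only.

    Candidates are visited in descending order of image intensity at
    their location (ties broken by (row, col)); each kept candidate
    removes every later candidate within Chebyshev distance w2.  All
    pairwise Chebyshev distances in the output exceed w2.
    """
    if cfg is None:
        cfg = NmsConfig()
    rows, cols = image.shape
    for p in points:
        if not (0 <= p.row < rows and 0 <= p.col < cols):
            raise ValueError(f"point {(p.row, p.col)} outside image {image.shape}")
    order = sorted(
        points, key=lambda p: (-image.pixels[p.row, p.col], p.row, p.col)
    )
    kept: list[Keypoint] = []
    for p in order:
        if all(
            max(abs(p.row - q.row), abs(p.col - q.col)) > cfg.w2 for q in kept
        ):
            kept.append(p)
    return kept


def write_keypoints_csv(path: str | Path, points: list[Keypoint]) -> None:
    """Dump candidates as ``x,y,scale,response`` (x = col, y = row)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "scale", "response"])
        for p in points:
            writer.writerow([p.col, p.row, p.scale, p.response])


def read_keypoints_csv(path: str | Path) -> list[Keypoint]:
    """Load an external candidate list (``x,y[,scale,response]``)."""
    points = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            points.append(
                Keypoint(
                    row=int(round(float(row["y"]))),
                    col=int(round(float(row["x"]))),
                    scale=float(row.get("scale", 0) or 0),
                    response=float(row.get("response", 0) or 0),
                )
            )
    return points
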