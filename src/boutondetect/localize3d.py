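"""Lift accepted 2D detections to a z-slice.

A bouton found on the mean projection is assigned the stack slice whose
N x N patch sum around the detection is largest: the slice where the
bouton is in focus carries the most fluorescence.  Crossing axons that
overlap in (x, y) at different depths yield multi-modal patch-sum
profiles; the profile is returned as a diagnostic so such cases can be
audited, but no disambiguation is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .imaging_io import ImageStack

DEFAULT_PATCH_SIDE = 25


@dataclass
class Detection3D:
    """A bouton detection with its depth coordinate (all 0-based)."""

    row: int
    col: int
    z: int
    score: float
    profile: np.ndarray | None = None


def locate_z(
    stack: ImageStack,
    point: tuple[int, int],
    patch_side: int = DEFAULT_PATCH_SIDE,
    normalize_by_area: bool = False,
) -> tuple[int, np.ndarray]:
    """z = argmax over slices of the N x N patch intensity sum.

    The window is clipped at frame borders and only in-frame voxels are
    summed (the literal patch-sum rule); ``normalize_by_area`` divides by
    the clipped window's pixel count instead, making border and interior
    points comparable.  Ties go to the smallest z.  Returns (z, profile).
    """
    if patch_side % 2 == 0:
        raise ValueError("patch side must be odd")
    if stack.depth < 1:
        raise ValueError("empty stack")
    row, col = point
    rows, cols = stack.frame_shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise ValueError(f"point {point} outside frame {(rows, cols)}")
    h = patch_side // 2
    r0, r1 = max(0, row - h), min(rows, row + h + 1)
    c0, c1 = max(0, col - h), min(cols, col + h + 1)
    profile = stack.voxels[:, r0:r1, c0:c1].sum(axis=(1, 2))
    if normalize_by_area:
        profile = profile / ((r1 - r0) * (c1 - c0))
    # np.argmax returns the first maximum, i.e. the smallest tied z.
    return int(np.argmax(profile)), profile


def localize_detections(
    stack: ImageStack,
    points: list[tuple[int, int]],
    scores: list[float] | None = None,
    patch_side: int = DEFAULT_PATCH_SIDE,
    keep_profiles: bool = False,
) -> list[Detection3D]:
    """Apply :func:`locate_z` to each accepted 2D detection."""
    if scores is None:
        scores = [0.0] * len(points)
    out = []
    for (row, col), score in zip(points, scores):
        z, profile = locate_z(stack, (row, col), patch_side)
        out.append(
            Detection3D(row, col, z, float(score), profile if keep_profiles else None)
        )
    return out


def write_detections_csv(path: str | Path, detections: list[Detection3D]) -> None:
    """Dump detections as ``x,y,z,score`` (x = col, y = row, 0-based)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "z", "score"])
        for d in detections:
            writer.writerow([d.col, d.row, d.z, f"{d.score:.6f}"])


def read_detections_csv(path: str | Path) -> list[Detection3D]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Detection3D(
                    row=int(round(float(row["y"]))),
                    col=int(round(float(row["x"]))),
                    z=int(round(float(row.get("z", 0) or 0))),
                    score=float(row.get("score", 0) or 0),
                )
            )
    return out
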