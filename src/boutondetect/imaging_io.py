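"""Reading and writing image stacks, projections, and ground-truth boxes.

The pipeline works on grayscale 3D two-photon stacks stored as multi-page
TIFF, indexed ``(z, row, col)``.  The 2D stages operate on the mean
intensity projection of the stack.  Ground truth comes either as a binary
mask image in which each labelled bouton is a filled box, or as a plain
CSV listing box corners.

Coordinate convention: 0-based ``(row, col)`` everywhere in memory; public
CSV outputs report ``x = col``, ``y = row``, ``z = slice``, all 0-based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

#: Default physical voxel size (x, y, z) in micrometres for two-photon
#: stacks when the file carries no resolution metadata.
DEFAULT_VOXEL_SIZE = (0.147, 0.147, 1.0)


@dataclass
class ImageStack:
    """A 3D grayscale image stack.

    Parameters
    ----------
    voxels
        3D float array indexed ``(z, row, col)``, non-negative.
    voxel_size
        Physical size of a voxel ``(x, y, z)`` in micrometres.
    bit_depth
        Sample depth of the source file (bits), for provenance.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3D (z, row, col), got shape {self.voxels.shape}")
        if min(self.voxels.shape) < 1:
            raise ValueError("stack must have positive extent on every axis")
        if np.any(self.voxels < 0):
            raise ValueError("stack intensities must be non-negative")

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]


@dataclass
class Image2D:
    """A 2D real-valued image indexed ``(row, col)``."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BoxSet:
    """Axis-aligned ground-truth boxes on a fixed frame.

    Each box is ``(row_min, col_min, row_max, col_max)`` with 0-based,
    inclusive corners.
    """

    boxes: list[tuple[int, int, int, int]] = field(default_factory=list)
    frame_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        rows, cols = self.frame_shape
        for b in self.boxes:
            r0, c0, r1, c1 = b
            if not (0 <= r0 <= r1 < rows and 0 <= c0 <= c1 < cols):
                raise ValueError(f"box {b} outside frame {self.frame_shape}")

    def __len__(self) -> int:
        return len(self.boxes)

    def contains(self, row: float, col: float) -> list[int]:
        """Indices of boxes containing the point, edges inclusive."""
        return [
            i
            for i, (r0, c0, r1, c1) in enumerate(self.boxes)
            if r0 <= row <= r1 and c0 <= col <= c1
        ]

    def to_mask(self) -> np.ndarray:
        """Rasterize boxes to a binary uint8 mask of ``frame_shape``."""
        mask = np.zeros(self.frame_shape, dtype=np.uint8)
        for r0, c0, r1, c1 in self.boxes:
            mask[r0 : r1 + 1, c0 : c1 + 1] = 1
        return mask


class UnsupportedFormatError(ValueError):
    """Raised for files whose layout the reader does not handle."""


def read_stack(path: str | Path) -> ImageStack:
    """Read a single-channel multi-page TIFF into an :class:`ImageStack`.

    Intensities are promoted to float64 without rescaling so the raw data
    stay auditable; normalization happens explicitly downstream.  If the
    file carries no resolution metadata the two-photon defaults
    (0.147, 0.147, 1.0) µm are used.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        bit_depth = int(tif.pages[0].bitspersample)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise UnsupportedFormatError(
            f"expected a single-channel stack, got array of shape {arr.shape}"
        )
    # A trailing small axis means interleaved channels (RGB etc.).
    if arr.shape[-1] in (2, 3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise UnsupportedFormatError(
            f"multi-channel image with {arr.shape[-1]} channels is not supported"
        )
    return ImageStack(arr.astype(np.float64), DEFAULT_VOXEL_SIZE, bit_depth)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as a multi-page grayscale TIFF (float32 samples)."""
    tifffile.imwrite(Path(path), stack.voxels.astype(np.float32))


def mean_projection(stack: ImageStack) -> Image2D:
    """Arithmetic mean over z at every (row, col) — the 2D pipeline input."""
    return Image2D(stack.voxels.mean(axis=0))


def max_projection(stack: ImageStack) -> Image2D:
    """Maximum over z; exploratory alternative, never the pipeline default."""
    return Image2D(stack.voxels.max(axis=0))


def read_groundtruth(path: str | Path, frame_shape: tuple[int, int]) -> BoxSet:
    """Read ground-truth boxes from a binary mask TIFF or a box-list CSV.

    Mask form: every 8-connected component of positive pixels becomes one
    box, its bounding rectangle.  CSV form: header
    ``x_min,y_min,x_max,y_max``, one box per line (x = col, y = row).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_box_csv(path, frame_shape)
    mask = tifffile.imread(path)
    if mask.ndim != 2 or mask.shape != tuple(frame_shape):
        raise UnsupportedFormatError(
            f"mask shape {mask.shape} does not match frame {frame_shape}"
        )
    values = np.unique(mask)
    if len(values) > 2:
        raise UnsupportedFormatError(
            f"ground-truth mask must be binary, found {len(values)} distinct values"
        )
    labels, n = ndimage.label(mask > 0, structure=np.ones((3, 3), dtype=int))
    boxes = []
    for sl in ndimage.find_objects(labels):
        boxes.append((sl[0].start, sl[1].start, sl[0].stop - 1, sl[1].stop - 1))
    return BoxSet(boxes, tuple(frame_shape))


def _read_box_csv(path: Path, frame_shape: tuple[int, int]) -> BoxSet:
    boxes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"x_min", "y_min", "x_max", "y_max"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise UnsupportedFormatError(
                f"box CSV needs header {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            boxes.append(
                (
                    int(row["y_min"]),
                    int(row["x_min"]),
                    int(row["y_max"]),
                    int(row["x_max"]),
                )
            )
    return BoxSet(boxes, tuple(frame_shape))


def write_groundtruth_csv(path: str | Path, boxes: BoxSet) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_min", "y_min", "x_max", "y_max"])
        for r0, c0, r1, c1 in boxes.boxes:
            writer.writerow([c0, r0, c1, r1])


def write_groundtruth_mask(path: str | Path, boxes: BoxSet) -> None:
    tifffile.imwrite(Path(path), boxes.to_mask() * np.uint8(255))
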