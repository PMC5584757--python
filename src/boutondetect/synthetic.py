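"""Synthetic two-photon stacks with known bouton ground truth.

The generator emulates the appearance of in-vivo two-photon axon imaging
at 0.147 µm/px: bright curvilinear axons (smooth random splines rendered
as Gaussian tubes spread over 2–4 adjacent z-slices), boutons as 2D
Gaussian varicosities (sd 4 px by default) riding on the axons, apparent
low-intensity gaps along axons (smooth intensity modulation), axon
crossings, detached blob-like distractors, and background plus
read/shot noise.  Every bouton gets a 25 x 25 ground-truth box and a
z-slice label, so every pipeline stage and the end-to-end system can be
trained and scored without any external data.

All randomness flows from the single integer seed in
:class:`SceneParams`; no global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .imaging_io import BoxSet, ImageStack

#: Side of the ground-truth box drawn around each bouton centre.
GT_BOX_SIDE = 25


@dataclass
class SceneParams:
    """Study conditions for one synthetic scene.

    Defaults mirror the imaging conditions the pipeline targets:
    512 x 512 frames, 20 slices, ~15 boutons per stack (3 axons x 5),
    bouton sd 4 px, bouton peak 3x the local axon intensity, low read
    noise (1% of axon intensity), and a handful of detached blob
    distractors.
    """

    frame: tuple[int, int, int] = (512, 512, 20)  # rows, cols, depth
    n_axons: int = 3
    axon_intensity: float = 100.0
    axon_sd: float = 1.5
    n_boutons_per_axon: int = 5
    bouton_amplitude_ratio: float = 3.0
    bouton_sd: float = 4.0
    min_spacing: float = 30.0
    background: float = 10.0
    read_noise_sd: float = 1.0
    shot_noise: bool = False
    photon_budget: float = 50.0
    n_distractors: int = 5
    gap_modulation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols, depth = self.frame
        if rows < 64 or cols < 64 or depth < 3:
            raise ValueError("frame must be at least 64 x 64 x 3")
        if self.min_spacing <= 0:
            raise ValueError("min_spacing must be positive")
        if self.bouton_amplitude_ratio <= 1:
            raise ValueError("bouton amplitude ratio must exceed 1")


@dataclass
class Scene:
    """A generated scene with full ground truth and layout diagnostics."""

    stack: ImageStack
    boxes: BoxSet
    boutons: list[tuple[int, int, int]]  # (row, col, z)
    axon_points: np.ndarray  # (M, 2) sampled arc pixels (row, col)
    axon_gains: np.ndarray  # (M,) local tube gain at each arc pixel
    distractors: list[tuple[int, int, int]]
    crossings: list[tuple[int, int]]


class GenerationError(RuntimeError):
    """Raised when the requested layout cannot be placed."""


def _spline_axon(
    rng: np.random.Generator, rows: int, cols: int
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth random curve across the frame, densely sampled.

    Returns (points (M, 2) float, gains (M,)): arc samples at ~0.5 px
    steps and the smooth gap-modulation gain along the arc.
    """
    n_way = 6
    # Endpoints on opposite border bands so the axon spans the frame.
    horizontal = rng.random() < 0.5
    t_way = np.linspace(0.0, 1.0, n_way)
    if horizontal:
        xs = np.linspace(2, cols - 3, n_way) + rng.normal(0, 4, n_way)
        ys = rng.uniform(0.15 * rows, 0.85 * rows, n_way)
    else:
        ys = np.linspace(2, rows - 3, n_way) + rng.normal(0, 4, n_way)
        xs = rng.uniform(0.15 * cols, 0.85 * cols, n_way)
    cs_r = CubicSpline(t_way, ys)
    cs_c = CubicSpline(t_way, xs)
    n_dense = int(4 * max(rows, cols))
    t = np.linspace(0.0, 1.0, n_dense)
    pts = np.stack([cs_r(t), cs_c(t)], axis=1)
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= rows - 1)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= cols - 1)
    )
    pts = pts[inside]
    # Smooth per-arc gain emulating apparent low-intensity gaps.
    g_way = rng.uniform(0.0, 1.0, n_way)
    gain = 0.3 + 0.7 * np.clip(CubicSpline(t_way, g_way)(t[inside]), 0.0, 1.0)
    return pts, gain


def _rasterize_tube(
    pts: np.ndarray, gain: np.ndarray, shape: tuple[int, int], sd: float
) -> np.ndarray:
    """Render arc samples as a Gaussian tube with unit peak intensity."""
    canvas = np.zeros(shape)
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, shape[1] - 1)
    np.maximum.at(canvas, (rr, cc), gain)
    tube = ndimage.gaussian_filter(canvas, sd)
    # Peak of a 1-px-wide unit ridge after Gaussian blur.
    ridge_peak = math.erf(0.5 / (math.sqrt(2.0) * sd))
    return tube / ridge_peak


def _gaussian_blob(
    shape: tuple[int, int], centre: tuple[float, float], sd: float, amplitude: float
) -> np.ndarray:
    r0, c0 = centre
    h = int(math.ceil(4 * sd))
    rows, cols = shape
    r_lo, r_hi = max(0, int(r0) - h), min(rows, int(r0) + h + 1)
    c_lo, c_hi = max(0, int(c0) - h), min(cols, int(c0) + h + 1)
    out = np.zeros(shape)
    y, x = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    out[r_lo:r_hi, c_lo:c_hi] = amplitude * np.exp(
        -((y - r0) ** 2 + (x - c0) ** 2) / (2 * sd * sd)
    )
    return out


def _z_weights(rng: np.random.Generator, depth: int) -> tuple[int, np.ndarray, np.ndarray]:
    """Unimodal weights over 2-4 adjacent slices; returns (zc, slices, weights)."""
    n_spread = int(rng.integers(2, 5))
    templates = {
        2: (np.array([0, 1]), np.array([2.0, 1.0])),
        3: (np.array([-1, 0, 1]), np.array([1.0, 2.0, 1.0])),
        4: (np.array([-1, 0, 1, 2]), np.array([1.0, 3.0, 2.0, 1.0])),
    }
    offsets, w = templates[n_spread]
    zc = int(rng.integers(max(1, -offsets.min()), depth - max(1, offsets.max())))
    slices = zc + offsets
    keep = (slices >= 0) & (slices < depth)
    w = w[keep] / w[keep].sum()
    return zc, slices[keep], w


def _place_boutons(
    rng: np.random.Generator,
    arcs: list[tuple[np.ndarray, np.ndarray]],
    params: SceneParams,
) -> list[tuple[int, float, float, float]]:
    """Pick bouton arc positions with a global 2D minimum spacing.

    Returns (axon index, row, col, gain) per bouton.  Centres stay at
    least half a ground-truth box from the frame border so boxes are
    full-sized.
    """
    rows, cols, _ = params.frame
    margin = GT_BOX_SIDE // 2
    placed: list[tuple[int, float, float, float]] = []
    for ai, (pts, gain) in enumerate(arcs):
        ok = (
            (pts[:, 0] >= margin) & (pts[:, 0] < rows - margin)
            & (pts[:, 1] >= margin) & (pts[:, 1] < cols - margin)
        )
        candidates = np.flatnonzero(ok)
        if len(candidates) == 0:
            raise GenerationError(f"axon {ai} has no interior arc to host boutons")
        accepted = 0
        for idx in rng.permutation(candidates):
            r, c = pts[idx]
            if all(
                (r - pr) ** 2 + (c - pc) ** 2 >= params.min_spacing**2
                for _, pr, pc, _ in placed
            ):
                placed.append((ai, float(r), float(c), float(gain[idx])))
                accepted += 1
                if accepted == params.n_boutons_per_axon:
                    break
        if accepted < params.n_boutons_per_axon:
            raise GenerationError(
                f"could not place {params.n_boutons_per_axon} boutons on axon {ai} "
                f"at spacing {params.min_spacing}; reduce count or spacing"
            )
    return placed


def build_scene(params: SceneParams) -> Scene:
    """Generate one scene: stack, ground truth, and layout diagnostics."""
    rng = np.random.default_rng(params.seed)
    rows, cols, depth = params.frame

    arcs = [_spline_axon(rng, rows, cols) for _ in range(params.n_axons)]
    placed = _place_boutons(rng, arcs, params)

    stack = np.zeros((depth, rows, cols))
    axon_z: list[tuple[int, np.ndarray, np.ndarray]] = []
    for pts, gain in arcs:
        tube = _rasterize_tube(pts, gain, (rows, cols), params.axon_sd)
        zc, slices, w = _z_weights(rng, depth)
        axon_z.append((zc, slices, w))
        for s, wk in zip(slices, w):
            stack[s] += params.axon_intensity * wk * tube

    boutons: list[tuple[int, int, int]] = []
    for ai, r, c, g in placed:
        zc, slices, w = axon_z[ai]
        # The blob rides on the axon tube, so the added amplitude is
        # (ratio - 1) x local axon intensity: the observed peak is then
        # ratio x the local shaft intensity.
        amp = (params.bouton_amplitude_ratio - 1) * params.axon_intensity * g
        blob = _gaussian_blob((rows, cols), (r, c), params.bouton_sd, amp)
        for s, wk in zip(slices, w):
            stack[s] += wk * blob
        boutons.append((int(round(r)), int(round(c)), zc))

    # Detached blob-like distractors, away from axons and boutons.
    all_arc = np.vstack([pts for pts, _ in arcs])
    distractors: list[tuple[int, int, int]] = []
    attempts = 0
    while len(distractors) < params.n_distractors and attempts < 2000:
        attempts += 1
        r = rng.uniform(GT_BOX_SIDE, rows - GT_BOX_SIDE)
        c = rng.uniform(GT_BOX_SIDE, cols - GT_BOX_SIDE)
        d_arc = np.min((all_arc[:, 0] - r) ** 2 + (all_arc[:, 1] - c) ** 2)
        d_btn = min(
            ((br - r) ** 2 + (bc - c) ** 2 for br, bc, _ in boutons), default=np.inf
        )
        if d_arc < (4 * params.bouton_sd) ** 2 or d_btn < params.min_spacing**2:
            continue
        amp = params.bouton_amplitude_ratio * params.axon_intensity * rng.uniform(0.6, 1.0)
        blob = _gaussian_blob((rows, cols), (r, c), params.bouton_sd, amp)
        zc, slices, w = _z_weights(rng, depth)
        for s, wk in zip(slices, w):
            stack[s] += wk * blob
        distractors.append((int(round(r)), int(round(c)), zc))

    image = stack + params.background
    if params.shot_noise:
        scale = params.axon_intensity / params.photon_budget
        image = rng.poisson(image / scale).astype(np.float64) * scale
    if params.read_noise_sd > 0:
        image = image + rng.normal(0.0, params.read_noise_sd, image.shape)
    image = np.clip(image, 0.0, None)

    h = GT_BOX_SIDE // 2
    boxes = BoxSet(
        [
            (
                max(0, r - h),
                max(0, c - h),
                min(rows - 1, r + h),
                min(cols - 1, c + h),
            )
            for r, c, _ in boutons
        ],
        (rows, cols),
    )
    crossings = _axon_crossings(arcs, (rows, cols))
    return Scene(
        stack=ImageStack(image),
        boxes=boxes,
        boutons=boutons,
        axon_points=all_arc,
        axon_gains=np.concatenate([g for _, g in arcs]),
        distractors=distractors,
        crossings=crossings,
    )


def _enhanced_projection(proj: np.ndarray) -> np.ndarray:
    """LoG-enhanced projection used to rank shaft hard negatives."""
    from .enhancement import EnhancementConfig, enhance
    from .imaging_io import Image2D

    return enhance(Image2D(proj), EnhancementConfig()).pixels


def _axon_crossings(
    arcs: list[tuple[np.ndarray, np.ndarray]], shape: tuple[int, int]
) -> list[tuple[int, int]]:
    """Pixels where two different axons pass within 1 px of each other."""
    pixel_sets = []
    for pts, _ in arcs:
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, shape[1] - 1)
        s = set()
        for r, c in zip(rr, cc):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    s.add((r + dr, c + dc))
        pixel_sets.append(s)
    hits: set[tuple[int, int]] = set()
    for i in range(len(pixel_sets)):
        for j in range(i + 1, len(pixel_sets)):
            hits |= pixel_sets[i] & pixel_sets[j]
    return sorted(
        (r, c) for r, c in hits if 0 <= r < shape[0] and 0 <= c < shape[1]
    )


def generate_stack(
    params: SceneParams,
) -> tuple[ImageStack, BoxSet, list[tuple[int, int, int]]]:
    """Stack, ground-truth boxes, and bouton centres for one scene."""
    scene = build_scene(params)
    return scene.stack, scene.boxes, scene.boutons


#: Reduced layout used for patch harvesting: many small scenes are
#: cheaper than few large ones, and a 25 x 25 crop never sees the frame.
#: Depth is inherited from the caller's params so the projection
#: contrast of training patches matches the deployment stacks.
_PATCH_SCENE_OVERRIDES = dict(
    frame_xy=(160, 160), n_axons=2, n_boutons_per_axon=4, n_distractors=3
)


def generate_patches(
    params: SceneParams, n_per_class: int
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labelled 25 x 25 training patches from synthetic scenes.

    Positives are crops of the mean projection centred on boutons.
    Negatives are centred on axon shaft points, axon crossings, or
    distractor blobs — never blank background, so the classifier learns
    to reject exactly the structures that fool the detector.  Shaft
    negatives are drawn preferentially from arc points where the
    LoG-enhanced projection is locally brightest: those gap-modulation
    bumps are exactly where the interest-point detector fires spurious
    candidates, so sampling them as negatives matches the candidate
    distribution the classifier sees at deployment.  Scenes are
    generated (small frames, same appearance parameters) until both
    classes are filled.  Deterministic given ``params.seed``.

    Returns ``(patches, labels)`` with patches of shape
    ``(2 * n_per_class, 25, 25)`` and labels 1 = bouton, 0 = non-bouton.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(params.seed)
    half = GT_BOX_SIDE // 2
    pos: list[np.ndarray] = []
    neg: list[np.ndarray] = []
    scene_idx = 0
    while (len(pos) < n_per_class or len(neg) < n_per_class) and scene_idx < 500:
        ov = dict(_PATCH_SCENE_OVERRIDES)
        fr, fc = ov.pop("frame_xy")
        sp = replace(
            params,
            frame=(fr, fc, params.frame[2]),
            **ov,
            min_spacing=min(params.min_spacing, 28.0),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scene_idx += 1
        try:
            scene = build_scene(sp)
        except GenerationError:
            continue  # unlucky spline layout; try the next scene seed
        proj = scene.stack.voxels.mean(axis=0)
        rows, cols = proj.shape
        enhanced = _enhanced_projection(proj)

        def crop(r: int, c: int) -> np.ndarray | None:
            r, c = int(round(r)), int(round(c))
            if half <= r < rows - half and half <= c < cols - half:
                return proj[r - half : r + half + 1, c - half : c + half + 1].copy()
            return None

        for r, c, _ in scene.boutons:
            if len(pos) < n_per_class and (p := crop(r, c)) is not None:
                pos.append(p)

        neg_centres: list[tuple[float, float]] = []
        # Axon shaft points well away from every bouton; mostly at the
        # locally brightest (enhanced) arc pixels, plus random ones.
        arc = scene.axon_points
        far = np.ones(len(arc), dtype=bool)
        for br, bc, _ in scene.boutons:
            far &= (arc[:, 0] - br) ** 2 + (arc[:, 1] - bc) ** 2 > (2 * half) ** 2
        shaft = arc[far]
        if len(shaft) > 0:
            vals = enhanced[
                np.clip(np.round(shaft[:, 0]).astype(int), 0, rows - 1),
                np.clip(np.round(shaft[:, 1]).astype(int), 0, cols - 1),
            ]
            bright = shaft[np.argsort(vals)[-max(1, len(shaft) // 5):]]
            for idx in rng.choice(len(bright), min(4, len(bright)), replace=False):
                neg_centres.append((bright[idx, 0], bright[idx, 1]))
            for idx in rng.choice(len(shaft), min(2, len(shaft)), replace=False):
                neg_centres.append((shaft[idx, 0], shaft[idx, 1]))
        for r, c, _ in scene.distractors:
            neg_centres.append((r, c))
        if scene.crossings:
            cr = scene.crossings[int(rng.integers(0, len(scene.crossings)))]
            neg_centres.append(cr)
        for r, c in neg_centres:
            if len(neg) < n_per_class and (p := crop(r, c)) is not None:
                neg.append(p)
    if len(pos) < n_per_class or len(neg) < n_per_class:
        raise GenerationError("could not harvest enough patches; relax params")
    patches = np.stack(pos[:n_per_class] + neg[:n_per_class])
    labels = np.concatenate(
        [np.ones(n_per_class, dtype=int), np.zeros(n_per_class, dtype=int)]
    )
    return patches, labels
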