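# Methods

## Model and assumptions

The detector assumes boutons are approximately isotropic Gaussian-shaped
intensity blobs (sd ≈ 4 px at 0.147 µm/px sampling) that are locally
brighter than the axon shaft they sit on, and that a 2D mean-intensity
projection of the stack preserves enough contrast to find them. Axons are
assumed thin (cross-section ≈ 1–2 px sd) and curvilinear; structures that
violate these assumptions — boutons at very different magnifications,
axons crossing in depth at the same (x, y) — are known failure modes
(see Limitations).

## Stage-by-stage conventions

**Coordinates.** 0-based `(row, col)` in memory everywhere; CSV outputs
use `x = col`, `y = row`, `z = slice`, all 0-based.

**Enhancement.** The LoG kernel follows the 1/(2πσ⁵) amplitude
convention, giving centre value −1/(πσ³). Support half-width defaults to
⌈3σ⌉ (σ = 4 → 25 × 25 kernel, matching the descriptor patch). The
discrete truncation does not sum to zero, so a zero-mean correction is
applied by default: flat background then maps exactly to 0, stabilising
the detector threshold. Borders are mirror-padded. When responses are
compared *across* scales (scale-selectivity checks), they are multiplied
by σ: with this kernel's extra 1/σ relative to the scale-normalized
Laplacian, the σ-weighted centre response to a disc of radius r peaks at
σ = r/√2, which is the matching rule `optimal_sigma_for_radius` encodes.
Raw (unweighted) responses peak at a smaller σ; a single-σ run is
unaffected by this distinction.

**Interest points.** Dense determinant-of-Hessian scale space using the
box-filter (integral image) approximation, 3 octaves × 4 scales from
base σ 2.0. The image is min–max normalized first so the response
threshold (default 5 × 10⁻⁴) is intensity-scale-free. The default was
calibrated once on synthetic validation scenes so the detector admits
roughly 3–10× more candidates than true boutons — deliberate over-firing,
since the classifier is the precision stage and a candidate lost here is
unrecoverable.

**NMS.** W₁ = 20 is the full side of the relocation window (±10, clipped
at borders); W₂ = 10 is a Chebyshev suppression radius. Suppression is
greedy in descending image intensity with (row, col) lexicographic
tie-breaks, so the output is deterministic and pairwise Chebyshev
distances exceed W₂. Intensity lookups use the enhanced image by default
(`enhancement.nms_intensity_source` switches to the raw projection).

**Descriptor.** Patch side from `I = 2·round(3σ) + 1` (banker's
rounding), 25 at σ = 4. Patches are cropped from the raw projection
(`pipeline.patch_source` switches to the enhanced image) with mirror
padding at borders and min–max normalized to [0, 1] per patch — the
descriptor then encodes shape, not brightness, which makes it robust to
the several-fold intensity variation along real axons. The 12 angles
nπ/6 are kept verbatim although even-symmetric filters repeat with
period π; the 6-fold redundancy is accepted so the descriptor length is
exactly 12. The carrier has zero phase at the patch centre and the
envelope stays axis-aligned; only the carrier rotates.

**Gabor frequency.** The carrier frequency is the descriptor's main free
parameter. The default is w = 1/(4σₓ) = 0.0625 cycles/px: the first
cosine zero-crossing then falls near the 2σ edge of a bouton-sized blob,
so a centred blob projects onto the positive main lobe at every
orientation while elongated structure modulates strongly with θ. On
synthetic validation patches this choice roughly halves classification
error relative to a 1/(2σₓ) carrier (cross-validated accuracy 0.96 vs
0.88), and it is exposed as `gabor.frequency` for retuning at other
magnifications.

**Classifier.** `sklearn.svm.SVC` with the inhomogeneous polynomial
kernel (u·v + 1)³ (degree 3, coef0 = 1, C = 1 default; `grid_search`
re-derives degree/C per dataset with ties broken toward simpler models).
Training balances classes by down-sampling and splits 80/20
(the 720/180 partition of a 900-patch set). Raw decision values on the
training partition define the affine [−1, 1] score scaling, persisted
with the model.

**Operating threshold.** −0.0399 on the scaled score is the historical
default. Because min–max scaling is anchored to the extreme training
scores, the raw decision boundary lands wherever the training score
spread puts it (with this descriptor the negative tail is long and the
boundary sits near scaled +0.9), so a fixed scaled threshold does not
transfer between datasets. `train(..., calibrate_threshold=True)` —
the default path of `train_from_synthetic` — re-derives the F1-optimal
threshold on the validation partition over a 1000-point grid, mirroring
how the original operating point was chosen on validation ROC data.

**z-localization.** Per slice, the 25 × 25 patch sum around the
detection, clipped to the frame (raw sum by default; an area-normalized
option exists for border points). Ties go to the smallest z. The full
per-slice profile is available as a diagnostic for multi-modal cases.

**Evaluation.** Point-in-box with one TP per box; points are matched in
descending score order, box membership is edge-inclusive, and
TP + FN = number of boxes always. True negatives are undefined for a
point process, so `tn_mode="none"` (tn = 0, PR metrics) is the default;
`tn_mode="pixel"` counts frame pixels outside the union of 25 × 25
exclusion zones around TPs/FPs/FNs, reproducing the pixel-population
FPR convention under which ROC AUCs come out of order 10⁻⁵ on a
512 × 512 frame. Aggregates report the mean and sample standard
deviation over images.

## Synthetic scenes

The generator emulates in-vivo two-photon axon imaging: default frame
512 × 512 × 20 (depth within the 15–50 slice range typical of such
stacks), 3 axons × 5 boutons at ≥ 30 px spacing, axon intensity 100 on
background 10, bouton sd 4 px with observed peak 3× the local shaft
intensity, read noise 1% of axon intensity, 5 detached distractor blobs.
Axons are cubic splines through random waypoints rendered as Gaussian
tubes (sd 1.5 px) spread over 2–4 adjacent slices with unimodal weights;
apparent low-intensity gaps come from a smooth per-arc gain in
[0.3, 1]; shot noise (optional) is Poisson resampling at a configurable
photon budget. All randomness flows from one integer seed.

Training patches are harvested from many small scenes (160 × 160, same
depth and appearance parameters as the deployment frame — depth matters
because projection contrast scales with slice count). Negatives are
centred on axon shaft points, crossings, and distractors, never blank
background; shaft negatives are drawn preferentially from arc points
where the enhanced projection is locally brightest, because those
gap-modulation bumps are exactly where the detector fires spurious
candidates — sampling them aligns the training negatives with the
deployment candidate distribution.

What the generator does **not** model: a realistic PSF (axial spread is
only coarsely emulated by the 2–4-slice tube weights; a real
0.45 × 0.45 × 2.5 µm FWHM PSF couples neighbouring structures more),
mixed Poisson–Gaussian detector statistics with gain, motion artefacts,
photobleaching, and densely packed neuropil. Passing synthetic tests
therefore demonstrates the pipeline's mechanics and its noise behaviour,
not field performance on real tissue; on real data the classifier should
be retrained on labelled patches and the detector threshold revisited.

## Problem sizes used in tests and the acceptance script

The end-to-end benchmark uses 20 stacks of 512 × 512 × 20 with ~15
boutons each and an SVM trained on 450 + 450 synthetic patches; the
noise study measures mean F1 over three fixed scenes per read-noise
level (1%, 5%, 20% of axon intensity). Per-scene F1 at 15 boutons moves
in ~0.03 steps, so the noise comparison uses the three-scene mean, which
is stably monotone, rather than single-scene values. Oracle-equivalence
checks run 100 randomized trials per kernel against brute-force
reimplementations.

## Known limitations

* Single-σ enhancement: boutons far from 4 px sd need a different σ (no
  multi-scale pyramid).
* Axons crossing in depth at the same (x, y) produce multi-modal z
  profiles; the argmax picks one slice and no disambiguation is
  attempted (the profile is exposed for auditing).
* The min–max patch normalization discards absolute brightness; on data
  where brightness is the discriminating cue, switch
  `gabor.normalize_patch` off and retrain.
* The evaluation protocol allows at most one TP per box, so two true
  boutons closer than a box width cannot both be credited.
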