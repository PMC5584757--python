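"""LoG enhancement and interest-point candidates on a synthetic scene.

Shows the candidate funnel: the determinant-of-Hessian detector fires
generously on the enhanced projection, and the two-window NMS (W1 = 20
relocation, W2 = 10 suppression) reduces duplicates so roughly one
candidate per blob-like structure survives.
"""

from boutondetect import (
    EnhancementConfig,
    NmsConfig,
    SceneParams,
    detect_interest_points,
    enhance,
    generate_stack,
    mean_projection,
    relocate_to_local_max,
    suppress_duplicates,
)

stack, boxes, centres = generate_stack(SceneParams(seed=1))
proj = mean_projection(stack)
enhanced = enhance(proj, EnhancementConfig(sigma=4.0))

points = detect_interest_points(enhanced)
cfg = NmsConfig(w1=20, w2=10)
relocated = relocate_to_local_max(points, enhanced, cfg)
kept = suppress_duplicates(relocated, enhanced, cfg)

hits = sum(
    any(max(abs(k.row - r), abs(k.col - c)) <= 5 for k in kept)
    for r, c, _ in centres
)
print(f"raw interest points: {len(points)}")
print(f"after NMS:           {len(kept)}")
print(f"boutons with a candidate within 5 px: {hits}/{len(centres)}")
# All true boutons should survive as candidates; the surplus candidates
# (axon bumps, distractors) are what the classifier must reject.
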