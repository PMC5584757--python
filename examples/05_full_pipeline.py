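"""End-to-end detection on a synthetic stack, scored against ground truth.

Runs projection -> enhancement -> keypoints -> NMS -> Gabor + SVM ->
z-localization, then applies the point-in-box protocol (one TP per box)
and prints precision, recall and F1.
"""

from boutondetect import (
    SceneParams,
    detect_boutons,
    generate_stack,
    run_evaluation,
    train_from_synthetic,
)

model = train_from_synthetic(SceneParams(seed=7), n_per_class=450, split_seed=7)
stack, boxes, centres = generate_stack(SceneParams(seed=11))

result = detect_boutons(stack, model)
counts, (precision, recall, f1) = run_evaluation(result, boxes)

print("stage counts:", result.stage_counts)
print(f"TP {counts.tp}  FP {counts.fp}  FN {counts.fn}")
print(f"precision {precision:.3f}  recall {recall:.3f}  F1 {f1:.3f}")
z_ok = sum(
    1
    for d in result.detections
    for r, c, z in centres
    if max(abs(d.row - r), abs(d.col - c)) <= 5 and d.z == z
)
print(f"detections with the correct z slice: {z_ok}/{counts.tp}")
# High recall with moderate FP count is the expected operating point;
# each accepted detection also carries the stack slice it lives on.
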