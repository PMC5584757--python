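"""Precision-recall behaviour across the classifier score range.

Sweeps the operating threshold over [-1, 1], re-matching detections at
each cut, and reports the precision-recall AUC plus a few sample
operating points.
"""

import numpy as np

from boutondetect import (
    SceneParams,
    detect_boutons,
    generate_stack,
    threshold_sweep,
    train_from_synthetic,
)
import dataclasses

model = train_from_synthetic(SceneParams(seed=7), n_per_class=450, split_seed=7)
# Accept everything so every scored candidate enters the sweep.
model.params = dataclasses.replace(model.params, threshold=-1.0)

stack, boxes, _ = generate_stack(SceneParams(seed=11))
result = detect_boutons(stack, model)
scored = [(d.row, d.col, min(1.0, max(-1.0, d.score))) for d in result.detections]

sweep = threshold_sweep(scored, boxes, n_thresholds=1000)
print(f"candidates scored: {len(scored)}")
print(f"PR AUC: {sweep['auc_pr']:.3f}")
for frac in (0.25, 0.5, 0.9):
    i = int(frac * 999)
    print(f"threshold {sweep['thresholds'][i]:+.2f}: "
          f"precision {sweep['precision'][i]:.2f}, recall {sweep['recall'][i]:.2f}")
# Precision rises and recall falls as the threshold tightens; the AUC
# summarizes the trade-off independent of any single operating point.
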