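"""Generate a synthetic two-photon scene with known bouton ground truth.

Builds one 512 x 512 x 20 stack with 3 axons, 15 boutons and a few
blob-like distractors, and prints its layout.  The ground-truth boxes
are 25 x 25 px squares centred on the boutons, the format the
evaluation protocol consumes.
"""

from boutondetect import SceneParams, build_scene

scene = build_scene(SceneParams(seed=1))
stack = scene.stack

print(f"stack: {stack.depth} slices of {stack.frame_shape}, "
      f"voxel size {stack.voxel_size} um")
print(f"boutons: {len(scene.boutons)} (ground-truth boxes: {len(scene.boxes)})")
print(f"distractor blobs: {len(scene.distractors)}")
print(f"axon crossing pixels: {len(scene.crossings)}")
print("first three bouton centres (row, col, z):", scene.boutons[:3])
# Each bouton centre lies inside its box and carries a z-slice label the
# 3D localization stage should recover.
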