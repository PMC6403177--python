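"""Train a small U-net on phantom patches and segment a held-out case.

A scaled-down run (half architecture at base width 8, 32x32 patches,
4 training subjects) that fits in a couple of minutes on one CPU; the
published configurations (base width 64/32, 96x96 patches) are the same
code at larger settings.
"""

import numpy as np

from vesselseg import (
    PhantomConfig,
    SamplerConfig,
    UNet2D,
    UNetConfig,
    evaluate_case,
    generate_phantom,
    predict_volume,
    sample_patches,
    train,
)

patches = []
for seed in range(4):
    volume, mask, label = generate_phantom(PhantomConfig(seed=seed))
    cfg = SamplerConfig(patch_size=32, n_vessel_per_subject=125,
                        n_background_per_subject=125, seed=100 + seed)
    patches.extend(sample_patches(volume, label, mask, cfg))
print(f"training patches: {len(patches)}")

net_cfg = UNetConfig(base_width=8, depth=4, patch_size=32,
                     learning_rate=1e-3, batch_size=16, epochs=5, seed=0)
model = UNet2D(net_cfg)
print(f"trainable parameters: {model.num_parameters():,}")
history = train(model, patches, net_cfg)
for epoch, (loss, dice) in enumerate(zip(history.loss, history.train_dice), 1):
    print(f"  epoch {epoch}: loss={loss:.4f}  train soft-Dice={dice:.4f}")

volume, mask, label = generate_phantom(PhantomConfig(seed=500))
result = predict_volume(model, volume, mask, patch_size=32, stride=32)
report = evaluate_case(result.binary, label.data)
print()
print(f"held-out phantom: Dice={report.dice:.3f}  "
      f"95HD={report.hd95:.2f} voxels  AVD={report.avd:.3f} voxels")
print()
print("Dice near 1 and sub-voxel AVD mean the reconstructed vasculature")
print("overlaps the ground-truth tubes almost voxel for voxel.")
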