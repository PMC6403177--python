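"""Generate a synthetic TOF-like phantom and inspect its statistics.

Builds a 64^3 volume with bright tapered vessel tubes inside an
ellipsoidal brain mask and prints the vessel prevalence (targeted at
0.9% of brain voxels, the class imbalance the sampler is designed for)
and the intensity contrast between vessel and tissue voxels.
"""

import numpy as np

from vesselseg import PhantomConfig, generate_phantom, vessel_fraction

config = PhantomConfig(seed=1)
volume, mask, label = generate_phantom(config)

fraction = vessel_fraction(label, mask)
vessel_mean = volume.data[label.data > 0].mean()
tissue_mean = volume.data[(mask.data > 0) & (label.data == 0)].mean()

print(f"volume shape:        {volume.shape}")
print(f"brain voxels:        {int(mask.data.sum())}")
print(f"vessel voxels:       {int(label.data.sum())}")
print(f"vessel fraction:     {fraction:.4f}  (target {config.target_vessel_fraction})")
print(f"vessel mean / tissue mean intensity: {vessel_mean:.1f} / {tissue_mean:.1f}")
print()
print("The fraction sits in the sub-1% prevalence regime of real brain")
print("angiography; the contrast ratio mimics bright flowing blood on a")
print("darker tissue background.")
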