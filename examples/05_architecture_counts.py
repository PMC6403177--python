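"""Parameter accounting of the full and half U-net architectures.

The closed-form count (9*Cin*Cout + Cout per 3x3 convolution, Cin + 1
for the final 1x1) and the built model agree exactly; a learned 2x2
up-convolution decoder would land on a different total, which is how
the parameter-free nearest-neighbor up-sampling is pinned down.
"""

from vesselseg import UNet2D, UNetConfig, count_parameters

full = UNetConfig(base_width=64, depth=4, patch_size=96)
half = UNetConfig(base_width=32, depth=4, patch_size=96)

print(f"full U-net  (base 64): closed form {count_parameters(full):>12,}")
print(f"                       built model {UNet2D(full).num_parameters():>12,}")
print(f"half U-net  (base 32): closed form {count_parameters(half):>12,}")
print(f"                       built model {UNet2D(half).num_parameters():>12,}")
print(f"learned-upconv variant (full):     {count_parameters(full, upsampling='transpose'):>12,}")
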