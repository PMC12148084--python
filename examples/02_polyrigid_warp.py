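"""Fuse per-bone rigid motions into a dense polyrigid deformation field.

Each bone gets its own rigid transform (a 6-vector se(3) twist).  The field
exponentiates the weighted average of the twist table at every voxel, with
weights m_k / (1 + d_k^2) from the structure masses and distance maps, so the
warp is exactly rigid inside each bone and blends smoothly in between —
without folding.
"""

import numpy as np

from polypose.metrics import jacobian_stats
from polypose.phantom import PhantomConfig, generate_phantom
from polypose.polyrigid import build_field, build_structure_set, build_weights
from polypose import se3

volume, labelmap = generate_phantom(PhantomConfig(seed=0))
ss = build_structure_set(labelmap)
weights = build_weights(ss, "mass")
print(f"structure masses (normalized volumes): {np.round(ss.masses, 3)}")

# bone 1: 8 degrees about z, 5 mm toward -x; bone 2: -5 degrees about x, 4 mm in +y
twists = np.array([
    [0.0, 0.0, np.deg2rad(8.0), -5.0, 0.0, 0.0],
    [np.deg2rad(-5.0), 0.0, 0.0, 0.0, 4.0, 0.0],
])
field = build_field(weights, twists)

disp = field.displacement()
norm = np.linalg.norm(disp, axis=-1)
for k in (1, 2):
    inside = labelmap.labels == k
    print(f"bone {k}: mean displacement {norm[inside].mean():.2f} mm")
print(f"soft tissue: mean displacement {norm[labelmap.labels == 0].mean():.2f} mm "
      "(carried smoothly by the bone weights)")

report = jacobian_stats(field)
print(f"topology: {report.percent_folds:.2f}% folded voxels, "
      f"sigma(log|J|) = {report.sigma_log_jac:.4f}")

# with identical twists the field degenerates to a single rigid motion
rigid = build_field(weights, np.stack([twists[0], twists[0]]))
print(f"identical twists: sigma(log|J|) = {jacobian_stats(rigid).sigma_log_jac:.2e} "
      "(rigid motion changes no volume)")
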