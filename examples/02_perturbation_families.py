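"""Manufacture revision-required masks with the four synthetic error families.

Dilation/erosion move the boundary by ~2 px along chosen axes, shifts
translate the whole mask by a nonzero offset within +/-2 px, and boundary
noise displaces up to 15 contour vertices by +/-2 px and refills the polygon.
"""

import numpy as np

from contourqa.perturb import sample_perturbation
from contourqa.phantom import PhantomConfig, generate_patient

patient = generate_patient(PhantomConfig(), "demo", np.random.default_rng(3))
mask = patient.slices[0].masks[0]  # the bladder-like structure
print(f"clean mask area: {int(mask.sum())} px")

rng = np.random.default_rng(11)
for family in ("dilate", "erode", "shift", "boundary_noise"):
    perturbed, spec = sample_perturbation(mask, rng, family=family)
    sym_diff = int(np.abs(perturbed.astype(int) - mask.astype(int)).sum())
    print(f"{family:15s} area {int(mask.sum()):4d} -> {int(perturbed.sum()):4d} px, "
          f"symmetric difference {sym_diff:3d} px, params {spec.to_dict()}")
# The symmetric difference is the number of pixels a reviewer would have to
# correct; all families keep it small, i.e. errors stay anatomically plausible.
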