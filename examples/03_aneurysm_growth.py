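"""Grow a saccular aneurysm on a straight vessel segment.

Every ten frames the growth law converts the strongest outward blood-particle
impact near the lesion into a radius increment, resisted by the tissue fluid
and the collagen/elastin springs.  The radius never shrinks: inward pushes
are clamped to zero in this growth-only model.
"""

import numpy as np

from arterysph import AneurysmState, WallModel, evaluate_growth, make_fixture, step
from arterysph.kernels import KernelSet

system, geometry, config = make_fixture("tube_flow", radius=0.05, length=0.2)
kernels = KernelSet(config.h)
wall = WallModel()
lesion = AneurysmState(
    site=np.array([0.05, 0.1, 0.0]),
    outward_normal=np.array([1.0, 0.0, 0.0]),
    R=0.015,
    capture_radius=2 * config.h,
)
rng = np.random.default_rng(3)
print(f"{len(system)} particles; lesion R0 = {lesion.R * 1e3:.1f} mm")
for frame in range(1, 201):
    step(system, geometry, config, kernels, aneurysm=lesion, rng=rng)
    if frame % 10 == 0:
        rec = evaluate_growth(system, lesion, wall, kernels, config)
        if frame % 50 == 0:
            print(
                f"frame {frame:3d}: F_blood={rec['F_blood']:.3f} N, "
                f"dR={rec['dR'] * 1e6:.3f} um, R={rec['R'] * 1e3:.4f} mm"
            )
print("radius is non-decreasing by construction; final R =", f"{lesion.R * 1e3:.4f} mm")
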