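"""Validate the SPH wall-shear-stress estimate against planar Couette flow.

For a linear shear profile v_t = gamma * x_n the analytic WSS is mu*gamma.
Wall particles see a truncated kernel support, so their raw sums are biased
low; the correction C_xi = Nbar/N_i rescales them.  The central bottom-wall
particles should land within a few percent of the analytic value.
"""

import numpy as np

from arterysph import make_fixture, build_neighbors, compute_density, wss_frame
from arterysph.kernels import KernelSet

H = 0.025
GAMMA = 10.0  # shear rate, 1/s

system, geometry, config = make_fixture(
    "couette_channel", height=4 * H, lateral=12 * H, shear_rate=GAMMA
)
kernels = KernelSet(config.h)
nb = build_neighbors(system.positions, kernels.h)
compute_density(system, kernels, nb)
field = wss_frame(system, geometry, kernels, config, neighbors=nb)

pos = field.wall_positions
margin = 6 * H - 1.5 * H
central = (np.abs(pos[:, 1]) < margin) & (np.abs(pos[:, 2]) < margin) & (pos[:, 0] < H / 2)
got = field.wss_values[central].mean()
print(f"{len(system)} particles, {central.sum()} central bottom-wall particles")
print(f"analytic WSS  mu*gamma = {config.mu * GAMMA:.2f}")
print(f"SPH WSS (corrected)    = {got:.2f}   ({100 * got / (config.mu * GAMMA):.1f}% of analytic)")
print(f"mean correction C_xi   = {field.mean_c_xi:.3f}")
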