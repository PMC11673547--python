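"""Drive incompressible flow through a small bifurcation and watch the
solver residuals and the kernel-truncation correction.

The run uses a reduced copy of the reference scenario (G2).  The frame-mean
correction coefficient C_xi = Nbar/N_i quantifies how neighbor-deficient
the wall-adjacent particles are; in a steady run it settles into a narrow
band and fluctuates quasi-periodically with the particle circulation.
"""

from arterysph import preset, Simulation

cfg = preset("G2")
cfg.geometry.rp = 0.05
cfg.geometry.parent_length = 4 * cfg.geometry.rp
cfg.geometry.daughter_length = 4 * cfg.geometry.rp
cfg.run.priming_frames = 60
cfg.run.frames = 120
cfg.run.seed = 1

sim = Simulation(cfg).run()
stats = sim.stats_frame()
print(f"{len(sim.system)} particles, {cfg.run.frames} recorded frames")
print(f"max density error     : {stats['max_density_error'].max():.4f}  (target <= 0.01)")
print(f"mean |div v| (1/s)    : {stats['mean_divergence'].mean():.3f}")
print(f"frame-mean C_xi       : {stats['mean_c_xi'].mean():.3f} "
      f"(min {stats['mean_c_xi'].min():.3f}, max {stats['mean_c_xi'].max():.3f})")
print(f"particles recycled    : {sim.system.recycled_total}")
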