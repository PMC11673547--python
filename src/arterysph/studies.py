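"""Reference studies: the quantities the simulator is validated against.

Two study designs are bundled here so that tests, scripts and users run
the exact same computations:

* the Murray-angle table — total bifurcation angles for the tabulated
  radius ratios, straight from the radii relations;
* the correction-coefficient study — the reference bifurcation run (G2)
  monitored for the frame-mean kernel-truncation correction ``C_xi``;
* the orifice-WSS structure study — scaled-down lesioned runs across the
  preset matrix, summarised as per-scenario orifice WSS series.
"""

from __future__ import annotations

import numpy as np

from .scenarios_io import Simulation, preset
from .vessel_geometry import bifurcation_angles, daughter_radii

__all__ = [
    "murray_angle",
    "correction_coefficient_study",
    "scaled_down_scenario",
    "orifice_structure_study",
    "separation_score",
]


def murray_angle(r: float, n: float = 3.0) -> float:
    """Total bifurcation angle (degrees) for radius ratio ``r`` with
    ``rd2 = 1`` fixed, radii from Murray's law."""
    rp = (1.0 + r) ** (1.0 / n)
    rd1, rd2 = daughter_radii(rp, r, n)
    return bifurcation_angles(rp, rd1, rd2)[2]


def correction_coefficient_study(
    seed: int = 1, priming_frames: int = 200, frames: int = 600
):
    """Reference G2 bifurcation run monitored for the truncation correction.

    Runs the reference preset (n = 3, A = 75 deg, r = 1) at desk scale
    (~5,400 particles, spacing h/2) and records the frame mean of
    ``C_xi = Nbar / N_i`` over wall-adjacent particles for every recorded
    frame.  Returns a dict with the time-averaged frame mean, the series
    and run metadata.
    """
    cfg = preset("G2")
    cfg.run.seed = int(seed)
    cfg.run.priming_frames = priming_frames
    cfg.run.frames = frames
    sim = Simulation(cfg).run()
    stats = sim.stats_frame()
    return {
        "mean_c_xi": float(stats["mean_c_xi"].mean()),
        "series": stats[["frame", "mean_c_xi"]],
        "n_particles": len(sim.system),
        "frames": frames,
        "max_density_error": float(stats["max_density_error"].max()),
    }


def scaled_down_scenario(name: str, seed: int):
    """A reduced copy of a preset for the multi-scenario structure study.

    Roughly 1,600 particles (parent radius 0.05 m, segment lengths of four
    parent radii) with the lesion enabled near the junction, out of the
    bifurcation plane.  Priming covers roughly one transit of the vessel so
    the recorded window is quasi-steady.
    """
    cfg = preset(name)
    cfg.geometry.rp = 0.05
    cfg.geometry.parent_length = 4 * cfg.geometry.rp
    cfg.geometry.daughter_length = 4 * cfg.geometry.rp
    cfg.lesion.enabled = True
    cfg.lesion.branch = "parent"
    cfg.lesion.axial_fraction = 0.9
    cfg.lesion.azimuth_deg = 90.0
    cfg.run.seed = int(seed)
    cfg.run.priming_frames = 250
    cfg.run.frames = 350
    cfg.run.wss_interval = 2
    return cfg


def orifice_structure_study(names, seed: int = 1):
    """Run scaled-down lesioned scenarios and collect orifice WSS series.

    All scenarios share the one seed (a paired design: differences between
    cases are then structural, not sampling noise).  The orifice patch is
    2.5 lesion radii wide so each per-frame mean averages a few dozen wall
    particles.  Returns ``{name: 1-D array of per-sample orifice mean WSS}``.
    """
    out = {}
    for name in names:
        cfg = scaled_down_scenario(name, seed=seed)
        sim = Simulation(cfg).run()
        r0 = 0.3 * cfg.geometry.rp
        series = sim.orifice_series(orifice_radius=2.5 * r0)
        out[name] = series["mean_wss"].dropna().to_numpy()
    return out


def separation_score(series_by_name) -> float:
    """Ranked-separation statistic for a group of orifice WSS series.

    The largest pairwise difference of series means divided by the pooled
    within-series standard deviation: > 1 means the group members are
    clearly distinguishable against their own temporal variability.
    """
    means = np.array([np.mean(v) for v in series_by_name.values()])
    pooled = np.sqrt(np.mean([np.var(v, ddof=1) for v in series_by_name.values()]))
    spread = means.max() - means.min()
    return float(spread / pooled) if pooled > 0 else float("inf")
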