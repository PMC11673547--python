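"""Aneurysm growth from the force balance at the lesion site.

The lesion is a saccular (cystic) bulge: a sphere unioned into the lumen,
attached to the wall at a prescribed site.  Its radius grows under the net
outward force

    F_aneurysm = F_blood - F_fluid - F_protein

where ``F_blood`` is the largest outward push any nearby blood particle
exerts on the wall, ``F_fluid = rho_f * c * s * v_w`` is the resistance of
the surrounding tissue fluid treated as a compressible pseudo-fluid, and
``F_protein = (K_C S_C + K_E S_E) * (dR/R)`` is the spring-like resistance
of collagen and elastin in the wall under the hoop strain ``dR/R``.  The
radius increment per growth evaluation is

    dR = F_blood / (m/t^2 + rho_f c s / t + (K_C S_C + K_E S_E) / R)

with configurable effective wall mass ``m`` and growth time scale ``t``.
The printed constants mix units freely (the growth law is phenomenological,
not dimensional); they are reproduced verbatim and every one of them is
configurable.  Because ``F_blood`` is clamped at zero (blood pushing inward
cannot shrink a lesion in this growth-only model), ``dR >= 0`` and the
radius is non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSet
from .sph_core import Neighbors, ParticleSystem, SolverConfig, build_neighbors, compute_forces

__all__ = [
    "WallModel",
    "AneurysmState",
    "blood_impact_force",
    "tissue_fluid_force",
    "protein_resistance",
    "net_outward_force",
    "radius_increment",
    "grow",
    "evaluate_growth",
]

log = logging.getLogger(__name__)


@dataclass
class WallModel:
    """Wall / tissue constants of the growth law.

    Defaults are the pre-defined model parameters: tissue-fluid density
    ``rho_f`` (kg/m^3), wave propagation speed ``c`` (m/s), tissue-fluid
    cross-section ``s`` (m^2), collagen/elastin scale factors ``K_C, K_E``
    (N/m) and cross-sections ``S_C, S_E``.  ``m_wall`` (kg) and ``t_growth``
    (s) close the growth law; the model leaves them free.
    """

    rho_f: float = 1000.0
    c: float = 1500.0
    s: float = 0.01
    K_C: float = 3.52
    K_E: float = 800.0
    S_C: float = 10.0
    S_E: float = 20.0
    m_wall: float = 1.0
    t_growth: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rho_f", "c", "s", "K_C", "K_E", "S_C", "S_E", "m_wall", "t_growth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"WallModel.{name} must be strictly positive")

    @property
    def protein_stiffness(self) -> float:
        """Combined collagen + elastin stiffness ``K_C S_C + K_E S_E``."""
        return self.K_C * self.S_C + self.K_E * self.S_E


@dataclass
class AneurysmState:
    """Lesion site, bulge radius and growth bookkeeping.

    The bulge sphere is centred at ``site + overlap * R * outward_normal``
    so it stays attached to the wall and forms an orifice (the aneurysm
    mouth) where wall shear stress is monitored.
    """

    site: np.ndarray
    outward_normal: np.ndarray
    R: float
    dR: float = 0.0
    vw: float = 0.0
    sigma: float = 0.0
    active: bool = True
    capture_radius: float = 0.05      # particle capture radius around the site (m)
    overlap: float = 0.5              # bulge-centre offset as a fraction of R

    def __post_init__(self) -> None:
        self.site = np.asarray(self.site, dtype=float)
        n = np.asarray(self.outward_normal, dtype=float)
        self.outward_normal = n / np.linalg.norm(n)
        if self.R <= 0:
            raise ValueError("initial aneurysm radius must be positive")

    @property
    def center(self) -> np.ndarray:
        return self.site + self.overlap * self.R * self.outward_normal

    @property
    def strain(self) -> float:
        return self.sigma


def blood_impact_force(
    system: ParticleSystem,
    state: AneurysmState,
    kernels: KernelSet,
    config: SolverConfig,
    neighbors: Neighbors | None = None,
) -> float:
    """Maximum outward impact force of the blood particles near the lesion.

    Each particle in the capture set contributes
    ``f_i = (m_i / rho_i) (-grad p_i + mu lap v_i + F_adv,i)``; the returned
    scalar is the largest projection onto the outward wall normal, clamped
    at zero.  An empty capture set contributes no force.
    """
    pos = system.positions
    near = np.linalg.norm(pos - state.site, axis=1) <= state.capture_radius
    if not np.any(near):
        log.info("aneurysm capture region is empty; F_blood = 0")
        return 0.0
    if neighbors is None:
        neighbors = build_neighbors(pos, kernels.h)
    acc = compute_forces(system, kernels, config, neighbors, include_pressure=True)
    f = system.masses[:, None] * acc  # (m/rho) * force density
    proj = f[near] @ state.outward_normal
    return float(max(proj.max(), 0.0))


def tissue_fluid_force(state: AneurysmState, wall: WallModel) -> float:
    """Tissue-fluid resistance ``rho_f * c * s * v_w`` (pseudo-fluid model)."""
    return wall.rho_f * wall.c * wall.s * state.vw


def protein_resistance(state: AneurysmState, wall: WallModel) -> float:
    """Collagen/elastin spring resistance ``(K_C S_C + K_E S_E) * dR/R``."""
    if state.R <= 0:
        raise ValueError("aneurysm radius must be positive")
    return wall.protein_stiffness * (state.dR / state.R)


def net_outward_force(f_blood: float, f_fluid: float, f_protein: float) -> float:
    """Net expansion force ``F_blood - F_fluid - F_protein``."""
    return f_blood - f_fluid - f_protein


def radius_increment(f_blood: float, state: AneurysmState, wall: WallModel) -> float:
    """Radius increment of the growth law.

    ``dR = F_blood / (m/t^2 + rho_f c s / t + (K_C S_C + K_E S_E)/R)``;
    non-negative because ``F_blood`` is clamped at zero upstream.
    """
    if state.R <= 0:
        raise ValueError("aneurysm radius must be positive")
    denom = (
        wall.m_wall / wall.t_growth**2
        + wall.rho_f * wall.c * wall.s / wall.t_growth
        + wall.protein_stiffness / state.R
    )
    return max(f_blood, 0.0) / denom


def grow(state: AneurysmState, increment: float, t_growth: float = 1.0) -> AneurysmState:
    """Apply a radius increment; updates lesion velocity and strain in place.

    The geometric coupling is implicit: the bulge centre and radius that
    the signed-distance queries see are properties of this state.
    """
    if increment < 0:
        raise ValueError("radius increment must be non-negative")
    state.dR = float(increment)
    state.R += state.dR
    state.sigma = state.dR / state.R
    state.vw = state.dR / t_growth
    return state


def evaluate_growth(
    system: ParticleSystem,
    state: AneurysmState,
    wall: WallModel,
    kernels: KernelSet,
    config: SolverConfig,
    neighbors: Neighbors | None = None,
) -> dict:
    """One growth evaluation: force balance, increment, and bulge update.

    Returns a record of the force balance suitable for the growth log.
    ``F_fluid`` and ``F_protein`` are evaluated with the state *before* the
    increment (lesion velocity and strain lag one evaluation, as in an
    explicit update).
    """
    f_blood = blood_impact_force(system, state, kernels, config, neighbors)
    f_fluid = tissue_fluid_force(state, wall)
    f_protein = protein_resistance(state, wall)
    f_net = net_outward_force(f_blood, f_fluid, f_protein)
    d_r = radius_increment(f_blood, state, wall)
    grow(state, d_r, wall.t_growth)
    return {
        "F_blood": f_blood,
        "F_fluid": f_fluid,
        "F_protein": f_protein,
        "F_net": f_net,
        "dR": d_r,
        "R": state.R,
    }
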