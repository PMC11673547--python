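"""Incompressible SPH core: neighbors, density, forces, projection, walls.

Blood is treated as a water-like incompressible fluid discretised into
particles of equal mass ``m = rho0 * spacing^3``.  Each frame advances the
system through: neighbor search -> density -> non-pressure forces ->
semi-implicit Euler integration -> incompressibility projection (a
density-invariance position pass followed by a divergence-free velocity
pass) -> wall collision against the implicit vessel -> inlet/outlet
particle circulation.

The incompressibility projection enforces the twin conditions
``drho/dt = 0`` and ``div v = 0`` iteratively: the position pass is a
position-based-fluids style constraint solve that drives every particle's
density back to the rest density (compression only; rarefaction at free
boundaries is left alone, as is standard), and the velocity pass is a
divergence-free stiffness solve in the DFSPH family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .kernels import KernelSet

__all__ = [
    "SolverConfig",
    "ParticleSystem",
    "Neighbors",
    "SolveReport",
    "build_neighbors",
    "compute_density",
    "compute_pressure",
    "compute_forces",
    "enforce_incompressibility",
    "handle_boundary",
    "recycle_particles",
    "step",
    "lattice_points",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class SolverConfig:
    """Numerical and physical parameters of the fluid solver.

    ``mu`` and ``mu_b`` are the dimensionless blood-viscosity and
    vessel-wall viscous coefficients; ``mu`` multiplies the SPH viscosity
    term while ``mu_b`` scales tangential velocity damping during wall
    contact.  ``spacing`` defaults to ``h/2`` and fixes the particle mass
    ``m = rho0 * spacing^3``.
    """

    h: float = 0.025                  # kernel support radius (m)
    dt: float = 1.0e-3                # time step (s)
    mu: float = 4.0                   # blood viscosity coefficient (dimensionless)
    mu_b: float = 30.0                # wall viscous coefficient (dimensionless)
    rho0: float = 1000.0              # rest density (kg/m^3)
    density_tolerance: float = 0.01   # max relative density error allowed
    divergence_tolerance: float = 1.0 # mean |div v| bound (1/s)
    max_iterations: int = 16          # cap per projection pass
    inflow_speed: float = 0.5         # plug inflow speed (m/s)
    seed: int = 0
    spacing: float | None = None      # particle spacing (m); default h/2
    pressure_stiffness: float = 50.0  # EOS stiffness for reported pressure (m^2/s^2)
    inflow_zone: float | None = None  # axial depth of the inlet forcing zone (m)
    circulation: bool = True          # recycle outlet-crossers back to the inlet

    def __post_init__(self) -> None:
        if self.h <= 0 or self.dt <= 0:
            raise ValueError("h and dt must be positive")
        if self.density_tolerance <= 0 or self.divergence_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.spacing is None:
            self.spacing = 0.5 * self.h
        if self.inflow_zone is None:
            self.inflow_zone = 3.0 * self.spacing

    @property
    def particle_mass(self) -> float:
        return self.rho0 * self.spacing**3

    @property
    def kernels(self) -> KernelSet:
        return KernelSet(self.h)


# --------------------------------------------------------------------------
# Particle system
# --------------------------------------------------------------------------

class ParticleSystem:
    """Positions, velocities, masses and field estimates of the blood particles."""

    def __init__(self, positions, velocities=None, masses=None, *, mass: float | None = None):
        self.positions = np.array(positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.velocities = (
            np.zeros((n, 3)) if velocities is None else np.array(velocities, dtype=float).reshape(-1, 3)
        )
        if masses is not None:
            self.masses = np.array(masses, dtype=float).reshape(-1)
        else:
            self.masses = np.full(n, 1.0 if mass is None else float(mass))
        self.densities = np.zeros(n)
        self.pressures = np.zeros(n)
        self.external_force = np.zeros((n, 3))  # force density field (N/m^3)
        self.out_flagged = np.zeros(n, dtype=bool)
        self.recycled_total = 0
        self.crossings_total = 0
        self.deferred = 0

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def copy(self) -> "ParticleSystem":
        out = ParticleSystem(self.positions.copy(), self.velocities.copy(), self.masses.copy())
        out.densities = self.densities.copy()
        out.pressures = self.pressures.copy()
        out.external_force = self.external_force.copy()
        out.out_flagged = self.out_flagged.copy()
        out.recycled_total = self.recycled_total
        out.crossings_total = self.crossings_total
        out.deferred = self.deferred
        return out


def lattice_points(lo, hi, spacing: float) -> np.ndarray:
    """Cubic lattice covering ``[lo, hi]`` at the given spacing."""
    axes = [np.arange(lo[k], hi[k] + 0.5 * spacing, spacing) for k in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)


# --------------------------------------------------------------------------
# Neighbor search
# --------------------------------------------------------------------------

@dataclass
class Neighbors:
    """Symmetric neighbor structure as a directed edge list.

    ``e_i[k] -> e_j[k]`` lists every ordered pair with ``0 < |x_i - x_j| <= h``;
    both directions are present, so per-particle sums are plain bincounts
    over ``e_i``.
    """

    n: int
    e_i: np.ndarray
    e_j: np.ndarray

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.e_i, minlength=self.n)

    def lists(self) -> list[np.ndarray]:
        order = np.argsort(self.e_i, kind="stable")
        split = np.searchsorted(self.e_i[order], np.arange(1, self.n))
        return [np.sort(a) for a in np.split(self.e_j[order], split)]


def build_neighbors(positions, h: float) -> Neighbors:
    """All ordered pairs within the kernel support (grid-accelerated)."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite particle positions")
    n = len(pos)
    if n < 2:
        return Neighbors(n, np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp))
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=h, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        pairs = pairs[d > 0.0]
    e_i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    e_j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return Neighbors(n, e_i.astype(np.intp), e_j.astype(np.intp))


def _edge_geometry(positions, neigh: Neighbors):
    rel = positions[neigh.e_i] - positions[neigh.e_j]
    dist = np.linalg.norm(rel, axis=1)
    return rel, dist


def _edge_grad_spiky(rel, dist, h: float) -> np.ndarray:
    """Spiky gradient on each edge, vectorised (zero at r=0 and beyond h)."""
    coef = -45.0 / (np.pi * h**6)
    mag = np.where((dist > 0) & (dist <= h), coef * (h - dist) ** 2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(dist > 0, mag / np.where(dist > 0, dist, 1.0), 0.0)
    return scale[:, None] * rel


def _scatter(e_i, values, n) -> np.ndarray:
    """Sum per-edge vectors into per-particle vectors."""
    if values.ndim == 1:
        return np.bincount(e_i, weights=values, minlength=n)
    return np.stack(
        [np.bincount(e_i, weights=values[:, k], minlength=n) for k in range(values.shape[1])],
        axis=1,
    )


# --------------------------------------------------------------------------
# Field estimates
# --------------------------------------------------------------------------

def compute_density(system: ParticleSystem, kernels: KernelSet, neighbors: Neighbors | None = None):
    """SPH density ``rho_i = sum_j m_j W_poly6(|x_ij|)`` including the self term."""
    if neighbors is None:
        neighbors = build_neighbors(system.positions, kernels.h)
    _, dist = _edge_geometry(system.positions, neighbors)
    w = kernels.poly6(dist)
    rho = _scatter(neighbors.e_i, system.masses[neighbors.e_j] * w, len(system))
    rho = rho + system.masses * kernels.poly6(0.0)
    system.densities = rho
    return rho


def compute_pressure(system: ParticleSystem, config: SolverConfig):
    """Reported pressure from a clamped linear state equation.

    The projection solver, not this pressure, enforces incompressibility;
    the state-equation value is used for force analysis and export.
    """
    p = config.pressure_stiffness * (system.densities - config.rho0)
    system.pressures = np.maximum(p, 0.0)
    return system.pressures


def compute_forces(
    system: ParticleSystem,
    kernels: KernelSet,
    config: SolverConfig,
    neighbors: Neighbors | None = None,
    include_pressure: bool = True,
):
    """Per-particle accelerations ``(-grad p + mu lap v + F_adv) / rho``.

    The pressure gradient uses the standard symmetrised form, so pairwise
    pressure forces are exactly equal and opposite; the viscous term uses
    the viscosity-kernel Laplacian, which always damps relative motion.
    """
    if np.any(system.densities <= 0.0):
        raise RuntimeError("solver failure: non-positive particle density")
    if neighbors is None:
        neighbors = build_neighbors(system.positions, kernels.h)
    n = len(system)
    rel, dist = _edge_geometry(system.positions, neighbors)
    e_i, e_j = neighbors.e_i, neighbors.e_j
    rho, m, v = system.densities, system.masses, system.velocities

    acc = system.external_force / rho[:, None]

    lap = kernels.lap_viscosity(dist)
    dv = v[e_j] - v[e_i]
    visc = config.mu * _scatter(e_i, (m[e_j] / rho[e_j] * lap)[:, None] * dv, n)
    acc = acc + visc / rho[:, None]

    if include_pressure:
        p = system.pressures
        gw = _edge_grad_spiky(rel, dist, kernels.h)
        coef = m[e_j] * (p[e_i] / rho[e_i] ** 2 + p[e_j] / rho[e_j] ** 2)
        acc = acc - _scatter(e_i, coef[:, None] * gw, n)
    return acc


# --------------------------------------------------------------------------
# Incompressibility projection
# --------------------------------------------------------------------------

# minimum neighbor count for a particle to drive the divergence constraint
_DIV_MIN_NEIGHBORS = 20


@dataclass
class SolveReport:
    density_iterations: int = 0
    divergence_iterations: int = 0
    max_density_error: float = 0.0
    mean_divergence: float = 0.0
    density_converged: bool = True
    divergence_converged: bool = True
    rounds: int = 1


def _density_from_edges(system, kernels, neigh, dist):
    w = kernels.poly6(dist)
    rho = _scatter(neigh.e_i, system.masses[neigh.e_j] * w, len(system))
    return rho + system.masses * kernels.poly6(0.0)


def enforce_incompressibility(
    system: ParticleSystem,
    kernels: KernelSet,
    config: SolverConfig,
    neighbors: Neighbors | None = None,
    dt: float | None = None,
    max_rounds: int = 1,
    warn: bool = True,
) -> SolveReport:
    """Drive densities to the rest density and the velocity field to zero
    divergence.

    The density pass moves particles (compression error only — the free
    surface is allowed to be rarefied); accumulated displacements are folded
    back into the velocities when ``dt`` is given.  The velocity pass then
    removes the residual SPH velocity divergence.  ``max_rounds > 1``
    rebuilds the neighbor lists between rounds so the reported residual is
    measured on fresh lists (useful when initial displacements are large).
    """
    if dt is None:
        dt = config.dt
    n = len(system)
    m, rho0 = system.masses, config.rho0
    report = SolveReport()
    displacement = np.zeros((n, 3))

    for rnd in range(max_rounds):
        if neighbors is None:
            neighbors = build_neighbors(system.positions, kernels.h)
        e_i, e_j = neighbors.e_i, neighbors.e_j
        rel, dist = _edge_geometry(system.positions, neighbors)

        # --- density-invariance (position) pass ---
        it = 0
        for it in range(config.max_iterations + 1):
            rho = _density_from_edges(system, kernels, neighbors, dist)
            C = np.maximum(rho / rho0 - 1.0, 0.0)
            err = float(C.max()) if n else 0.0
            if err <= config.density_tolerance or it == config.max_iterations:
                break
            gw = _edge_grad_spiky(rel, dist, kernels.h)
            grad_i = _scatter(e_i, (m[e_j] / rho0)[:, None] * gw, n)
            sq_sum = _scatter(e_i, (m[e_j] / rho0) ** 2 * np.einsum("ij,ij->i", gw, gw), n)
            denom = np.einsum("ij,ij->i", grad_i, grad_i) + sq_sum
            eps = 1e-6 * denom.max() + 1e-30
            lam = -C / (denom + eps)
            dx = _scatter(e_i, ((m[e_j] / rho0) * (lam[e_i] + lam[e_j]))[:, None] * gw, n)
            system.positions += dx
            displacement += dx
            rel, dist = _edge_geometry(system.positions, neighbors)
        report.density_iterations += it
        report.max_density_error = err
        report.density_converged = err <= config.density_tolerance
        report.rounds = rnd + 1

        # --- divergence-free (velocity) pass ---
        rho = _density_from_edges(system, kernels, neighbors, dist)
        system.densities = rho
        gw = _edge_grad_spiky(rel, dist, kernels.h)
        sum_grad = _scatter(e_i, m[e_j][:, None] * gw, n)
        sum_sq = _scatter(e_i, m[e_j] ** 2 * np.einsum("ij,ij->i", gw, gw), n)
        denom = np.einsum("ij,ij->i", sum_grad, sum_grad) + sum_sq
        eps = 1e-6 * (denom.max() if n else 0.0) + 1e-30
        alpha = rho / (denom + eps)
        # free-surface particles (deficient neighborhoods) are excluded from
        # driving the constraint: their apparent divergence is a truncation
        # artifact, and correcting it destabilises the Jacobi iteration
        interior = neighbors.counts >= _DIV_MIN_NEIGHBORS
        div_it = 0
        for div_it in range(config.max_iterations + 1):
            dv = system.velocities[e_i] - system.velocities[e_j]
            drho_dt = _scatter(e_i, m[e_j] * np.einsum("ij,ij->i", dv, gw), n)
            drho_dt = np.where(interior, drho_dt, 0.0)
            mean_div = float(np.mean(np.abs(drho_dt)) / rho0) if n else 0.0
            if mean_div <= config.divergence_tolerance or div_it == config.max_iterations:
                break
            kappa = alpha * drho_dt  # stiffness * dt, applied directly below
            term = (m[e_j] * (kappa[e_i] / rho[e_i] + kappa[e_j] / rho[e_j]))[:, None] * gw
            # 0.5: Jacobi under-relaxation (a symmetric pair update otherwise
            # overshoots the pairwise solution by exactly a factor of two)
            system.velocities -= 0.5 * _scatter(e_i, term, n)
        report.divergence_iterations += div_it
        report.mean_divergence = mean_div
        report.divergence_converged = mean_div <= config.divergence_tolerance

        if report.density_converged or rnd == max_rounds - 1:
            break
        neighbors = None  # force a rebuild for the next round

    if dt > 0:
        system.velocities += displacement / dt

    if warn and not (report.density_converged and report.divergence_converged):
        warnings.warn(
            "incompressibility solve did not fully converge: "
            f"max density error {report.max_density_error:.3e}, "
            f"mean |div v| {report.mean_divergence:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
    return report


# --------------------------------------------------------------------------
# Boundary handling and particle circulation
# --------------------------------------------------------------------------

def handle_boundary(system: ParticleSystem, geometry, config: SolverConfig, aneurysm=None):
    """Project escaped particles back inside the lumen (no-penetration,
    free-slip with tangential damping).

    A particle found outside the implicit surface is moved along the inward
    normal to half a particle spacing inside the wall; its outward normal
    velocity component is removed and the tangential component is damped by
    ``1 - mu_b * dt`` (never below zero), so the collision never adds energy.
    """
    target = -0.5 * config.spacing
    d, nrm = geometry.signed_distance(system.positions, aneurysm)
    out = d > 0.0
    if not np.any(out):
        return out
    idx = np.where(out)[0]
    for _ in range(3):  # Newton-style projection; exact for straight walls
        system.positions[idx] -= (d[idx] - target)[:, None] * nrm[idx]
        d_new, nrm_new = geometry.signed_distance(system.positions[idx], aneurysm)
        d[idx], nrm[idx] = d_new, nrm_new
        if np.all(d[idx] <= 1e-12):
            break
    vn = np.einsum("ij,ij->i", system.velocities[idx], nrm[idx])
    outward = vn > 0.0
    system.velocities[idx[outward]] -= vn[outward, None] * nrm[idx[outward]]
    damp = max(0.0, 1.0 - config.mu_b * config.dt)
    vn2 = np.einsum("ij,ij->i", system.velocities[idx], nrm[idx])
    v_norm = vn2[:, None] * nrm[idx]
    v_tan = system.velocities[idx] - v_norm
    system.velocities[idx] = v_norm + damp * v_tan
    return out


def recycle_particles(system: ParticleSystem, geometry, config: SolverConfig, rng: np.random.Generator):
    """Re-insert outlet-crossing particles at the inlet with plug inflow.

    Particle count is conserved.  Insertions are capped at the number of
    inlet lattice slots per frame; any surplus crossers stay flagged beyond
    the outlet and re-enter the queue on the next frame.
    """
    excess = geometry.outlet_excess(system.positions)
    out = excess > 0.0
    new_crossers = out & ~system.out_flagged
    system.crossings_total += int(new_crossers.sum())
    system.out_flagged |= new_crossers
    queued = np.where(system.out_flagged)[0]
    if len(queued) == 0:
        system.deferred = 0
        return 0
    r_in = geometry.inlet_radius - 0.5 * config.spacing
    slots = max(1, int(np.pi * r_in**2 / config.spacing**2))
    take = queued[:slots]
    k = len(take)
    u = rng.random((k, 3))
    rad = r_in * np.sqrt(u[:, 0])
    theta = 2.0 * np.pi * u[:, 1]
    system.positions[take, 0] = rad * np.cos(theta)
    system.positions[take, 1] = 0.5 * config.spacing * u[:, 2]
    system.positions[take, 2] = rad * np.sin(theta)
    system.velocities[take] = (0.0, config.inflow_speed, 0.0)
    system.densities[take] = config.rho0
    system.pressures[take] = 0.0
    system.out_flagged[take] = False
    system.recycled_total += k
    system.deferred = len(queued) - k
    return k


# --------------------------------------------------------------------------
# Frame step
# --------------------------------------------------------------------------

def step(
    system: ParticleSystem,
    geometry,
    config: SolverConfig,
    kernels: KernelSet | None = None,
    aneurysm=None,
    rng: np.random.Generator | None = None,
) -> SolveReport:
    """Advance one frame; deterministic given the RNG state.

    Order: neighbors -> density -> non-pressure forces -> semi-implicit
    Euler -> incompressibility projection -> wall collision -> circulation.
    Pressure is enforced by the projection, not integrated as a force; the
    state-equation pressure is refreshed for analysis and export.
    """
    if kernels is None:
        kernels = config.kernels
    if rng is None:
        rng = np.random.default_rng(config.seed)
    neighbors = build_neighbors(system.positions, kernels.h)
    compute_density(system, kernels, neighbors)
    compute_pressure(system, config)
    acc = compute_forces(system, kernels, config, neighbors, include_pressure=False)
    system.velocities += acc * config.dt
    if config.circulation and config.inflow_speed != 0.0:
        zone = system.positions[:, 1] < config.inflow_zone
        system.velocities[zone] = (0.0, config.inflow_speed, 0.0)
    system.positions += system.velocities * config.dt
    report = enforce_incompressibility(
        system, kernels, config, neighbors=neighbors, dt=config.dt, warn=False
    )
    handle_boundary(system, geometry, config, aneurysm)
    if config.circulation:
        recycle_particles(system, geometry, config, rng)
    compute_pressure(system, config)
    return report
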