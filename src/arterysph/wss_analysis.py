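"""Wall shear stress on wall-adjacent particles, SPH-discretised.

WSS is the tangential traction the flowing blood exerts on the vessel wall,
``WSS = -mu * d v_t / d x_n`` in the continuum.  On particles it becomes a
kernel sum over each wall particle's neighbors,

    WSS_i = mu * | sum_j m_j C_xi,i v_t,j / rho_j * dW/dx_n(x_i - x_j) |

where ``v_t,j`` is the neighbor's velocity projected tangential to the wall,
``dW/dx_n`` the directional kernel derivative along the local wall normal,
and ``C_xi,i = Nbar / N_i`` a kernel-truncation correction: wall particles
sit at the edge of the fluid and see too few neighbors, so their sums are
rescaled by the ratio of the frame-wide mean neighbor count ``Nbar`` to
their own count.  Both ``Nbar`` and ``C_xi`` are recomputed every frame.

The summand is accumulated as a tangential *vector* and reported as its
magnitude times the viscosity, which is non-negative and reduces to
``|mu * dv_t/dx_n|`` in the planar Couette limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kernels import KernelSet
from .sph_core import Neighbors, ParticleSystem, SolverConfig, build_neighbors

__all__ = [
    "WSSField",
    "select_wall_particles",
    "correction_coefficient",
    "wss_at_particle",
    "wss_frame",
    "orifice_timeseries",
    "wss_colors",
]

log = logging.getLogger(__name__)


@dataclass
class WSSField:
    """Per-frame wall shear stress field over the wall-adjacent particles."""

    frame: int
    wall_particle_ids: np.ndarray     # indices into the particle system
    wall_positions: np.ndarray        # (k, 3) positions at evaluation time
    wss_values: np.ndarray            # (k,) stress (Pa)
    c_xi: np.ndarray                  # (k,) correction coefficients
    neighbor_counts: np.ndarray       # (k,) N_i of each wall particle
    mean_c_xi: float
    n_bar: float                      # mean neighbor count over all fluid particles
    delta: float                      # wall-distance threshold used (m)


def select_wall_particles(system: ParticleSystem, geometry, delta: float, aneurysm=None):
    """Particles within ``delta`` of the wall, with their outward normals.

    Returns ``(ids, normals, wall_points)`` where ``wall_points`` are the
    projections of the selected particles onto the wall surface.
    """
    d, nrm = geometry.signed_distance(system.positions, aneurysm)
    mask = np.abs(d) <= delta
    ids = np.where(mask)[0]
    normals = nrm[ids]
    wall_points = system.positions[ids] - d[ids, None] * normals
    return ids, normals, wall_points


def correction_coefficient(n_i, n_bar: float):
    """Kernel-truncation correction ``C_xi = Nbar / N_i`` (vectorised)."""
    n_i = np.asarray(n_i, dtype=float)
    if np.any(n_i <= 0):
        raise ValueError("correction coefficient undefined for N_i = 0")
    out = n_bar / n_i
    return out if out.ndim else float(out)


def wss_at_particle(
    i: int,
    system: ParticleSystem,
    kernels: KernelSet,
    normal,
    wall_point,
    c_xi: float,
    neighbors: Neighbors | None = None,
    mu: float = 4.0,
) -> float:
    """WSS at a single wall particle (scalar reference path).

    The vectorised frame computation in :func:`wss_frame` follows exactly
    this sum; this function is the readable single-particle form.
    """
    if neighbors is None:
        neighbors = build_neighbors(system.positions, kernels.h)
    nb = neighbors.e_j[neighbors.e_i == i]
    if len(nb) == 0:
        log.info("wall particle %d has no neighbors; WSS = 0", i)
        return 0.0
    n_hat = np.asarray(normal, dtype=float)
    wall_point = np.asarray(wall_point, dtype=float)
    xi, xj = system.positions[i], system.positions[nb]
    rel = xi - xj
    dist = np.linalg.norm(rel, axis=1)
    xn_i = float((xi - wall_point) @ n_hat)
    xn_j = (xj - wall_point) @ n_hat
    grad_n = (xn_i - xn_j) / dist * kernels.spiky_radial_derivative(dist)
    vj = system.velocities[nb]
    vt = vj - (vj @ n_hat)[:, None] * n_hat
    summand = (system.masses[nb] * c_xi / system.densities[nb] * grad_n)[:, None] * vt
    return float(mu * np.linalg.norm(summand.sum(axis=0)))


def wss_frame(
    system: ParticleSystem,
    geometry,
    kernels: KernelSet,
    config: SolverConfig,
    frame: int = 0,
    neighbors: Neighbors | None = None,
    aneurysm=None,
    delta: float | None = None,
    mu_phys: float | None = None,
) -> WSSField:
    """Select wall particles and compute corrected WSS for one frame.

    ``delta`` defaults to one particle spacing below the kernel radius,
    ``h/2``.  ``mu_phys`` optionally replaces the dimensionless viscosity
    coefficient by a physical viscosity for reporting in Pa.
    """
    if delta is None:
        delta = 0.5 * kernels.h
    if neighbors is None:
        neighbors = build_neighbors(system.positions, kernels.h)
    counts = neighbors.counts
    n_bar = float(counts.mean()) if len(counts) else 0.0
    ids, normals, wall_points = select_wall_particles(system, geometry, delta, aneurysm)

    usable = counts[ids] > 0
    if not np.all(usable):
        log.info("excluding %d isolated wall particles from WSS", int((~usable).sum()))
    ids, normals, wall_points = ids[usable], normals[usable], wall_points[usable]
    k = len(ids)
    mu = config.mu if mu_phys is None else mu_phys

    wss = np.zeros(k)
    c_xi = np.zeros(k)
    if k:
        c_xi = correction_coefficient(counts[ids], n_bar)
        # edges whose source is a wall particle
        wall_slot = np.full(len(system), -1, dtype=np.intp)
        wall_slot[ids] = np.arange(k)
        sel = wall_slot[neighbors.e_i] >= 0
        ei, ej = neighbors.e_i[sel], neighbors.e_j[sel]
        slot = wall_slot[ei]
        rel = system.positions[ei] - system.positions[ej]
        dist = np.linalg.norm(rel, axis=1)
        n_e = normals[slot]
        wp_e = wall_points[slot]
        xn_i = np.einsum("ij,ij->i", system.positions[ei] - wp_e, n_e)
        xn_j = np.einsum("ij,ij->i", system.positions[ej] - wp_e, n_e)
        grad_n = (xn_i - xn_j) / dist * kernels.spiky_radial_derivative(dist)
        vj = system.velocities[ej]
        vt = vj - np.einsum("ij,ij->i", vj, n_e)[:, None] * n_e
        w = system.masses[ej] * c_xi[slot] / system.densities[ej] * grad_n
        vec = np.stack(
            [np.bincount(slot, weights=w * vt[:, d], minlength=k) for d in range(3)],
            axis=1,
        )
        wss = mu * np.linalg.norm(vec, axis=1)

    return WSSField(
        frame=frame,
        wall_particle_ids=ids,
        wall_positions=system.positions[ids].copy(),
        wss_values=wss,
        c_xi=c_xi,
        neighbor_counts=counts[ids],
        mean_c_xi=float(c_xi.mean()) if k else float("nan"),
        n_bar=n_bar,
        delta=delta,
    )


def orifice_timeseries(fields, state, window=None, orifice_radius: float | None = None):
    """Per-frame mean WSS over the aneurysm mouth.

    ``fields`` is a sequence of :class:`WSSField`; the orifice region is
    the set of wall particles within ``orifice_radius`` (default 1.5 times
    the lesion's initial radius, passed explicitly by the caller) of the
    lesion site.  Frames whose orifice region is empty yield NaN.

    Returns a pandas DataFrame with columns ``frame, mean_wss, n_orifice``.
    """
    import pandas as pd

    if orifice_radius is None:
        orifice_radius = 1.5 * state.R
    site = np.asarray(state.site, dtype=float)
    rows = []
    for f in fields:
        if window is not None and not (window[0] <= f.frame < window[1]):
            continue
        if len(f.wall_particle_ids):
            near = np.linalg.norm(f.wall_positions - site, axis=1) <= orifice_radius
        else:
            near = np.zeros(0, dtype=bool)
        if near.any():
            rows.append((f.frame, float(f.wss_values[near].mean()), int(near.sum())))
        else:
            rows.append((f.frame, float("nan"), 0))
    return pd.DataFrame(rows, columns=["frame", "mean_wss", "n_orifice"])


def wss_colors(values, cmap_name: str = "YlOrRd"):
    """Map WSS values monotonically to colors (small -> light, large -> dark).

    Returns RGB triples in [0, 1]; the rank order of luminance-inverted
    colors follows the rank order of the values.
    """
    import matplotlib

    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo if hi > lo else 1.0
    t = (values - lo) / span
    cmap = matplotlib.colormaps[cmap_name]
    return np.asarray(cmap(t))[:, :3]
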