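"""Parameter-adjustable bifurcating-artery geometry based on Murray's law.

The lumen is an implicit surface: the union of a parent tube, two daughter
tubes whose radii blend smoothly from the parent radius across the junction,
and (optionally) a spherical aneurysm bulge.  Murray's law fixes the daughter
radii from the parent radius, the bifurcation index ``n`` and the radius
ratio ``r``; the energy-optimal branching angles follow from the same radii.

Working in an implicit representation keeps boundary handling cheap: a
particle only ever needs the signed distance to the wall and the outward
normal, both of which are closed-form here.

Coordinate convention: the parent axis runs along +y with the inlet plane at
``y = 0``; the bifurcation lies in the x-y plane; daughter 1 (the smaller
radius) is rotated by ``+alpha`` about the junction point, daughter 2 by
``-beta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryInfeasibleError",
    "JunctionProfile",
    "BifurcationSpec",
    "daughter_radii",
    "bifurcation_angles",
    "build_bifurcation",
    "junction_profile",
    "fit_junction_profile",
    "signed_distance",
    "BifurcationGeometry",
    "Tube",
    "SlabChannel",
    "Box",
    "surface_mesh",
]


class GeometryInfeasibleError(ValueError):
    """Raised when radii admit no consistent bifurcation angle."""


# --------------------------------------------------------------------------
# Murray's law radii and angles
# --------------------------------------------------------------------------

def daughter_radii(rp: float, r: float, n: float) -> tuple[float, float]:
    """Daughter radii from Murray's law ``rp^n = rd1^n + rd2^n``.

    ``r`` is the radius ratio ``rd1^n / rd2^n``.  Daughters are oriented so
    that ``rd1 <= rd2`` (for ``r > 1`` the labels are swapped).
    """
    if rp <= 0 or r <= 0 or n <= 0:
        raise ValueError(f"rp, r and n must be positive (got rp={rp}, r={r}, n={n})")
    rd_a = rp * (r / (1.0 + r)) ** (1.0 / n)
    rd_b = rp * (1.0 / (1.0 + r)) ** (1.0 / n)
    rd1, rd2 = min(rd_a, rd_b), max(rd_a, rd_b)
    return rd1, rd2


def bifurcation_angles(rp: float, rd1: float, rd2: float) -> tuple[float, float, float]:
    """Energy-optimal branching angles (degrees) from the vessel radii.

    The cosine relations are those of a triangle with sides ``rp^2``,
    ``rd1^2``, ``rd2^2`` (a consequence of minimising pumping power under
    Poiseuille flow), so ``A = alpha + beta`` is verified against the
    closed-form ``cos(A)`` as an internal consistency check.
    """
    if min(rp, rd1, rd2) <= 0:
        raise ValueError("radii must be positive")
    rp2, r12, r22 = rp * rp, rd1 * rd1, rd2 * rd2
    cos_a = (rp2**2 + r12**2 - r22**2) / (2.0 * rp2 * r12)
    cos_b = (rp2**2 + r22**2 - r12**2) / (2.0 * rp2 * r22)
    cos_t = (rp2**2 - r12**2 - r22**2) / (2.0 * r12 * r22)
    for name, c in (("alpha", cos_a), ("beta", cos_b), ("A", cos_t)):
        if not -1.0 <= c <= 1.0 + 1e-12:
            raise GeometryInfeasibleError(
                f"cos({name}) = {c:.6f} outside [-1, 1]; radii admit no planar bifurcation"
            )
    alpha = math.degrees(math.acos(min(cos_a, 1.0)))
    beta = math.degrees(math.acos(min(cos_b, 1.0)))
    total = math.degrees(math.acos(min(max(cos_t, -1.0), 1.0)))
    if abs(total - (alpha + beta)) > 1e-6:
        raise GeometryInfeasibleError(
            f"angle closure violated: alpha + beta = {alpha + beta:.8f} vs A = {total:.8f}"
        )
    return alpha, beta, alpha + beta


# --------------------------------------------------------------------------
# Junction smoothing profile
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionProfile:
    """Sigmoid wall-radius blend ``F(d) = a1 * G(a2*d + b2) + b1``.

    ``G`` is the logistic function, ``d`` the axial distance into the blend
    region.  ``b1`` is the parent-side radius (limit ``d -> -inf``) and
    ``a1 + b1`` the daughter-side radius (limit ``d -> +inf``).  An exact
    first-derivative zero at the finite ends of the blend is impossible for
    a sigmoid; instead ``a2 * blend_length`` is chosen large enough that
    ``|dF/dd|`` at the endpoints is negligible against the mid-blend slope.
    """

    a1: float
    a2: float
    b1: float
    b2: float

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        g = 1.0 / (1.0 + np.exp(-np.clip(self.a2 * d + self.b2, -500, 500)))
        out = self.a1 * g + self.b1
        return out if out.ndim else float(out)

    def derivative(self, d):
        d = np.asarray(d, dtype=float)
        g = 1.0 / (1.0 + np.exp(-np.clip(self.a2 * d + self.b2, -500, 500)))
        out = self.a1 * self.a2 * g * (1.0 - g)
        return out if out.ndim else float(out)


def fit_junction_profile(
    r_parent: float, r_daughter: float, blend_length: float, sharpness: float = 20.0
) -> JunctionProfile:
    """Fit the sigmoid so the radius blends from ``r_parent`` to ``r_daughter``
    over ``[0, blend_length]`` with near-zero slope at both ends.

    ``sharpness = a2 * blend_length`` (default 20) keeps the endpoint slope
    below ``1e-3`` of the mid-blend slope ``a1*a2/4``.
    """
    if blend_length <= 0:
        raise ValueError("blend_length must be positive")
    a2 = sharpness / blend_length
    return JunctionProfile(
        a1=r_daughter - r_parent, a2=a2, b1=r_parent, b2=-0.5 * sharpness
    )


def junction_profile(d, profile: JunctionProfile):
    """Wall offset (radius) at axial blend distance ``d``."""
    return profile(d)


# --------------------------------------------------------------------------
# The bifurcation specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BifurcationSpec:
    """Fully resolved bifurcating-vessel geometry.

    The junction blend coefficients ``a1, a2, b1, b2`` are per-daughter
    pairs ``(daughter 1, daughter 2)`` since the two daughters generally
    have different radii.
    """

    rp: float
    rd1: float
    rd2: float
    n: float
    A: float          # total bifurcation angle, degrees
    alpha: float      # daughter-1 angle from the parent axis, degrees
    beta: float       # daughter-2 angle, degrees
    r: float          # radius ratio rd1^n / rd2^n
    parent_length: float
    daughter_length: float
    blend_length: float
    a1: tuple[float, float]
    a2: tuple[float, float]
    b1: tuple[float, float]
    b2: tuple[float, float]
    N_daughters: int = 2

    def __post_init__(self) -> None:
        lhs = self.rd1**self.n + self.rd2**self.n
        if abs(lhs - self.rp**self.n) > 1e-9 * self.rp**self.n:
            raise ValueError("Murray identity rp^n = rd1^n + rd2^n violated")
        if abs(self.A - (self.alpha + self.beta)) > 1e-9:
            raise ValueError("A must equal alpha + beta")
        if not (0 < self.rd1 <= self.rd2 <= self.rp):
            raise ValueError("require 0 < rd1 <= rd2 <= rp")

    # -- derived geometry ---------------------------------------------------
    @property
    def junction(self) -> np.ndarray:
        return np.array([0.0, self.parent_length, 0.0])

    @property
    def daughter_axes(self) -> np.ndarray:
        a, b = math.radians(self.alpha), math.radians(self.beta)
        return np.array(
            [
                [math.sin(a), math.cos(a), 0.0],
                [-math.sin(b), math.cos(b), 0.0],
            ]
        )

    def daughter_profile(self, i: int) -> JunctionProfile:
        return JunctionProfile(self.a1[i], self.a2[i], self.b1[i], self.b2[i])

    @property
    def daughter_radii_(self) -> tuple[float, float]:
        return (self.rd1, self.rd2)


def build_bifurcation(
    n: float,
    r: float,
    rp: float,
    A_override: float | None = None,
    parent_length: float | None = None,
    daughter_length: float | None = None,
    blend_length: float | None = None,
    sharpness: float = 20.0,
) -> BifurcationSpec:
    """Construct a :class:`BifurcationSpec` from the three adjustable
    parameters (bifurcation index ``n``, radius ratio ``r``, parent radius
    ``rp``).

    Radii always satisfy Murray's law.  The total angle defaults to the
    energy-optimal value from the radii; ``A_override`` replaces it (needed
    for study designs that vary the angle independently), split between the
    daughters in proportion to the optimal split, or symmetrically when the
    optimal angle degenerates to zero.
    """
    rd1, rd2 = daughter_radii(rp, r, n)
    alpha_m, beta_m, A_m = bifurcation_angles(rp, rd1, rd2)
    if A_override is None:
        alpha, beta, A = alpha_m, beta_m, A_m
    else:
        if A_override <= 0 or A_override >= 180:
            raise ValueError("A_override must lie in (0, 180) degrees")
        A = float(A_override)
        if A_m > 1e-9:
            alpha = A * alpha_m / A_m
        else:
            alpha = 0.5 * A
        beta = A - alpha
    parent_length = 8.0 * rp if parent_length is None else parent_length
    daughter_length = 8.0 * rp if daughter_length is None else daughter_length
    blend_length = 2.0 * rp if blend_length is None else blend_length
    p1 = fit_junction_profile(rp, rd1, blend_length, sharpness)
    p2 = fit_junction_profile(rp, rd2, blend_length, sharpness)
    return BifurcationSpec(
        rp=rp,
        rd1=rd1,
        rd2=rd2,
        n=n,
        A=A,
        alpha=alpha,
        beta=beta,
        r=r,
        parent_length=parent_length,
        daughter_length=daughter_length,
        blend_length=blend_length,
        a1=(p1.a1, p2.a1),
        a2=(p1.a2, p2.a2),
        b1=(p1.b1, p2.b1),
        b2=(p1.b2, p2.b2),
    )


# --------------------------------------------------------------------------
# Implicit-surface queries
# --------------------------------------------------------------------------

def _union(d_list, n_list):
    d = np.stack(d_list, axis=0)
    nrm = np.stack(n_list, axis=0)
    idx = np.argmin(d, axis=0)
    cols = np.arange(d.shape[1])
    return d[idx, cols], nrm[idx, cols]


def _aneurysm_sdf(points, aneurysm):
    c = np.asarray(aneurysm.center, dtype=float)
    rel = points - c
    dist = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore"):
        nrm = np.where(dist[:, None] > 0, rel / np.where(dist[:, None] > 0, dist[:, None], 1.0), 0.0)
    nrm[dist == 0] = (1.0, 0.0, 0.0)
    return dist - aneurysm.R, nrm


def signed_distance(points, spec: BifurcationSpec, aneurysm=None):
    """Signed distance (negative inside the lumen) and outward unit normal.

    The lumen is the union of the parent tube (capped at the junction
    plane), the two daughter tubes with sigmoid-blended radii (capped at
    the junction, open at the outlets), and, when ``aneurysm`` is given and
    active, its spherical bulge.  Inlet and outlet planes carry no wall.
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    ds, ns = [], []

    # parent tube: radial distance, capped at the junction plane
    radial = np.hypot(p[:, 0], p[:, 2])
    sd_rad = radial - spec.rp
    sd_cap = p[:, 1] - spec.parent_length
    d_par = np.maximum(sd_rad, sd_cap)
    with np.errstate(invalid="ignore"):
        rad_n = np.zeros_like(p)
        nz = radial > 0
        rad_n[nz, 0] = p[nz, 0] / radial[nz]
        rad_n[nz, 2] = p[nz, 2] / radial[nz]
        rad_n[~nz] = (1.0, 0.0, 0.0)
    n_par = np.where((sd_rad >= sd_cap)[:, None], rad_n, [0.0, 1.0, 0.0])
    ds.append(d_par)
    ns.append(n_par)

    # daughters: blended radius along each axis, capped at the junction
    J = spec.junction
    axes = spec.daughter_axes
    for i in range(2):
        u = axes[i]
        prof = spec.daughter_profile(i)
        rel = p - J
        t = rel @ u
        radvec = rel - t[:, None] * u
        radd = np.linalg.norm(radvec, axis=1)
        R_t = prof(t)
        sd_rad = radd - R_t
        d_i = np.maximum(sd_rad, -t)
        with np.errstate(invalid="ignore"):
            rdir = np.where(radd[:, None] > 0, radvec / np.where(radd[:, None] > 0, radd[:, None], 1.0), 0.0)
        grad = rdir - prof.derivative(t)[:, None] * u
        gn = np.linalg.norm(grad, axis=1)
        grad = np.where(gn[:, None] > 0, grad / np.where(gn[:, None] > 0, gn[:, None], 1.0), rdir)
        n_i = np.where((sd_rad >= -t)[:, None], grad, -u)
        ds.append(d_i)
        ns.append(n_i)

    if aneurysm is not None and getattr(aneurysm, "active", True):
        d_a, n_a = _aneurysm_sdf(p, aneurysm)
        ds.append(d_a)
        ns.append(n_a)

    d, nrm = _union(ds, ns)
    if single:
        return float(d[0]), nrm[0]
    return d, nrm


# --------------------------------------------------------------------------
# Geometry adapters (shared interface for the solver and fixtures)
# --------------------------------------------------------------------------

class BifurcationGeometry:
    """Bind a :class:`BifurcationSpec` to the solver's geometry interface."""

    def __init__(self, spec: BifurcationSpec):
        self.spec = spec

    def signed_distance(self, points, aneurysm=None):
        return signed_distance(points, self.spec, aneurysm)

    def outlet_excess(self, points):
        """Per-particle distance beyond an open inlet/outlet plane (>0 if out).

        A particle is "out" when it has left a daughter outlet plane or
        drifted backwards past the inlet plane.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        excess = np.maximum(-p[:, 1], 0.0)  # backwards through the inlet
        rel = p - self.spec.junction
        for u in self.spec.daughter_axes:
            t = rel @ u
            excess = np.maximum(excess, t - self.spec.daughter_length)
        return excess

    @property
    def inlet_radius(self) -> float:
        return self.spec.rp

    def bounding_box(self):
        """Tight axis-aligned box around the lumen (excluding any bulge)."""
        s = self.spec
        a, b = math.radians(s.alpha), math.radians(s.beta)
        xmax = max(s.rp, math.sin(a) * s.daughter_length + s.rd1)
        xmin = -max(s.rp, math.sin(b) * s.daughter_length + s.rd2)
        ymax = s.parent_length + s.daughter_length * max(math.cos(a), math.cos(b)) + s.rp
        return (np.array([xmin, 0.0, -s.rp]), np.array([xmax, ymax, s.rp]))


class Tube:
    """Straight tube along +y, open at both ends (fixture geometry)."""

    def __init__(self, radius: float, length: float):
        self.radius = float(radius)
        self.length = float(length)

    def signed_distance(self, points, aneurysm=None):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        radial = np.hypot(p[:, 0], p[:, 2])
        d = radial - self.radius
        nrm = np.zeros_like(p)
        nz = radial > 0
        nrm[nz, 0] = p[nz, 0] / radial[nz]
        nrm[nz, 2] = p[nz, 2] / radial[nz]
        nrm[~nz] = (1.0, 0.0, 0.0)
        if aneurysm is not None and getattr(aneurysm, "active", True):
            d_a, n_a = _aneurysm_sdf(p, aneurysm)
            d, nrm = _union([d, d_a], [nrm, n_a])
        if np.asarray(points).ndim == 1:
            return float(d[0]), nrm[0]
        return d, nrm

    def outlet_excess(self, points):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.maximum(np.maximum(-p[:, 1], p[:, 1] - self.length), 0.0)

    @property
    def inlet_radius(self) -> float:
        return self.radius


class SlabChannel:
    """Fluid slab between two parallel walls at ``x_n = 0`` and ``x_n = H``.

    The wall-normal axis is x; the channel is unbounded in y and z (used
    for shear-flow validation against the planar Couette solution).
    """

    def __init__(self, height: float):
        self.height = float(height)

    def signed_distance(self, points, aneurysm=None):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d_bot = -p[:, 0]
        d_top = p[:, 0] - self.height
        d = np.maximum(d_bot, d_top)
        nrm = np.where(
            (d_bot >= d_top)[:, None],
            np.array([-1.0, 0.0, 0.0]),
            np.array([1.0, 0.0, 0.0]),
        )
        if np.asarray(points).ndim == 1:
            return float(d[0]), nrm[0]
        return d, nrm

    def outlet_excess(self, points):
        return np.zeros(np.atleast_2d(points).shape[0])


class Box:
    """Closed rectangular container (fixture geometry for settling tests)."""

    def __init__(self, lo, hi):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)

    def signed_distance(self, points, aneurysm=None):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        faces = np.concatenate([self.lo - p, p - self.hi], axis=1)  # (N, 6)
        d = faces.max(axis=1)
        which = faces.argmax(axis=1)
        normals = np.vstack([-np.eye(3), np.eye(3)])
        nrm = normals[which]
        if np.asarray(points).ndim == 1:
            return float(d[0]), nrm[0]
        return d, nrm

    def outlet_excess(self, points):
        return np.zeros(np.atleast_2d(points).shape[0])


# --------------------------------------------------------------------------
# Surface extraction for export
# --------------------------------------------------------------------------

def surface_mesh(spec: BifurcationSpec, aneurysm=None, resolution: int = 60):
    """Triangulate the zero level set on a regular grid (marching cubes).

    Returns ``(vertices, faces)`` in world coordinates, suitable for the
    PLY / legacy-VTK writers in :mod:`arterysph.export`.
    """
    from skimage.measure import marching_cubes

    geo = BifurcationGeometry(spec)
    lo, hi = geo.bounding_box()
    pad = 0.1 * (hi - lo)
    lo, hi = lo - pad, hi + pad
    xs = [np.linspace(lo[k], hi[k], resolution) for k in range(3)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1).reshape(-1, 3)
    d, _ = geo.signed_distance(grid, aneurysm)
    vol = d.reshape(resolution, resolution, resolution)
    spacing = tuple((hi[k] - lo[k]) / (resolution - 1) for k in range(3))
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=spacing)
    return verts + lo, faces
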