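"""SPH smoothing kernels.

The three classic kernels of particle hydrodynamics are used for the three
field estimates they were designed for: poly6 for density sums, the spiky
gradient for pressure forces (its gradient does not vanish at the origin,
which prevents particle clumping), and the viscosity Laplacian, which is
non-negative on its support so that viscous coupling always damps relative
motion.

All kernels have compact support ``|x| <= h`` and are evaluated in double
precision directly from their closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSet", "w_poly6", "grad_spiky", "lap_viscosity", "spiky_radial_derivative"]


def _check_h(h: float) -> float:
    h = float(h)
    if not np.isfinite(h) or h <= 0.0:
        raise ValueError(f"kernel support radius h must be positive, got {h!r}")
    return h


def w_poly6(x, h: float):
    """Poly6 density kernel ``315/(64 pi h^9) (h^2 - x^2)^3`` on ``0 <= x <= h``.

    Parameters
    ----------
    x : float or ndarray
        Distance(s); negative values are treated as ``|x|``.
    h : float
        Support radius (m).

    Returns
    -------
    float or ndarray
        Kernel weight in m^-3; zero outside the support.
    """
    h = _check_h(h)
    x = np.abs(np.asarray(x, dtype=float))
    coef = 315.0 / (64.0 * np.pi * h**9)
    w = np.where(x <= h, coef * np.maximum(h * h - x * x, 0.0) ** 3, 0.0)
    return w if w.ndim else float(w)


def spiky_radial_derivative(x, h: float):
    """Radial derivative ``W'(x) = -45/(pi h^6) (h - x)^2`` of the spiky kernel.

    This is the scalar factor of the spiky gradient; it is what a directional
    derivative of the kernel along any axis is built from.
    """
    h = _check_h(h)
    x = np.abs(np.asarray(x, dtype=float))
    coef = -45.0 / (np.pi * h**6)
    d = np.where(x <= h, coef * np.maximum(h - x, 0.0) ** 2, 0.0)
    return d if d.ndim else float(d)


def grad_spiky(r_vec, h: float):
    """Spiky kernel gradient ``-45/(pi h^6) (h - |r|)^2 r_hat``.

    Parameters
    ----------
    r_vec : array_like, shape (3,) or (N, 3)
        Displacement vector(s) ``x_i - x_j``.
    h : float
        Support radius (m).

    Returns
    -------
    ndarray
        Gradient vector(s) in m^-4. The zero vector is returned at
        ``r = 0`` (the symmetric limit: a particle exerts no pressure
        force on itself) and outside the support.
    """
    h = _check_h(h)
    r = np.asarray(r_vec, dtype=float)
    single = r.ndim == 1
    r = np.atleast_2d(r)
    dist = np.linalg.norm(r, axis=1)
    coef = -45.0 / (np.pi * h**6)
    mag = np.where((dist > 0.0) & (dist <= h), coef * (h - dist) ** 2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dist[:, None] > 0.0, r / np.where(dist[:, None] > 0.0, dist[:, None], 1.0), 0.0)
    out = mag[:, None] * unit
    return out[0] if single else out


def lap_viscosity(x, h: float):
    """Viscosity kernel Laplacian ``45/(pi h^6) (h - x)`` on ``0 <= x <= h``.

    Non-negative on the support and monotone decreasing in ``x``, so
    viscous forces always act to damp relative velocities.
    """
    h = _check_h(h)
    x = np.abs(np.asarray(x, dtype=float))
    w = np.where(x <= h, 45.0 / (np.pi * h**6) * np.maximum(h - x, 0.0), 0.0)
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class KernelSet:
    """The smoothing kernels bound to one support radius ``h`` (m)."""

    h: float

    def __post_init__(self) -> None:
        _check_h(self.h)

    def poly6(self, x):
        return w_poly6(x, self.h)

    def grad_spiky(self, r_vec):
        return grad_spiky(r_vec, self.h)

    def spiky_radial_derivative(self, x):
        return spiky_radial_derivative(x, self.h)

    def lap_viscosity(self, x):
        return lap_viscosity(x, self.h)
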