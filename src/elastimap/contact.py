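"""Elastic contact models for a rigid sphere indenting a soft half-space.

Two closed-form models relate indentation depth ``delta`` to force ``F``
for a rigid spherical probe of radius ``R`` pressed into an elastic
half-space characterised by its reduced apparent elastic modulus
``K = E / (1 - nu**2)`` (Pa). ``K`` is used throughout instead of the
Young's modulus so that no Poisson's-ratio assumption is baked in.

* Hertz (paraboloid approximation, accurate for ``delta/R < 1/3``)::

      F = (4/3) * K * sqrt(R) * delta**1.5

* Sneddon (exact rigid sphere, valid to deep indentation), parametrised
  by the contact radius ``a``::

      delta(a) = (a/2) * ln((R + a) / (R - a))
      F(a)     = K * [ ((a**2 + R**2)/2) * ln((R + a)/(R - a)) - a*R ]

All quantities are SI (m, N, Pa). Unit conversion happens at I/O
boundaries, never here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Indenter",
    "ElasticHalfSpace",
    "SneddonSolution",
    "hertz_force",
    "hertz_depth",
    "hertz_stiffness",
    "sneddon_contact_radius",
    "sneddon_depth_from_radius",
    "sneddon_force",
    "sneddon_depth",
    "model_force",
    "model_depth",
    "unit_force_shape",
    "HERTZ_VALIDITY_RATIO",
]

#: delta/R threshold below which the paraboloid (Hertz) geometry is
#: conventionally considered interchangeable with the true sphere.
HERTZ_VALIDITY_RATIO = 1.0 / 3.0

#: default probe radius used throughout the study protocol: a 44.65 um
#: polystyrene bead glued to a tipless cantilever.
DEFAULT_BEAD_RADIUS = 44.65e-6

# guard fraction keeping the contact radius away from the log singularity a = R
_RADIUS_GUARD = 1e-9


@dataclass(frozen=True)
class Indenter:
    """Rigid spherical probe of radius ``radius`` (m)."""

    radius: float = DEFAULT_BEAD_RADIUS
    shape: str = "sphere"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"indenter radius must be positive, got {self.radius}")
        if self.shape != "sphere":
            raise ValueError(f"unsupported indenter shape {self.shape!r}")


@dataclass(frozen=True)
class ElasticHalfSpace:
    """Sample model: an elastic half-space with reduced modulus ``K`` (Pa)."""

    K: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"reduced modulus K must be positive, got {self.K}")


@dataclass(frozen=True)
class SneddonSolution:
    """One consistent (contact radius, depth, force) triple of the sphere model."""

    contact_radius: float
    indentation: float
    force: float


def _check_depth(depth, radius: float):
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation depth must be non-negative")
    if np.any(d >= radius):
        raise ValueError(
            f"indentation depth {np.max(d):.3g} m reaches the probe radius "
            f"{radius:.3g} m; the half-space sphere solutions do not extrapolate there"
        )
    return d


def hertz_force(half_space: ElasticHalfSpace, indenter: Indenter, depth):
    """Hertz force F = (4/3) K sqrt(R) delta^{3/2} at indentation ``depth`` (m)."""
    d = _check_depth(depth, indenter.radius)
    return (4.0 / 3.0) * half_space.K * np.sqrt(indenter.radius) * d ** 1.5


def hertz_depth(half_space: ElasticHalfSpace, indenter: Indenter, force):
    """Closed-form inverse of :func:`hertz_force`: depth producing ``force`` (N)."""
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    return (3.0 * f / (4.0 * half_space.K * np.sqrt(indenter.radius))) ** (2.0 / 3.0)


def hertz_stiffness(half_space: ElasticHalfSpace, indenter: Indenter, depth):
    """Analytic tangent stiffness dF/ddelta = 2 K sqrt(R delta) (N/m)."""
    d = _check_depth(depth, indenter.radius)
    return 2.0 * half_space.K * np.sqrt(indenter.radius * d)


def sneddon_depth_from_radius(indenter: Indenter, contact_radius):
    """Forward relation delta(a) = (a/2) ln((R+a)/(R-a)) of the sphere solution."""
    a = np.asarray(contact_radius, dtype=float)
    R = indenter.radius
    if np.any(a < 0) or np.any(a >= R):
        raise ValueError("contact radius must lie in [0, R)")
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(a > 0, 0.5 * a * np.log((R + a) / (R - a)), 0.0)
    return delta


def sneddon_contact_radius(indenter: Indenter, depth: float, tol: float = 1e-12) -> float:
    """Invert delta(a) for the contact radius by bracketed root-finding.

    The relation is strictly increasing on ``a`` in ``[0, R)`` so the root is
    unique; Brent's method on ``[0, (1 - 1e-9) R]`` guarantees convergence
    without derivatives while staying clear of the logarithmic singularity at
    ``a = R``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    depth = float(depth)
    R = indenter.radius
    _check_depth(depth, R)
    if depth == 0.0:
        return 0.0
    hi = (1.0 - _RADIUS_GUARD) * R

    def residual(a: float) -> float:
        return 0.5 * a * np.log((R + a) / (R - a)) - depth

    if residual(hi) < 0:
        raise RuntimeError(
            f"Sneddon contact-radius bracket [0, {hi:.6g}] does not contain the "
            f"root for depth {depth:.6g} m (residual at bracket end {residual(hi):.3g})"
        )
    try:
        # xtol is absolute: keep it far below the ~1e-5 m radius scale so the
        # relative tolerance governs convergence
        return float(brentq(residual, 0.0, hi, xtol=1e-18, rtol=tol, maxiter=200))
    except RuntimeError as exc:  # pragma: no cover - brentq rarely fails in bracket
        raise RuntimeError(
            f"Sneddon inversion did not converge for depth {depth:.6g} m "
            f"within bracket [0, {hi:.6g}]: {exc}"
        ) from exc


def _sneddon_force_from_radius(K: float, R: float, a):
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(
            a > 0,
            K * (0.5 * (a ** 2 + R ** 2) * np.log((R + a) / (R - a)) - a * R),
            0.0,
        )
    return F


def sneddon_force(half_space: ElasticHalfSpace, indenter: Indenter, depth):
    """Sneddon sphere force at indentation ``depth`` (m); scalar or array."""
    d = _check_depth(depth, indenter.radius)
    if d.ndim == 0:
        a = sneddon_contact_radius(indenter, float(d))
        return float(_sneddon_force_from_radius(half_space.K, indenter.radius, a))
    a = np.array([sneddon_contact_radius(indenter, float(x)) for x in d.ravel()])
    return _sneddon_force_from_radius(half_space.K, indenter.radius, a).reshape(d.shape)


def sneddon_depth(half_space: ElasticHalfSpace, indenter: Indenter, force: float,
                  tol: float = 1e-12) -> float:
    """Invert the Sneddon force law for depth via root-finding on ``a``.

    Solves F(a) = force for the contact radius, then maps back to depth with
    the closed-form delta(a); both legs are monotone so the answer is unique.
    """
    force = float(force)
    if force < 0:
        raise ValueError("force must be non-negative")
    if force == 0.0:
        return 0.0
    K, R = half_space.K, indenter.radius
    hi = (1.0 - _RADIUS_GUARD) * R

    def residual(a: float) -> float:
        return float(_sneddon_force_from_radius(K, R, a)) - force

    if residual(hi) < 0:
        raise RuntimeError(
            f"force {force:.6g} N is not reachable below the probe radius"
        )
    a = float(brentq(residual, 0.0, hi, xtol=1e-18, rtol=tol, maxiter=200))
    return float(sneddon_depth_from_radius(Indenter(R), a))


def unit_force_shape(model: str, indenter: Indenter, depth, n_grid: int = 4096):
    """Force at K = 1 Pa evaluated on ``depth``: the linear-in-K shape function.

    Least-squares modulus fits use ``F = K * g(delta)``; this returns
    ``g``. For Hertz the shape is closed form. For Sneddon it is evaluated
    through a dense monotone a-grid interpolant of the exact (delta(a), F(a))
    parametrisation, which avoids per-sample root-finding inside batch fits.
    """
    d = _check_depth(depth, indenter.radius)
    R = indenter.radius
    if model == "hertz":
        return (4.0 / 3.0) * np.sqrt(R) * d ** 1.5
    if model == "sneddon":
        dmax = float(np.max(d, initial=0.0))
        if dmax == 0.0:
            return np.zeros_like(d)
        a_hi = sneddon_contact_radius(Indenter(R), dmax)
        a_grid = np.linspace(0.0, min(a_hi * 1.001, (1 - _RADIUS_GUARD) * R), n_grid)
        d_grid = sneddon_depth_from_radius(Indenter(R), a_grid)
        f_grid = _sneddon_force_from_radius(1.0, R, a_grid)
        return np.interp(d, d_grid, f_grid)
    raise ValueError(f"unknown contact model {model!r}; expected 'hertz' or 'sneddon'")


def model_force(model: str, half_space: ElasticHalfSpace, indenter: Indenter, depth):
    """Dispatch to the forward model named by ``model`` ('hertz' or 'sneddon')."""
    if model == "hertz":
        return hertz_force(half_space, indenter, depth)
    if model == "sneddon":
        return sneddon_force(half_space, indenter, depth)
    raise ValueError(f"unknown contact model {model!r}")


def model_depth(model: str, half_space: ElasticHalfSpace, indenter: Indenter, force):
    """Dispatch to the inverse model named by ``model``."""
    if model == "hertz":
        return hertz_depth(half_space, indenter, force)
    if model == "sneddon":
        return sneddon_depth(half_space, indenter, force)
    raise ValueError(f"unknown contact model {model!r}")
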