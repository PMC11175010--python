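"""Scattering phase-function models.

A phase function here is the probability density of the cosine of the polar
scattering angle, ``u = cos(theta)``, normalized so that

    integral_{-1}^{1} p(u) du = 1 .

The azimuthal angle is always drawn uniformly on ``[0, 2*pi)`` by the
transport code, so the models below are one-dimensional densities in ``u``.

Available models
----------------
* :class:`HenyeyGreenstein` -- the classic one-parameter forward-peaked model,
  parameterized by the anisotropy factor ``g`` (its mean cosine).
* :class:`ReynoldsMcCormick` -- the two-parameter Gegenbauer-kernel
  generalization with shape ``gs`` and exponent ``alpha``; reduces to
  Henyey-Greenstein at ``alpha = 1/2``.
* :class:`DoubleHenyeyGreenstein` -- mixture ``beta*HG(g1) + (1-beta)*HG(g2)``.
* :class:`TabulatedPhase` -- piecewise-linear density on a ``cos(theta)`` grid
  (e.g. from Mie theory), sampled by exact inversion of its CDF.
* :class:`SplinePhase` -- clamped cubic spline through user knots, clipped at
  zero, renormalized and sampled through a dense tabulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import CubicSpline

__all__ = [
    "PhaseFunctionError",
    "PhaseTableError",
    "hg_pdf",
    "hg_sample",
    "rm_pdf",
    "tabulated_sample",
    "HenyeyGreenstein",
    "ReynoldsMcCormick",
    "DoubleHenyeyGreenstein",
    "TabulatedPhase",
    "SplinePhase",
    "load_tabulated",
]

# Fixed-order Gauss-Legendre rule used to normalize models that have no
# closed-form constant (Reynolds-McCormick, splines).  4096 points is far
# beyond what the smooth integrands need; the cost is paid once per object.
_GL_NODES, _GL_WEIGHTS = leggauss(4096)

#: grid resolution used when a model is converted to an inverse-CDF table
_TABLE_REFINEMENT = 4096


class PhaseFunctionError(ValueError):
    """Invalid phase-function parameters."""


class PhaseTableError(ValueError):
    """Malformed tabulated phase function (non-monotone grid, bad density...)."""


# ---------------------------------------------------------------------------
# Henyey-Greenstein primitives (module-level functions: these are also used by
# the perturbation weights, which take explicit g values).
# ---------------------------------------------------------------------------

def hg_pdf(g: float, u):
    """Henyey-Greenstein density per unit ``cos(theta)``.

    ``p(u) = (1 - g^2) / (2 * (1 + g^2 - 2 g u)^{3/2})``, normalized over
    ``u in [-1, 1]`` with mean cosine exactly ``g``.
    """
    g = float(g)
    if not -1.0 < g < 1.0:
        raise PhaseFunctionError(f"anisotropy g must lie in (-1, 1), got {g}")
    u = np.asarray(u, dtype=float)
    return (1.0 - g * g) / (2.0 * (1.0 + g * g - 2.0 * g * u) ** 1.5)


def hg_sample(g: float, r):
    """Draw ``cos(theta)`` from Henyey-Greenstein by closed-form inverse CDF.

    ``r`` is one or more uniform(0,1) variates.  For ``g = 0`` the draw is
    ``2 r - 1`` (isotropic).
    """
    g = float(g)
    if not -1.0 < g < 1.0:
        raise PhaseFunctionError(f"anisotropy g must lie in (-1, 1), got {g}")
    r = np.asarray(r, dtype=float)
    if abs(g) < 1e-7:
        # the closed form below is a 0/0 expression as g -> 0; the isotropic
        # draw is exact to O(g) and numerically stable
        return 2.0 * r - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * r)
    u = (1.0 + g * g - frac * frac) / (2.0 * g)
    return np.clip(u, -1.0, 1.0)


def rm_pdf(gs: float, alpha: float, u):
    """Reynolds-McCormick (Gegenbauer-kernel) density per unit ``cos(theta)``.

    Proportional to ``(1 + gs^2 - 2 gs u)^{-(alpha+1)}`` with the constant
    obtained numerically (fixed 4096-point Gauss-Legendre rule).  At
    ``alpha = 1/2`` the density coincides with Henyey-Greenstein of ``g = gs``.
    """
    return ReynoldsMcCormick(gs, alpha).pdf(u)


def tabulated_sample(u_grid, density, r):
    """Inverse-CDF draw from a tabulated (cos(theta), density) grid."""
    return TabulatedPhase(u_grid, density).sample_from_uniform(r)


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------

class _PhaseBase:
    """Shared interface: ``pdf(u)``, ``sample_from_uniform(r)``, ``sample``."""

    def pdf(self, u):  # pragma: no cover - abstract
        raise NotImplementedError

    def sample_from_uniform(self, r):  # pragma: no cover - abstract
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, n: int):
        return self.sample_from_uniform(rng.random(n))

    def mean_cosine(self) -> float:
        u = _GL_NODES
        return float(np.sum(_GL_WEIGHTS * u * self.pdf(u)))

    def normalization(self) -> float:
        """Numeric integral of the density over [-1, 1] (should be 1)."""
        return float(np.sum(_GL_WEIGHTS * self.pdf(_GL_NODES)))

    def tabulate(self, n: int = _TABLE_REFINEMENT) -> "TabulatedPhase":
        u = np.linspace(-1.0, 1.0, n + 1)
        return TabulatedPhase(u, self.pdf(u))


@dataclass(frozen=True)
class HenyeyGreenstein(_PhaseBase):
    g: float

    def __post_init__(self):
        if not -1.0 < self.g < 1.0:
            raise PhaseFunctionError(f"anisotropy g must lie in (-1, 1), got {self.g}")

    def pdf(self, u):
        return hg_pdf(self.g, u)

    def sample_from_uniform(self, r):
        return hg_sample(self.g, r)

    def mean_cosine(self) -> float:
        return self.g


class ReynoldsMcCormick(_PhaseBase):
    """Gegenbauer-kernel phase function with shape ``gs`` and exponent ``alpha``."""

    def __init__(self, gs: float, alpha: float):
        gs, alpha = float(gs), float(alpha)
        if not -1.0 < gs < 1.0:
            raise PhaseFunctionError(f"gs must lie in (-1, 1), got {gs}")
        if not alpha > -0.5:
            raise PhaseFunctionError(f"alpha must exceed -1/2, got {alpha}")
        self.gs = gs
        self.alpha = alpha
        raw = (1.0 + gs * gs - 2.0 * gs * _GL_NODES) ** (-(alpha + 1.0))
        self._norm = 1.0 / float(np.sum(_GL_WEIGHTS * raw))
        self._sampler = None

    def pdf(self, u):
        u = np.asarray(u, dtype=float)
        return self._norm * (1.0 + self.gs * self.gs - 2.0 * self.gs * u) ** (
            -(self.alpha + 1.0)
        )

    def sample_from_uniform(self, r):
        if self._sampler is None:
            self._sampler = self.tabulate()
        return self._sampler.sample_from_uniform(r)


class DoubleHenyeyGreenstein(_PhaseBase):
    """Mixture ``beta * HG(g1) + (1 - beta) * HG(g2)``.

    Typically ``g1 >= 0`` models the forward lobe and ``g2 <= 0`` a backward
    component; the mean cosine is ``beta*g1 + (1-beta)*g2``.
    """

    def __init__(self, g1: float, g2: float, beta: float):
        if not 0.0 <= beta <= 1.0:
            raise PhaseFunctionError(f"mixing weight beta must lie in [0, 1], got {beta}")
        self.h1 = HenyeyGreenstein(g1)
        self.h2 = HenyeyGreenstein(g2)
        self.beta = float(beta)

    def pdf(self, u):
        return self.beta * self.h1.pdf(u) + (1.0 - self.beta) * self.h2.pdf(u)

    def sample_from_uniform(self, r):
        # branch on the mixture weight, then reuse the remaining uniformity of
        # r within each branch so a single variate suffices
        r = np.asarray(r, dtype=float)
        pick1 = r < self.beta
        out = np.empty_like(r)
        if self.beta > 0.0:
            out[pick1] = self.h1.sample_from_uniform(r[pick1] / self.beta)
        if self.beta < 1.0:
            out[~pick1] = self.h2.sample_from_uniform(
                (r[~pick1] - self.beta) / (1.0 - self.beta)
            )
        return out

    def mean_cosine(self) -> float:
        return self.beta * self.h1.g + (1.0 - self.beta) * self.h2.g


class TabulatedPhase(_PhaseBase):
    """Piecewise-linear density on a strictly increasing ``cos(theta)`` grid.

    The grid lives in ``cos(theta)`` so the CDF is piecewise quadratic and can
    be inverted exactly cell by cell; sample moments therefore converge to the
    table's moments without interpolation bias.
    """

    def __init__(self, u_grid, density):
        u = np.asarray(u_grid, dtype=float)
        p = np.asarray(density, dtype=float)
        if u.ndim != 1 or u.size < 3:
            raise PhaseTableError("phase table needs at least 3 grid points")
        if p.shape != u.shape:
            raise PhaseTableError("grid and density shapes differ")
        if np.any(np.diff(u) <= 0.0):
            raise PhaseTableError("cos(theta) grid must be strictly increasing")
        if np.any(p < 0.0) or np.any(~np.isfinite(p)):
            raise PhaseTableError("densities must be finite and non-negative")
        cell = 0.5 * (p[1:] + p[:-1]) * np.diff(u)
        total = cell.sum()
        if total <= 0.0:
            raise PhaseTableError("density integrates to zero")
        self.u = u
        self.p = p / total
        self.cdf = np.concatenate(([0.0], np.cumsum(cell / total)))
        self.cdf[-1] = 1.0

    def pdf(self, u):
        u = np.asarray(u, dtype=float)
        out = np.interp(u, self.u, self.p)
        out = np.where((u < self.u[0]) | (u > self.u[-1]), 0.0, out)
        return out

    def sample_from_uniform(self, r):
        r = np.asarray(r, dtype=float)
        i = np.clip(np.searchsorted(self.cdf, r, side="right") - 1, 0, self.u.size - 2)
        u0, u1 = self.u[i], self.u[i + 1]
        p0, p1 = self.p[i], self.p[i + 1]
        du = u1 - u0
        y = r - self.cdf[i]
        # CDF within the cell: y = p0*s + (p1-p0)/(2*du) * s^2, s = u-u0
        a = 0.5 * (p1 - p0) / du
        disc = np.maximum(p0 * p0 + 4.0 * a * y, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            s_quad = (np.sqrt(disc) - p0) / (2.0 * a)
            s_lin = y / p0
        flat = np.abs(a) * du < 1e-14 * np.maximum(p0, 1e-300)
        s = np.where(flat, s_lin, s_quad)
        s = np.where((p0 <= 0.0) & flat, 0.0, s)
        return np.clip(u0 + s, u0, u1)

    def inverse_cdf_table(self, n: int = _TABLE_REFINEMENT) -> np.ndarray:
        """``u`` values at ``n`` equispaced CDF levels (for fast kernels)."""
        levels = np.linspace(0.0, 1.0, n)
        return np.asarray(self.sample_from_uniform(levels), dtype=float)


class SplinePhase(_PhaseBase):
    """Clamped cubic spline through knots in ``cos(theta)``, clipped at zero and
    renormalized; sampling goes through a dense tabulation."""

    def __init__(self, u_knots, p_knots, refinement: int = _TABLE_REFINEMENT):
        u = np.asarray(u_knots, dtype=float)
        p = np.asarray(p_knots, dtype=float)
        if u.size < 4:
            raise PhaseTableError("spline phase needs at least 4 knots")
        if np.any(np.diff(u) <= 0.0):
            raise PhaseTableError("spline knots must be strictly increasing")
        spline = CubicSpline(u, p, bc_type="clamped")
        grid = np.linspace(u[0], u[-1], refinement + 1)
        vals = np.clip(spline(grid), 0.0, None)
        self._table = TabulatedPhase(grid, vals)

    def pdf(self, u):
        return self._table.pdf(u)

    def sample_from_uniform(self, r):
        return self._table.sample_from_uniform(r)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_tabulated(path) -> TabulatedPhase:
    """Read a two-column ``angle_deg density`` text file ('#' comments).

    The density column is interpreted as proportional to the phase function
    per unit solid angle (the usual form of Mie tables); conversion to the
    internal per-``cos(theta)`` density is a constant factor absorbed by the
    normalization.  Rows may come in increasing or decreasing angle order.
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise PhaseTableError(f"{path}: expected two columns 'angle_deg density'")
    theta = np.radians(data[:, 0])
    if np.any(theta < -1e-12) or np.any(theta > math.pi + 1e-12):
        raise PhaseTableError(f"{path}: angles must lie in [0, 180] degrees")
    u = np.cos(theta)
    order = np.argsort(u)
    u, dens = u[order], data[order, 1]
    if np.any(np.diff(u) <= 0.0):
        raise PhaseTableError(f"{path}: duplicate angles in table")
    return TabulatedPhase(u, dens)
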