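"""Radiative transport inside the layered sample.

The sample is a stack of right-cylindrical layers on the z-axis (typically
glass / scattering medium / glass, held in a cutout of radius 10.5 mm whose
surround is a perfect absorber, emulating the black-coated holder).  Photons
propagate by Beer-Lambert free-path sampling against the scattering
coefficient alone, with per-segment absorption survival ``exp(-mu_a l)`` --
the unique scheme under which the multiplicative perturbation weights for
``mu_a`` and ``mu_s`` recorded along each path are exact.  Boundary crossings
draw Fresnel reflection/transmission and refract by Snell's law; leaving the
stack hands the photon to detection.

This module holds the domain description plus a plain-numpy reference
propagator used for validation; production runs go through the numba kernel
in :mod:`goniotwin._kernels` (same physics, cross-checked in tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .optics import Bundle, rotate_directions
from .phasefunc import HenyeyGreenstein, _PhaseBase

__all__ = [
    "Material",
    "Layer",
    "SampleDomain",
    "cuvette",
    "single_slab",
    "sample_free_path",
    "absorption_survival",
    "boundary_interact",
    "PathStats",
    "propagate_reference",
]

#: holder cutout radius (mm): 21 mm diameter opening
DEFAULT_CUTOUT_RADIUS_MM = 10.5

#: runaway guard: maximum interaction events for one photon
MAX_EVENTS = 10_000_000


@dataclass(frozen=True)
class Material:
    """Optical material: mu_a, mu_s (mm^-1), refractive index, phase function."""

    mua: float
    mus: float
    n: float
    phase: Optional[_PhaseBase] = None

    def __post_init__(self):
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if self.n <= 0:
            raise ValueError("refractive index must be positive")
        if self.mus > 0 and self.phase is None:
            raise ValueError("a scattering material needs a phase function")


@dataclass(frozen=True)
class Layer:
    thickness_mm: float
    material: Material

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ValueError("layer thickness must be positive")


@dataclass(frozen=True)
class SampleDomain:
    """Ordered layer stack with the front surface at z = 0 (+z toward 0 deg).

    ``perturbable`` is the index of the layer whose (mu_a, mu_s, g) the
    perturbation machinery tracks -- by convention the scattering medium; the
    glass windows stay fixed.
    """

    layers: tuple
    cutout_radius_mm: float = DEFAULT_CUTOUT_RADIUS_MM
    perturbable: int = 0
    n_outside: float = 1.0

    def __post_init__(self):
        if not self.layers:
            raise ValueError("need at least one layer")
        if not 0 <= self.perturbable < len(self.layers):
            raise ValueError("perturbable layer index out of range")

    @property
    def z_edges(self) -> np.ndarray:
        t = np.array([lay.thickness_mm for lay in self.layers])
        return np.concatenate(([0.0], np.cumsum(t)))

    @property
    def medium(self) -> Material:
        return self.layers[self.perturbable].material


def cuvette(
    mua: float,
    mus: float,
    g: float,
    n_med: float = 1.33,
    thickness_mm: float = 2.0,
    glass_n: float = 1.51,
    glass_thickness_mm: float = 1.0,
    phase: Optional[_PhaseBase] = None,
) -> SampleDomain:
    """Two glass windows around a scattering medium (the liquid-sample holder)."""
    glass = Material(0.0, 0.0, glass_n)
    med = Material(mua, mus, n_med, phase if phase is not None else HenyeyGreenstein(g))
    return SampleDomain(
        (
            Layer(glass_thickness_mm, glass),
            Layer(thickness_mm, med),
            Layer(glass_thickness_mm, glass),
        ),
        perturbable=1,
    )


def single_slab(
    mua: float,
    mus: float,
    g: float,
    n_med: float = 1.0,
    thickness_mm: float = 2.0,
    phase: Optional[_PhaseBase] = None,
) -> SampleDomain:
    """One scattering layer with no windows (used by the optical-depth sweep)."""
    med = Material(mua, mus, n_med, phase if phase is not None else HenyeyGreenstein(g))
    return SampleDomain((Layer(thickness_mm, med),), perturbable=0)


# ---------------------------------------------------------------------------
# Elementary sampling operations
# ---------------------------------------------------------------------------

def sample_free_path(mus: float, r):
    """Beer-Lambert free path ``-ln(1-r)/mu_s``; infinite for mu_s = 0.

    The complement ``1-r`` keeps ``r = 0`` harmless (it maps to path 0 with
    probability measure zero rather than to a log of zero).
    """
    if mus < 0:
        raise ValueError("mu_s must be non-negative")
    r = np.asarray(r, dtype=float)
    if mus == 0.0:
        return np.full_like(r, np.inf)
    return -np.log1p(-r) / mus


def absorption_survival(length, mua: float, r):
    """Per-segment survival draw: survive iff ``r < exp(-mu_a * l)``."""
    if mua < 0:
        raise ValueError("mu_a must be non-negative")
    length = np.asarray(length, dtype=float)
    r = np.asarray(r, dtype=float)
    return r < np.exp(-mua * length)


def boundary_interact(bundle: Bundle, n_from, n_to, rng: np.random.Generator):
    """Fresnel draw at a z-plane interface for every alive photon.

    Transmitted photons refract by Snell (transverse direction components
    scale by ``n_from/n_to``); reflected photons flip ``uz``.  Returns a
    boolean array marking the transmitted photons.
    """
    from .optics import fresnel as _fres

    m = bundle.alive
    idx = np.flatnonzero(m)
    cos_i = np.abs(bundle.uz[idx])
    n1 = np.broadcast_to(np.asarray(n_from, dtype=float), idx.shape)
    n2 = np.broadcast_to(np.asarray(n_to, dtype=float), idx.shape)
    r_ref, cos_t = _fres(n1, n2, cos_i)
    r_ref = np.atleast_1d(r_ref)
    cos_t = np.atleast_1d(cos_t)
    refl = rng.random(idx.size) < r_ref
    rf = idx[refl]
    bundle.uz[rf] *= -1.0
    tr = idx[~refl]
    eta = (n1 / n2)[~refl]
    bundle.ux[tr] *= eta
    bundle.uy[tr] *= eta
    bundle.uz[tr] = np.sign(bundle.uz[tr]) * cos_t[~refl]
    out = np.zeros(bundle.x.size, dtype=bool)
    out[tr] = True
    return out


@dataclass
class PathStats:
    """Per-photon path statistics feeding the perturbation weights."""

    l_mm: np.ndarray          # path length inside the perturbable medium
    n_scat: np.ndarray        # scattering events inside the perturbable medium
    log_wg: np.ndarray        # accumulated log HG density ratio (for delta_g)
    exit_xyz: Optional[np.ndarray] = None  # (n, 3) exit positions, NaN if not exited


# ---------------------------------------------------------------------------
# Reference propagator (plain numpy, used for validation and small studies)
# ---------------------------------------------------------------------------

def propagate_reference(
    bundle: Bundle,
    domain: SampleDomain,
    rng: np.random.Generator,
    delta_g: float = 0.0,
    max_events: int = 100_000,
):
    """Propagate a bundle through the layer stack; returns exit data.

    Photons must start on the front surface (z = 0) heading into +z inside
    the outside medium.  Returns ``(exit_theta_deg, stats, counters)`` where
    ``exit_theta_deg`` is NaN for photons that did not exit.

    This is the slow readable implementation: one python loop per interaction
    round over the whole bundle.  Use the numba kernel for big budgets.
    """
    n = bundle.x.size
    z_edges = domain.z_edges
    n_layers = len(domain.layers)
    mua = np.array([lay.material.mua for lay in domain.layers])
    mus = np.array([lay.material.mus for lay in domain.layers])
    n_idx = np.array([lay.material.n for lay in domain.layers])
    phases = [lay.material.phase for lay in domain.layers]
    g_pert = None
    med = domain.medium
    if isinstance(med.phase, HenyeyGreenstein):
        g_pert = med.phase.g

    x, y, z = bundle.x.copy(), bundle.y.copy(), bundle.z.copy()
    ux, uy, uz = bundle.ux.copy(), bundle.uy.copy(), bundle.uz.copy()
    alive = bundle.alive.copy()
    layer = np.full(n, -1, dtype=int)  # -1: outside in front
    l_med = np.zeros(n)
    n_scat = np.zeros(n, dtype=np.int64)
    log_wg = np.zeros(n)
    theta_exit = np.full(n, np.nan)
    counters = {"absorbed": 0, "side_wall": 0, "exited": 0, "runaway": 0}

    # entry interaction at z = 0: air -> layer 0
    m = alive & (uz > 0)
    from .optics import fresnel as _fres
    r_ref, cos_t = _fres(domain.n_outside, n_idx[0], uz[m])
    refl = rng.random(m.sum()) < r_ref
    idx = np.flatnonzero(m)
    back = idx[refl]
    uz[back] *= -1.0
    theta_exit[back] = np.degrees(np.arccos(np.clip(uz[back], -1, 1)))
    counters["exited"] += back.size
    alive[back] = False
    fwd = idx[~refl]
    eta = domain.n_outside / n_idx[0]
    ux[fwd] *= eta
    uy[fwd] *= eta
    uz[fwd] = cos_t[~refl]
    layer[fwd] = 0
    dead = np.flatnonzero(bundle.alive & ~(uz > 0) & (layer == -1))
    alive[dead] = False  # photons that never entered

    for _ in range(max_events):
        act = np.flatnonzero(alive)
        if act.size == 0:
            break
        k = layer[act]
        mus_k = mus[k]
        mua_k = mua[k]
        with np.errstate(divide="ignore"):
            s = np.where(mus_k > 0, -np.log1p(-rng.random(act.size)) / np.where(mus_k > 0, mus_k, 1.0), np.inf)
        z_lo = z_edges[k]
        z_hi = z_edges[k + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            db = np.where(uz[act] > 0, (z_hi - z[act]) / uz[act],
                          np.where(uz[act] < 0, (z_lo - z[act]) / uz[act], np.inf))
        step = np.minimum(s, db)
        x_new = x[act] + step * ux[act]
        y_new = y[act] + step * uy[act]
        outside = x_new**2 + y_new**2 > domain.cutout_radius_mm**2
        wall = act[outside]
        alive[wall] = False
        counters["side_wall"] += wall.size
        act = act[~outside]
        if act.size == 0:
            continue
        step = step[~outside]
        s = s[~outside]
        db = db[~outside]
        k = k[~outside]
        x[act] += step * ux[act]
        y[act] += step * uy[act]
        z[act] += step * uz[act]
        # segment absorption
        mua_k = mua[k]
        seg = mua_k > 0
        if np.any(seg):
            die = seg & (rng.random(act.size) >= np.exp(-mua_k * step))
            dead = act[die]
            alive[dead] = False
            counters["absorbed"] += dead.size
            keep = ~die
            act, step, s, db, k = act[keep], step[keep], s[keep], db[keep], k[keep]
        is_pert = k == domain.perturbable
        l_med[act[is_pert]] += step[is_pert]
        at_boundary = db <= s
        # ---- boundary crossing ----
        bnd = act[at_boundary]
        if bnd.size:
            kb = k[at_boundary]
            up = uz[bnd] > 0
            z[bnd] = np.where(up, z_edges[kb + 1], z_edges[kb])
            k_next = np.where(up, kb + 1, kb - 1)
            n1 = n_idx[kb]
            n2 = np.where((k_next >= 0) & (k_next < n_layers),
                          n_idx[np.clip(k_next, 0, n_layers - 1)], domain.n_outside)
            cos_i = np.abs(uz[bnd])
            r_ref, cos_t = _fres(n1, n2, cos_i)
            refl = rng.random(bnd.size) < r_ref
            uz[bnd[refl]] *= -1.0
            tr = bnd[~refl]
            if tr.size:
                eta = (n1 / n2)[~refl]
                ux[tr] *= eta
                uy[tr] *= eta
                uz[tr] = np.sign(uz[tr]) * cos_t[~refl]
                kn = k_next[~refl]
                exited = (kn < 0) | (kn >= n_layers)
                out = tr[exited]
                theta_exit[out] = np.degrees(np.arccos(np.clip(uz[out], -1, 1)))
                alive[out] = False
                counters["exited"] += out.size
                stay = tr[~exited]
                layer[stay] = kn[~exited]
        # ---- scattering ----
        sc = act[~at_boundary]
        if sc.size:
            ks = k[~at_boundary]
            u_new = np.empty(sc.size)
            for ki in np.unique(ks):
                pick = ks == ki
                u_new[pick] = phases[ki].sample(rng, int(pick.sum()))
            pert = ks == domain.perturbable
            n_scat[sc[pert]] += 1
            if delta_g and g_pert is not None and np.any(pert):
                from .phasefunc import hg_pdf
                g2 = g_pert * (1.0 + delta_g)
                lw = np.log(hg_pdf(g2, u_new[pert])) - np.log(hg_pdf(g_pert, u_new[pert]))
                log_wg[sc[pert]] += lw
            phi = 2.0 * np.pi * rng.random(sc.size)
            ux[sc], uy[sc], uz[sc] = rotate_directions(ux[sc], uy[sc], uz[sc], u_new, phi)
    else:
        counters["runaway"] = int(alive.sum())
        alive[:] = False

    exit_xyz = np.column_stack([x, y, z])
    exit_xyz[~np.isfinite(theta_exit)] = np.nan
    stats = PathStats(l_med, n_scat, log_wg, exit_xyz)
    return theta_exit, stats, counters
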