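"""Geometric photon tracing through the instrument's source/detector optics.

Photons travel in a right-handed frame with ``z`` along the incident beam and
``z = 0`` at the front sample surface; the fiber source sits at negative
``z``.  A :class:`Bundle` is a struct-of-arrays collection of rays that is
pushed through apertures and lens interfaces with vectorized numpy.  Lenses
are sequences of spherical (or plane) interfaces; at each interface the
unpolarized Fresnel reflectance decides stochastically between reflection and
Snell refraction, optionally overridden by a fixed anti-reflection coating
reflectance, and reflected rays may additionally be diffused by a small-angle
Reynolds-McCormick draw to emulate surface imperfections.

Every launched ray ends in exactly one bookkeeping category (passed,
discarded at an aperture, missed an interface, exited backward), which the
tests use for energy accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Union

import numpy as np

from .phasefunc import ReynoldsMcCormick

__all__ = [
    "Bundle",
    "SourceSpec",
    "ApertureSpec",
    "Interface",
    "LensSpec",
    "ConfigError",
    "fresnel",
    "sample_fiber_photons",
    "aperture_pass",
    "trace_lens",
    "build_source_train",
    "SourceTrain",
    "symmetric_biconvex",
    "rotate_directions",
]

# discard reason codes
ALIVE = 0
DISCARD_APERTURE = 1
DISCARD_BACKWARD = 2
DISCARD_MISS = 3
DISCARD_WRONG_WAY = 4


class ConfigError(ValueError):
    """Inconsistent optical-train configuration."""


@dataclass
class Bundle:
    """Struct-of-arrays photon bundle (positions mm, unit directions)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray
    status: np.ndarray  # int8 reason codes, 0 = alive

    @classmethod
    def empty(cls, n: int) -> "Bundle":
        z = np.zeros(n)
        return cls(z.copy(), z.copy(), z.copy(), z.copy(), z.copy(), np.ones(n), np.zeros(n, dtype=np.int8))

    @property
    def alive(self) -> np.ndarray:
        return self.status == ALIVE

    def renormalize(self) -> None:
        norm = np.sqrt(self.ux**2 + self.uy**2 + self.uz**2)
        self.ux /= norm
        self.uy /= norm
        self.uz /= norm


@dataclass(frozen=True)
class SourceSpec:
    """Multimode-fiber source: core radius, numerical aperture, axial position.

    ``angular_mode='uniform-angle'`` draws the polar angle uniformly on
    ``[0, arcsin(NA)]``; ``'uniform-solidangle'`` draws it uniformly in solid
    angle over the same cone.
    """

    fiber_radius_mm: float
    na: float
    z_mm: float
    angular_mode: str = "uniform-angle"

    def __post_init__(self):
        if self.fiber_radius_mm < 0.0:
            raise ConfigError("fiber radius must be >= 0")
        if not 0.0 < self.na < 1.0:
            raise ConfigError("numerical aperture must lie in (0, 1)")
        if self.angular_mode not in ("uniform-angle", "uniform-solidangle"):
            raise ConfigError(f"unknown angular mode {self.angular_mode!r}")


@dataclass(frozen=True)
class ApertureSpec:
    z_mm: float
    radius_mm: float

    def __post_init__(self):
        if self.radius_mm <= 0.0:
            raise ConfigError("aperture radius must be positive")


@dataclass(frozen=True)
class Interface:
    """One refracting surface of a lens.

    ``radius_mm`` is the signed radius of curvature (positive = center of
    curvature on the +z side of the vertex, ``inf`` = plane).  ``n_before`` /
    ``n_after`` are the indices on the -z / +z sides.  ``ar_reflectance``
    (if not None) replaces the Fresnel reflectance, modelling an AR coating
    as a fixed probability.  ``scatter_prob`` is the chance that a reflected
    ray is additionally diffused by an RM(gs, alpha) polar draw about the
    specular direction.
    """

    z_vertex_mm: float
    radius_mm: float
    semi_aperture_mm: float
    n_before: float
    n_after: float
    ar_reflectance: float | None = None
    scatter_prob: float = 0.0
    scatter_gs: float = 0.9
    scatter_alpha: float = 1.0

    def __post_init__(self):
        if self.semi_aperture_mm <= 0.0:
            raise ConfigError("semi-aperture must be positive")
        if self.ar_reflectance is not None and not 0.0 <= self.ar_reflectance <= 1.0:
            raise ConfigError("AR reflectance must lie in [0, 1]")
        if not 0.0 <= self.scatter_prob <= 1.0:
            raise ConfigError("scatter probability must lie in [0, 1]")


@dataclass(frozen=True)
class LensSpec:
    interfaces: tuple

    def __post_init__(self):
        zs = [i.z_vertex_mm for i in self.interfaces]
        if len(zs) < 1:
            raise ConfigError("lens needs at least one interface")
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ConfigError("lens interfaces must be ordered along +z")

    @property
    def z_entry(self) -> float:
        return self.interfaces[0].z_vertex_mm

    @property
    def z_exit(self) -> float:
        return self.interfaces[-1].z_vertex_mm


def symmetric_biconvex(
    focal_mm: float,
    thickness_mm: float = 5.0,
    n: float = 1.52,
    semi_aperture_mm: float = 12.7,
    z_center_mm: float = 0.0,
    n_outside: float = 1.0,
    ar_reflectance: float | None = 0.005,
    scatter_prob: float = 0.0,
    scatter_gs: float = 0.9,
    scatter_alpha: float = 1.0,
) -> LensSpec:
    """Thick symmetric biconvex singlet with the requested effective focal length.

    Stand-in prescription for commercial achromatic doublets whose internal
    construction is proprietary: |R| solves the thick-lens lensmaker equation
    ``1/f = (n-1) (2/R - (n-1) t / (n R^2))``.
    """
    nl, t, f = n, thickness_mm, focal_mm
    # quadratic in R: R^2/f - 2 (n-1) R + (n-1)^2 t / n = 0
    a, b, c = 1.0 / f, -2.0 * (nl - 1.0), (nl - 1.0) ** 2 * t / nl
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:
        raise ConfigError("no real biconvex solution for this focal length")
    r = (-b + math.sqrt(disc)) / (2.0 * a)
    half = 0.5 * t
    common = dict(
        semi_aperture_mm=semi_aperture_mm,
        ar_reflectance=ar_reflectance,
        scatter_prob=scatter_prob,
        scatter_gs=scatter_gs,
        scatter_alpha=scatter_alpha,
    )
    return LensSpec(
        (
            Interface(z_center_mm - half, r, n_before=n_outside, n_after=nl, **common),
            Interface(z_center_mm + half, -r, n_before=nl, n_after=n_outside, **common),
        )
    )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def fresnel(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance and transmitted cosine.

    Returns ``(R, cos_t)``; under total internal reflection ``R = 1`` and
    ``cos_t`` is reported as 0.  Inputs broadcast.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    cos_i = np.clip(np.asarray(cos_i, dtype=float), 0.0, 1.0)
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_i**2)
    tir = sin_t2 >= 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin_t2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
        rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    r = np.where(tir, 1.0, 0.5 * (rs + rp))
    cos_t = np.where(tir, 0.0, cos_t)
    if r.ndim == 0:
        return float(r), float(cos_t)
    return r, cos_t


def sample_fiber_photons(src: SourceSpec, rng: np.random.Generator, n: int) -> Bundle:
    """Launch ``n`` photons from the fiber face.

    Positions are uniform on the fiber disc; the polar angle is drawn per
    ``src.angular_mode`` within the NA cone (in air), azimuth uniform.
    """
    b = Bundle.empty(n)
    r = src.fiber_radius_mm * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    b.x = r * np.cos(phi)
    b.y = r * np.sin(phi)
    b.z = np.full(n, src.z_mm)
    theta_max = math.asin(src.na)
    if src.angular_mode == "uniform-angle":
        theta = theta_max * rng.random(n)
    else:  # uniform in solid angle over the cone
        cos_t = 1.0 - rng.random(n) * (1.0 - math.cos(theta_max))
        theta = np.arccos(cos_t)
    psi = 2.0 * np.pi * rng.random(n)
    st = np.sin(theta)
    b.ux = st * np.cos(psi)
    b.uy = st * np.sin(psi)
    b.uz = np.cos(theta)
    return b


def aperture_pass(bundle: Bundle, ap: ApertureSpec) -> Bundle:
    """Advance alive photons to the aperture plane; discard those outside.

    Photons moving away from the plane are discarded with a distinct reason
    code.  The boundary is inclusive: radial distance exactly equal to the
    open radius passes.
    """
    m = bundle.alive
    dz = ap.z_mm - bundle.z[m]
    approaching = dz * bundle.uz[m] > 0.0
    idx = np.flatnonzero(m)
    bundle.status[idx[~approaching]] = DISCARD_WRONG_WAY
    ok = idx[approaching]
    t = (ap.z_mm - bundle.z[ok]) / bundle.uz[ok]
    x = bundle.x[ok] + t * bundle.ux[ok]
    y = bundle.y[ok] + t * bundle.uy[ok]
    bundle.x[ok] = x
    bundle.y[ok] = y
    bundle.z[ok] = ap.z_mm
    outside = x**2 + y**2 > ap.radius_mm**2
    bundle.status[ok[outside]] = DISCARD_APERTURE
    return bundle


def rotate_directions(ux, uy, uz, cos_theta, phi):
    """Rotate unit vectors by polar angle ``theta`` (given its cosine) and
    azimuth ``phi`` about themselves (standard scattering rotation)."""
    ct = np.asarray(cos_theta, dtype=float)
    st = np.sqrt(np.clip(1.0 - ct * ct, 0.0, None))
    cp, sp = np.cos(phi), np.sin(phi)
    near_pole = np.abs(uz) > 1.0 - 1e-6
    denom = np.sqrt(np.clip(1.0 - uz * uz, 1e-30, None))
    nx = st * (ux * uz * cp - uy * sp) / denom + ux * ct
    ny = st * (uy * uz * cp + ux * sp) / denom + uy * ct
    nz = -st * cp * denom + uz * ct
    px = st * cp
    py = st * sp * np.sign(uz + (uz == 0.0))
    pz = ct * np.sign(uz + (uz == 0.0))
    nx = np.where(near_pole, px, nx)
    ny = np.where(near_pole, py, ny)
    nz = np.where(near_pole, pz, nz)
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


def _intersect_interface(bundle: Bundle, iface: Interface, idx: np.ndarray):
    """Intersection points and oriented normals for rays ``idx``.

    Returns ``(hit_mask, t, nx, ny, nz)`` where the normal is oriented
    against each incoming ray.  Rays that miss the surface or fall outside
    its clear aperture have ``hit_mask`` False.
    """
    x, y, z = bundle.x[idx], bundle.y[idx], bundle.z[idx]
    ux, uy, uz = bundle.ux[idx], bundle.uy[idx], bundle.uz[idx]
    if math.isinf(iface.radius_mm):
        with np.errstate(divide="ignore"):
            t = (iface.z_vertex_mm - z) / uz
        hit = (t > 1e-9) & np.isfinite(t)
        xh = x + t * ux
        yh = y + t * uy
        hit &= xh**2 + yh**2 <= iface.semi_aperture_mm**2
        n = np.full_like(t, -1.0)  # plane normal -z, flipped below
        nx = np.zeros_like(t)
        ny = np.zeros_like(t)
        nz = np.where(uz > 0, -1.0, 1.0)
        return hit, t, nx, ny, nz
    r_c = iface.radius_mm
    cz = iface.z_vertex_mm + r_c
    ox, oy, oz = x, y, z - cz
    b_half = ox * ux + oy * uy + oz * uz
    c = ox * ox + oy * oy + oz * oz - r_c * r_c
    disc = b_half * b_half - c
    valid = disc >= 0.0
    sq = np.sqrt(np.clip(disc, 0.0, None))
    t1 = -b_half - sq
    t2 = -b_half + sq
    def _ok(t):
        # hit must lie on the vertex-side hemisphere, within the clear aperture
        zh = z + t * uz - cz
        xh = x + t * ux
        yh = y + t * uy
        rad_ok = xh * xh + yh * yh <= iface.semi_aperture_mm**2
        hemi_ok = zh * np.sign(r_c) < 0.0
        return (t > 1e-9) & rad_ok & hemi_ok & valid

    # pick the first root on the correct hemisphere within the clear aperture
    ok1 = _ok(t1)
    ok2 = _ok(t2)
    t = np.where(ok1, t1, t2)
    hit = ok1 | ok2
    xh = x + t * ux
    yh = y + t * uy
    zh = z + t * uz
    nx = (xh - 0.0) / r_c
    ny = (yh - 0.0) / r_c
    nz = (zh - cz) / r_c
    # orient against the incoming ray
    dot = ux * nx + uy * ny + uz * nz
    flip = dot > 0.0
    nx = np.where(flip, -nx, nx)
    ny = np.where(flip, -ny, ny)
    nz = np.where(flip, -nz, nz)
    return hit, t, nx, ny, nz


def trace_lens(bundle: Bundle, lens: LensSpec, rng: np.random.Generator) -> Bundle:
    """Iteratively walk alive photons through a lens's interfaces.

    Transmission/reflection is drawn from the Fresnel (or AR-coating)
    reflectance; refraction follows Snell.  Reflected photons walk back
    through earlier interfaces and are discarded if they exit backward
    through interface 1.  With probability ``scatter_prob`` a reflection is
    diffused by an RM(gs, alpha) polar draw about the specular direction.
    """
    n_if = len(lens.interfaces)
    idx_if = np.full(bundle.x.size, 0, dtype=np.int64)
    pending = bundle.alive.copy()
    rm_cache: dict = {}
    guard = 0
    while np.any(pending):
        guard += 1
        if guard > 10_000:
            bundle.status[pending] = DISCARD_MISS
            break
        for k in range(n_if):
            sel = np.flatnonzero(pending & (idx_if == k) & bundle.alive)
            if sel.size == 0:
                continue
            iface = lens.interfaces[k]
            hit, t, nx, ny, nz = _intersect_interface(bundle, iface, sel)
            miss = sel[~hit]
            bundle.status[miss] = DISCARD_MISS
            pending[miss] = False
            sel = sel[hit]
            if sel.size == 0:
                continue
            t = t[hit]
            nx, ny, nz = nx[hit], ny[hit], nz[hit]
            bundle.x[sel] += t * bundle.ux[sel]
            bundle.y[sel] += t * bundle.uy[sel]
            bundle.z[sel] += t * bundle.uz[sel]
            going_fwd = bundle.uz[sel] > 0.0
            n1 = np.where(going_fwd, iface.n_before, iface.n_after)
            n2 = np.where(going_fwd, iface.n_after, iface.n_before)
            cos_i = -(bundle.ux[sel] * nx + bundle.uy[sel] * ny + bundle.uz[sel] * nz)
            r_fres, cos_t = fresnel(n1, n2, cos_i)
            if iface.ar_reflectance is not None:
                tir = r_fres >= 1.0
                r_fres = np.where(tir, 1.0, iface.ar_reflectance)
            reflect = rng.random(sel.size) < r_fres
            # --- refraction ---
            tr = sel[~reflect]
            if tr.size:
                eta = (n1 / n2)[~reflect]
                ci = cos_i[~reflect]
                ct = cos_t[~reflect]
                fac = eta * ci - ct
                bundle.ux[tr] = eta * bundle.ux[tr] + fac * nx[~reflect]
                bundle.uy[tr] = eta * bundle.uy[tr] + fac * ny[~reflect]
                bundle.uz[tr] = eta * bundle.uz[tr] + fac * nz[~reflect]
            # --- reflection (+ optional surface scattering) ---
            rf = sel[reflect]
            if rf.size:
                dot = -cos_i[reflect]
                bundle.ux[rf] -= 2.0 * dot * nx[reflect]
                bundle.uy[rf] -= 2.0 * dot * ny[reflect]
                bundle.uz[rf] -= 2.0 * dot * nz[reflect]
                if iface.scatter_prob > 0.0:
                    sc = rf[rng.random(rf.size) < iface.scatter_prob]
                    if sc.size:
                        key = (iface.scatter_gs, iface.scatter_alpha)
                        if key not in rm_cache:
                            rm_cache[key] = ReynoldsMcCormick(*key)
                        u = rm_cache[key].sample(rng, sc.size)
                        phi = 2.0 * np.pi * rng.random(sc.size)
                        bundle.ux[sc], bundle.uy[sc], bundle.uz[sc] = rotate_directions(
                            bundle.ux[sc], bundle.uy[sc], bundle.uz[sc], u, phi
                        )
            # update interface pointer by the travel direction
            nxt = np.where(bundle.uz[sel] > 0.0, k + 1, k - 1)
            idx_if[sel] = nxt
            back = sel[nxt < 0]
            bundle.status[back] = DISCARD_BACKWARD
            pending[back] = False
            done = sel[nxt >= n_if]
            pending[done] = False
    return bundle


# ---------------------------------------------------------------------------
# Source train
# ---------------------------------------------------------------------------

@dataclass
class SourceTrain:
    """Ordered optical elements between the fiber and the sample surface."""

    source: SourceSpec
    elements: List[Union[ApertureSpec, LensSpec]] = field(default_factory=list)

    def __post_init__(self):
        z_prev = self.source.z_mm
        for el in self.elements:
            z_lo = el.z_mm if isinstance(el, ApertureSpec) else el.z_entry
            z_hi = el.z_mm if isinstance(el, ApertureSpec) else el.z_exit
            if z_lo < z_prev:
                raise ConfigError("optical elements overlap or are out of order")
            z_prev = z_hi

    def trace(self, rng: np.random.Generator, n: int) -> Bundle:
        """Launch ``n`` photons and carry survivors to the sample plane z=0."""
        b = sample_fiber_photons(self.source, rng, n)
        return self.trace_bundle(b, rng)

    def trace_bundle(self, b: Bundle, rng: np.random.Generator) -> Bundle:
        for el in self.elements:
            if isinstance(el, ApertureSpec):
                aperture_pass(b, el)
            else:
                trace_lens(b, el, rng)
        # advance survivors to the sample surface plane z = 0
        m = b.alive & (b.uz > 0.0)
        stuck = b.alive & ~(b.uz > 0.0)
        b.status[stuck] = DISCARD_WRONG_WAY
        t = (0.0 - b.z[m]) / b.uz[m]
        idx = np.flatnonzero(m)
        b.x[idx] += t * b.ux[idx]
        b.y[idx] += t * b.uy[idx]
        b.z[idx] = 0.0
        return b


def build_source_train(source: SourceSpec, elements: Sequence[Union[ApertureSpec, LensSpec]]) -> SourceTrain:
    """Compose the source optics (apertures and lenses in z order)."""
    return SourceTrain(source, list(elements))
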