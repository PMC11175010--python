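"""Forward simulation of a full goniometric measurement.

Combines a source model (ideal pencil beam, or the instrument's fiber+lens
train represented by a resampled phase-space cache), the layered-sample
transport kernel, azimuth-integrated detection, and empty-stage reference
normalization into one callable forward model

    (mu_a, mu_s, g) -> normalized angular signal + pMC-perturbed signals,

which is what both the studies and the inverse solver consume.

The instrument source is traced once per process through the ray optics of
:mod:`goniotwin.optics` with a fixed internal seed and stored as ~1e6 rays in
(radial position, radial/tangential/axial direction) form; production runs
resample it with a fresh uniform azimuth per photon, which is exact for a
rotationally symmetric beam.  The cache is part of the model definition, so
truth and fit runs share it and its finite size cancels from fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _kernels
from .detection import DetectorSpec, GonioSignal, default_angle_grid
from .optics import ApertureSpec, SourceSpec, build_source_train, symmetric_biconvex
from .phasefunc import HenyeyGreenstein
from .sample import SampleDomain, cuvette, single_slab

__all__ = [
    "InstrumentSource",
    "pencil_source",
    "instrument_source",
    "ForwardModel",
    "ForwardResult",
    "PMC_DELTA_DEFAULT",
]

#: default fractional perturbation used for the single-run derivatives
PMC_DELTA_DEFAULT = 0.05

#: fixed seed for the source phase-space cache (a model constant, not a run seed)
_SOURCE_CACHE_SEED = 20240530

_EMPTY = np.empty(0, dtype=float)


@dataclass(frozen=True)
class InstrumentSource:
    """Source description handed to the kernel."""

    mode: int
    cache_r: np.ndarray = field(default_factory=lambda: _EMPTY)
    cache_ur: np.ndarray = field(default_factory=lambda: _EMPTY)
    cache_ut: np.ndarray = field(default_factory=lambda: _EMPTY)
    cache_uz: np.ndarray = field(default_factory=lambda: _EMPTY)
    label: str = "pencil"


def pencil_source() -> InstrumentSource:
    """Ideal axial pencil beam entering at the origin."""
    return InstrumentSource(_kernels.SRC_PENCIL)


_instrument_cache: dict = {}


def goniometer_source_train():
    """Preset source optics: 600 um NA-0.22 fiber at 348 mm, stop, f=75 mm
    imaging lens at 240 mm, exit aperture.  The stop emulates the corrected
    aperture of the commercial achromat so the imaged fiber spot is ~1.4 mm."""
    src = SourceSpec(0.3, 0.22, -348.0)
    lens = symmetric_biconvex(75.0, z_center_mm=-240.0)
    return build_source_train(src, [ApertureSpec(-245.0, 8.0), lens, ApertureSpec(-230.0, 12.7)])


def instrument_source(n_rays: int = 1_000_000) -> InstrumentSource:
    """Phase-space cache of the preset source train at the sample plane."""
    key = n_rays
    if key in _instrument_cache:
        return _instrument_cache[key]
    rng = np.random.default_rng(_SOURCE_CACHE_SEED)
    train = goniometer_source_train()
    chunks = []
    total = 0
    while total < n_rays:
        b = train.trace(rng, max(int((n_rays - total) * 3.2), 10_000))
        m = b.alive
        r = np.sqrt(b.x[m] ** 2 + b.y[m] ** 2)
        # radial/tangential direction components in the local frame
        with np.errstate(invalid="ignore", divide="ignore"):
            cph = np.where(r > 0, b.x[m] / np.where(r > 0, r, 1.0), 1.0)
            sph = np.where(r > 0, b.y[m] / np.where(r > 0, r, 1.0), 0.0)
        ur = b.ux[m] * cph + b.uy[m] * sph
        ut = -b.ux[m] * sph + b.uy[m] * cph
        chunks.append(np.column_stack([r, ur, ut, b.uz[m]]))
        total += int(m.sum())
    cat = np.concatenate(chunks)[:n_rays]
    out = InstrumentSource(
        _kernels.SRC_CACHE,
        np.ascontiguousarray(cat[:, 0]), np.ascontiguousarray(cat[:, 1]),
        np.ascontiguousarray(cat[:, 2]), np.ascontiguousarray(cat[:, 3]),
        label="instrument",
    )
    _instrument_cache[key] = out
    return out


@dataclass
class ForwardResult:
    """Raw and normalized outcome of one forward run."""

    signal: GonioSignal                  # normalized intensity + hit counts
    perturbed: dict                      # tag -> normalized perturbed intensity
    deltas: dict                         # tag -> fractional step used
    params: dict                         # mua, mus, g of the perturbable layer
    sq_sum: np.ndarray                   # per-angle sum of squared weights (raw)
    n_launched: int
    reference_per_photon: float
    counters: np.ndarray

    def derivative(self, tag: str) -> np.ndarray:
        """Single-run derivative d(signal)/d(parameter) per the perturbation
        estimator: (perturbed - base) / (p * delta_p)."""
        p = self.params[tag]
        d = self.deltas[tag]
        if p == 0.0:
            raise ValueError(
                f"multiplicative perturbation undefined at {tag} = 0; "
                "use an additive step instead"
            )
        return (self.perturbed[tag] - self.signal.intensity) / (p * d)

    def intensity_se(self) -> np.ndarray:
        """Per-angle standard error of the normalized intensity."""
        n = self.n_launched
        mean = self.signal.intensity * self.reference_per_photon
        var = np.clip(self.sq_sum / n - mean**2, 0.0, None) / n
        return np.sqrt(var) / self.reference_per_photon


class ForwardModel:
    """Configured instrument + sample geometry with free (mu_a, mu_s, g).

    ``domain_factory(mua, mus, g)`` must return a :class:`SampleDomain`; the
    perturbable layer must use a Henyey-Greenstein phase function for ``g``
    derivatives to be available.
    """

    def __init__(
        self,
        domain_factory: Callable[[float, float, float], SampleDomain],
        angles_deg: Optional[np.ndarray] = None,
        source: Optional[InstrumentSource] = None,
        detector: Optional[DetectorSpec] = None,
        deltas: Optional[dict] = None,
        is_frac: float = 0.5,
        parallax: bool = True,
    ):
        self.domain_factory = domain_factory
        self.angles_deg = np.asarray(
            default_angle_grid() if angles_deg is None else angles_deg, dtype=float
        )
        self.source = source if source is not None else pencil_source()
        det = detector if detector is not None else DetectorSpec(0.0)
        self.detector = det
        self.deltas = dict(deltas) if deltas else {
            "mua": PMC_DELTA_DEFAULT, "mus": PMC_DELTA_DEFAULT, "g": PMC_DELTA_DEFAULT
        }
        self.is_frac = float(is_frac)
        # detection angle from the trajectory's crossing with the detector
        # sphere (parallax) or from the exit direction alone (far field)
        self.parallax = bool(parallax)
        # detector precomputation
        th = np.radians(self.angles_deg)
        self._det_sin = np.sin(th)
        self._det_cos = np.cos(th)
        self._cos_tr = det.cos_theta_r
        self._theta_r_deg = det.theta_r_deg
        self._ref_cache: dict = {}

    # -- low-level kernel invocation ------------------------------------

    def _run_kernel(self, domain: SampleDomain, n_photons: int, rng, deltas, is_frac):
        layers = domain.layers
        n_layers = len(layers)
        z_edges = domain.z_edges
        mua = np.array([l.material.mua for l in layers])
        mus = np.array([l.material.mus for l in layers])
        n_idx = np.array([l.material.n for l in layers])
        g_arr = np.zeros(n_layers)
        use_table = np.zeros(n_layers, dtype=np.int64)
        table_len = 2048
        tables = np.zeros((n_layers, table_len))
        for i, l in enumerate(layers):
            ph = l.material.phase
            if ph is None:
                continue
            if isinstance(ph, HenyeyGreenstein):
                g_arr[i] = ph.g
            else:
                use_table[i] = 1
                tables[i] = ph.tabulate().inverse_cdf_table(table_len)
        nd = self.angles_deg.size
        s0 = np.zeros(nd)
        sa = np.zeros(nd)
        ss = np.zeros(nd)
        sg = np.zeros(nd)
        s0sq = np.zeros(nd)
        hits = np.zeros(nd, dtype=np.int64)
        counters = np.zeros(5, dtype=np.int64)
        src = self.source
        _kernels.transport_kernel(
            rng, n_photons,
            src.mode, src.cache_r, src.cache_ur, src.cache_ut, src.cache_uz,
            z_edges, mua, mus, n_idx, g_arr, use_table, tables,
            domain.n_outside, domain.cutout_radius_mm,
            domain.perturbable, deltas["mua"], deltas["mus"], deltas["g"],
            is_frac,
            self.detector.distance_mm if self.parallax else -1.0,
            self.angles_deg, self._det_sin, self._det_cos,
            self._cos_tr, self._theta_r_deg,
            s0, sa, ss, sg, s0sq, hits, counters,
        )
        return s0, sa, ss, sg, s0sq, hits, counters

    def reference_per_photon(self, n_photons: int = 2_000_000) -> float:
        """Empty-stage 0-degree intensity per launched photon.

        Exactly 1 for a pencil source; simulated once and cached for the
        instrument source (a 0.1 mm air layer stands in for the empty stage).
        """
        if self.source.mode == _kernels.SRC_PENCIL:
            return 1.0
        key = (self.source.label, n_photons)
        if key not in self._ref_cache:
            air = single_slab(0.0, 0.0, 0.0, n_med=1.0, thickness_mm=0.1,
                              phase=HenyeyGreenstein(0.0))
            rng = np.random.default_rng(_SOURCE_CACHE_SEED + 1)
            zero_d = {"mua": 0.0, "mus": 0.0, "g": 0.0}
            s0, *_rest = self._run_kernel(air, n_photons, rng, zero_d, 0.0)
            idx = int(np.argmin(np.abs(self.angles_deg)))
            self._ref_cache[key] = float(s0[idx]) / n_photons
        return self._ref_cache[key]

    # -- public API ------------------------------------------------------

    def simulate(self, mua: float, mus: float, g: float, n_photons: int,
                 seed: int) -> ForwardResult:
        """One forward run at the given optical parameters."""
        domain = self.domain_factory(mua, mus, g)
        rng = np.random.default_rng(seed)
        deltas = dict(self.deltas)
        if mua == 0.0:
            deltas = dict(deltas)
            deltas["mua"] = 0.0  # multiplicative step undefined; weight stays 1
        s0, sa, ss, sg, s0sq, hits, counters = self._run_kernel(
            domain, n_photons, rng, deltas, self.is_frac
        )
        ref = self.reference_per_photon()
        scale = 1.0 / (n_photons * ref)
        signal = GonioSignal(self.angles_deg, s0 * scale, hits,
                             reference=ref,
                             meta={"n_launched": n_photons, "seed": seed})
        perturbed = {"mua": sa * scale, "mus": ss * scale, "g": sg * scale}
        med = domain.medium
        params = {"mua": med.mua, "mus": med.mus, "g": g}
        return ForwardResult(signal, perturbed, deltas, params, s0sq,
                             n_photons, ref, counters)


def cuvette_model(thickness_mm: float = 2.0, n_med: float = 1.33,
                  glass_n: float = 1.51, glass_thickness_mm: float = 1.0,
                  **kwargs) -> ForwardModel:
    """Forward model for the two-window cuvette scenario."""
    def factory(mua, mus, g):
        return cuvette(mua, mus, g, n_med=n_med, thickness_mm=thickness_mm,
                       glass_n=glass_n, glass_thickness_mm=glass_thickness_mm)
    return ForwardModel(factory, **kwargs)


def slab_model(thickness_mm: float = 2.0, n_med: float = 1.0, **kwargs) -> ForwardModel:
    """Forward model for the single-layer optical-depth sweep scenario."""
    def factory(mua, mus, g):
        return single_slab(mua, mus, g, n_med=n_med, thickness_mm=thickness_mm)
    return ForwardModel(factory, **kwargs)
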