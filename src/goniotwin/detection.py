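"""Photon detection and goniometric signal assembly.

Two detection models are provided for the same instrument geometry:

* the azimuth-integrated detector for rotationally symmetric runs
  (incident angle 0): a photon leaving the sample with polar scattering
  angle ``theta_S`` is credited to every detector angle ``theta_D`` whose
  aperture cone its azimuthal circle crosses, with the analytic weight
  ``w = arccos(Phi) / pi`` equal to the fraction of the azimuth circle
  intercepted by the detector aperture -- the variance-reduction scheme;
* the explicit 2D-chip detector (aperture -> imaging lens -> cover glass ->
  pixelated chip), usable at any incidence, which the integrated detector
  must agree with in expectation.

Signals are normalized against the 0-degree intensity of an empty-stage
reference run, mirroring the calibration of the physical instrument.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from . import optics
from .optics import Bundle, LensSpec, symmetric_biconvex

__all__ = [
    "DetectorSpec",
    "GonioSignal",
    "azimuthal_weight",
    "detect_integrated",
    "detect_chip",
    "normalize_to_reference",
    "default_angle_grid",
    "read_signal",
    "write_signal",
]


def default_angle_grid() -> np.ndarray:
    """150 detector angles: 0-79 and 100-169 degrees in 1-degree steps.

    The gap (80, 100) excludes near-grazing exit angles where a thin-slab
    sample emits almost nothing and the physical sample holder interferes.
    """
    return np.concatenate([np.arange(0.0, 80.0), np.arange(100.0, 170.0)])


@dataclass(frozen=True)
class ChipSpec:
    """Imaging train behind the aperture: lens surrogate, cover glass, chip."""

    lens_f_mm: float = 30.0
    lens_z_mm: float = 131.0          # principal plane distance from the sample
    cover_z_mm: float = 168.0
    cover_thickness_mm: float = 0.5
    cover_n: float = 1.51
    chip_z_mm: float = 169.9
    n_rows: int = 1200
    n_cols: int = 1920
    pixel_um: float = 5.86
    binning: int = 10


@dataclass(frozen=True)
class DetectorSpec:
    """One goniometric detector position.

    ``theta_deg`` is the goniometer arm angle, ``distance_mm`` the entrance
    pupil distance from the sample, ``aperture_radius_mm`` the open radius.
    The derived half-opening angle satisfies ``tan(theta_r) = r / d``.
    """

    theta_deg: float
    distance_mm: float = 120.8
    aperture_radius_mm: float = 2.5
    chip: ChipSpec = field(default_factory=ChipSpec)

    def __post_init__(self):
        if self.distance_mm <= 0 or self.aperture_radius_mm <= 0:
            raise ValueError("detector distance and aperture radius must be positive")

    @property
    def tan_theta_r(self) -> float:
        return self.aperture_radius_mm / self.distance_mm

    @property
    def theta_r_deg(self) -> float:
        return math.degrees(math.atan(self.tan_theta_r))

    @property
    def cos_theta_r(self) -> float:
        return 1.0 / math.sqrt(1.0 + self.tan_theta_r**2)


def azimuthal_weight(theta_s_deg, det: DetectorSpec):
    """Azimuth-integrated detection weight ``w`` of a photon at angle theta_S.

    ``Phi = (cos(theta_r) - cos(theta_D) cos(theta_S)) / (sin(theta_D) sin(theta_S))``;
    ``w = arccos(Phi)/pi`` for ``|Phi| < 1``, ``1`` for ``Phi <= -1`` (the whole
    azimuth circle lies inside the aperture cone) and ``0`` for ``Phi >= 1``
    (no intersection).  The degenerate on-axis detectors (``sin(theta_D) = 0``)
    and exactly axial photons reduce to the plain cone test.
    """
    theta_s = np.radians(np.asarray(theta_s_deg, dtype=float))
    theta_d = math.radians(det.theta_deg)
    cos_tr = det.cos_theta_r
    theta_r = math.acos(min(cos_tr, 1.0))
    sin_d = math.sin(theta_d)
    scalar = theta_s.ndim == 0
    theta_s = np.atleast_1d(theta_s)
    w = np.zeros_like(theta_s)
    sin_s = np.sin(theta_s)
    degenerate_s = np.abs(sin_s) < 1e-12
    if abs(sin_d) < 1e-12:
        # detector at 0 or 180 degrees: photon inside the cone or not
        sep = np.abs(theta_s - theta_d)
        w = (sep <= theta_r).astype(float)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (cos_tr - math.cos(theta_d) * np.cos(theta_s)) / (sin_d * sin_s)
        inside = phi <= -1.0
        partial = np.abs(phi) < 1.0
        w = np.where(partial, np.arccos(np.clip(phi, -1.0, 1.0)) / np.pi, 0.0)
        w[inside] = 1.0
        # axial photon: cone test against the detector angle
        sep0 = np.abs(theta_s - 0.0)
        w[degenerate_s & (theta_s < math.pi / 2)] = float(theta_d <= theta_r)
        w[degenerate_s & (theta_s >= math.pi / 2)] = float(abs(theta_d - math.pi) <= theta_r)
    return float(w[0]) if scalar else w


@dataclass
class GonioSignal:
    """Angle-resolved detected signal.

    ``intensity`` carries the (possibly normalized) weighted sums per angle;
    ``n_photons`` the raw integer hit counts used by the counting-noise
    estimate; ``meta`` free-form header keys.
    """

    angles_deg: np.ndarray
    intensity: np.ndarray
    n_photons: np.ndarray
    reference: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.n_photons = np.asarray(self.n_photons, dtype=np.int64)
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angle grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if np.any(self.n_photons < 0):
            raise ValueError("photon counts must be non-negative")

    def copy(self) -> "GonioSignal":
        return GonioSignal(
            self.angles_deg.copy(), self.intensity.copy(), self.n_photons.copy(),
            self.reference, dict(self.meta),
        )


def detect_integrated(theta_s_deg, detectors, signal: GonioSignal, weights=None,
                      incident_angle_deg: float = 0.0) -> GonioSignal:
    """Credit exiting photons to the azimuth-integrated detectors.

    ``theta_s_deg`` are exit polar angles of photons (any length);
    ``weights`` optional per-photon multipliers (importance weights).  Valid
    only for rotationally symmetric runs; a non-zero incident angle is a
    configuration error.
    """
    if incident_angle_deg != 0.0:
        raise ValueError("azimuth-integrated detection requires incident angle 0")
    theta_s_deg = np.atleast_1d(np.asarray(theta_s_deg, dtype=float))
    weights = np.ones_like(theta_s_deg) if weights is None else np.atleast_1d(weights)
    for j, det in enumerate(detectors):
        w = azimuthal_weight(theta_s_deg, det)
        hit = w > 0.0
        signal.intensity[j] += float(np.sum(w[hit] * weights[hit]))
        signal.n_photons[j] += int(np.count_nonzero(hit))
    return signal


def detect_chip(bundle: Bundle, det: DetectorSpec, rng: np.random.Generator):
    """Trace exiting photons through one detector's full imaging train.

    The detector frame is the sample frame rotated by ``theta_D`` about the
    y-axis.  Photons pass the entrance-pupil aperture (position test at the
    pupil plane), the f=30 mm lens surrogate, the chip cover glass, and are
    binned onto the pixel grid.  Returns ``(rows, cols, hit_mask)`` in binned
    pixel units.
    """
    td = math.radians(det.theta_deg)
    ct, st = math.cos(td), math.sin(td)
    # rotate into the detector frame (detector axis -> +z')
    x = ct * bundle.x - st * bundle.z
    z = st * bundle.x + ct * bundle.z
    ux = ct * bundle.ux - st * bundle.uz
    uz = st * bundle.ux + ct * bundle.uz
    b = Bundle(x, bundle.y.copy(), z, ux, bundle.uy.copy(), uz, bundle.status.copy())
    optics.aperture_pass(b, optics.ApertureSpec(det.distance_mm, det.aperture_radius_mm))
    chip = det.chip
    lens = symmetric_biconvex(
        chip.lens_f_mm, thickness_mm=4.0, z_center_mm=chip.lens_z_mm,
        semi_aperture_mm=12.7, ar_reflectance=0.0,
    )
    optics.trace_lens(b, lens, rng)
    cover = LensSpec((
        optics.Interface(chip.cover_z_mm, math.inf, 12.7, 1.0, chip.cover_n, ar_reflectance=0.0),
        optics.Interface(chip.cover_z_mm + chip.cover_thickness_mm, math.inf, 12.7,
                         chip.cover_n, 1.0, ar_reflectance=0.0),
    ))
    optics.trace_lens(b, cover, rng)
    m = b.alive & (b.uz > 0)
    t = np.where(m, (chip.chip_z_mm - b.z) / np.where(b.uz != 0, b.uz, 1.0), 0.0)
    xc = b.x + t * b.ux
    yc = b.y + t * b.uy
    pix_mm = chip.pixel_um * 1e-3
    half_w = 0.5 * chip.n_cols * pix_mm
    half_h = 0.5 * chip.n_rows * pix_mm
    cols = np.floor((xc + half_w) / pix_mm).astype(int)
    rows = np.floor((yc + half_h) / pix_mm).astype(int)
    on_chip = m & (cols >= 0) & (cols < chip.n_cols) & (rows >= 0) & (rows < chip.n_rows)
    return rows // chip.binning, cols // chip.binning, on_chip


def bin_chip_counts(rows, cols, hit, chip: ChipSpec) -> np.ndarray:
    """Accumulate binned-pixel hit counts into an image array."""
    nr = -(-chip.n_rows // chip.binning)
    nc = -(-chip.n_cols // chip.binning)
    img = np.zeros((nr, nc), dtype=np.int64)
    np.add.at(img, (rows[hit], cols[hit]), 1)
    return img


def normalize_to_reference(signal: GonioSignal, reference: GonioSignal) -> GonioSignal:
    """Divide all intensities by the reference run's 0-degree intensity."""
    idx = int(np.argmin(np.abs(reference.angles_deg)))
    if abs(reference.angles_deg[idx]) > 1e-9:
        raise ValueError("reference signal lacks a 0-degree sample")
    ref = float(reference.intensity[idx])
    if ref <= 0.0:
        raise ValueError("reference 0-degree intensity is zero")
    out = signal.copy()
    out.intensity = out.intensity / ref
    out.reference = ref
    return out


# ---------------------------------------------------------------------------
# Signal file format: delimited text with '#' header, exact count round trip
# ---------------------------------------------------------------------------

def write_signal(signal: GonioSignal, path) -> None:
    buf = io.StringIO()
    for key, val in signal.meta.items():
        buf.write(f"# {key} = {val}\n")
    if np.isfinite(signal.reference):
        buf.write(f"# reference = {signal.reference!r}\n")
    buf.write("# angle_deg intensity n_photons\n")
    for a, i, n in zip(signal.angles_deg, signal.intensity, signal.n_photons):
        buf.write(f"{float(a):.6f} {float(i)!r} {int(n):d}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_signal(path) -> GonioSignal:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            a, i, n = line.split()
            rows.append((float(a), float(i), int(n)))
    if not rows:
        raise ValueError(f"{path}: empty signal file")
    arr = np.array([[r[0], r[1], r[2]] for r in rows])
    ref = float(meta.pop("reference", "nan"))
    return GonioSignal(arr[:, 0], arr[:, 1], arr[:, 2].astype(np.int64), ref, meta)
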