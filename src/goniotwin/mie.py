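"""Lorenz-Mie scattering of monodisperse spheres in a non-absorbing host.

Used to predict the phase function and scattering coefficient of calibration
suspensions (polystyrene microspheres in water) from first principles: the
sphere diameter, the wavelength and the two refractive indices fully determine
the single-particle scattering cross-section ``sigma_sca``, the anisotropy
``g`` and the angular pattern.  The suspension scattering coefficient follows
from the independent-scattering assumption, ``mu_s = N * sigma_sca`` with
number density ``N = f_v / (pi d^3 / 6)``.

The series is evaluated with the standard downward logarithmic-derivative
recurrence (Bohren & Huffman) truncated at ``n_max = x + 4 x^{1/3} + 2``.
Sphere absorption is neglected (real relative index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phasefunc import TabulatedPhase

__all__ = [
    "MieResult",
    "MieSizeError",
    "mie_compute",
    "mus_from_suspension",
    "polystyrene_index",
    "water_index",
    "nbk7_index",
]

#: hard ceiling on the size parameter; far beyond it the upward Riccati-Bessel
#: recurrence for chi_n overflows double precision
_MAX_SIZE_PARAMETER = 1200.0


class MieSizeError(ValueError):
    """Size parameter too large for a stable series evaluation."""


@dataclass(frozen=True)
class MieResult:
    """Single-sphere Mie solution.

    Attributes
    ----------
    x : size parameter ``pi d n_med / lambda``
    m : relative refractive index ``n_particle / n_medium``
    q_sca : scattering efficiency (dimensionless)
    sigma_sca_mm2 : scattering cross-section in mm^2
    g : anisotropy factor (mean cosine of the scattering angle)
    phase : normalized tabulated phase function on a cos(theta) grid
    """

    x: float
    m: float
    q_sca: float
    sigma_sca_mm2: float
    g: float
    phase: TabulatedPhase


def _mie_coefficients(x: float, m: float):
    """Mie coefficients a_n, b_n for real relative index m."""
    n_max = int(round(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    n = np.arange(1, n_max + 1)

    # logarithmic derivative D_n(mx) by downward recurrence
    mx = m * x
    n_start = n_max + 15
    d = np.zeros(n_start + 1)
    for k in range(n_start, 0, -1):
        d[k - 1] = k / mx - 1.0 / (d[k] + k / mx)
    d = d[1 : n_max + 1]

    # Riccati-Bessel psi_n, chi_n at x by upward recurrence (n = 1..n_max)
    psi_n = np.empty(n_max)
    chi_n = np.empty(n_max)
    p0, p1 = np.sin(x), np.sin(x) / x - np.cos(x)   # psi_0, psi_1
    c0, c1 = np.cos(x), np.cos(x) / x + np.sin(x)   # chi_0, chi_1
    psi_n[0], chi_n[0] = p1, c1
    for k in range(2, n_max + 1):
        fac = (2.0 * k - 1.0) / x
        p0, p1 = p1, fac * p1 - p0
        c0, c1 = c1, fac * c1 - c0
        psi_n[k - 1], chi_n[k - 1] = p1, c1
        if not np.isfinite(c1):
            raise MieSizeError(f"Riccati-Bessel overflow at order {k} (x={x:g})")
    psi_nm1 = np.concatenate(([np.sin(x)], psi_n[:-1]))
    chi_nm1 = np.concatenate(([np.cos(x)], chi_n[:-1]))

    xi_n = psi_n - 1j * chi_n
    xi_nm1 = psi_nm1 - 1j * chi_nm1

    da = d / m + n / x
    db = d * m + n / x
    a = (da * psi_n - psi_nm1) / (da * xi_n - xi_nm1)
    b = (db * psi_n - psi_nm1) / (db * xi_n - xi_nm1)
    return n, a, b


def mie_compute(
    diameter_um: float,
    wavelength_nm: float,
    n_particle: float,
    n_medium: float,
    n_angles: int = 1801,
) -> MieResult:
    """Full Mie solution for one sphere diameter and vacuum wavelength.

    Parameters are positive; indices are real (particle absorption neglected).
    Raises :class:`MieSizeError` when the size parameter exceeds the stable
    range of the series.
    """
    if diameter_um <= 0.0 or wavelength_nm <= 0.0:
        raise ValueError("diameter and wavelength must be positive")
    if n_particle <= 0.0 or n_medium <= 0.0:
        raise ValueError("refractive indices must be positive")
    wavelength_um = wavelength_nm * 1e-3
    x = np.pi * diameter_um * n_medium / wavelength_um
    if x > _MAX_SIZE_PARAMETER:
        raise MieSizeError(f"size parameter x={x:g} exceeds {_MAX_SIZE_PARAMETER:g}")
    m = n_particle / n_medium

    n, a, b = _mie_coefficients(x, m)
    two_n_plus_1 = 2.0 * n + 1.0
    q_sca = (2.0 / (x * x)) * np.sum(two_n_plus_1 * (np.abs(a) ** 2 + np.abs(b) ** 2))

    # asymmetry parameter
    g_sum = np.sum(
        n[:-1] * (n[:-1] + 2.0) / (n[:-1] + 1.0)
        * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:]))
    ) + np.sum(two_n_plus_1 / (n * (n + 1.0)) * np.real(a * np.conj(b)))
    g = float(4.0 / (x * x * q_sca) * g_sum)

    # angular pattern via pi_n / tau_n recurrences
    theta = np.linspace(0.0, np.pi, n_angles)
    mu = np.cos(theta)
    s1 = np.zeros(n_angles, dtype=complex)
    s2 = np.zeros(n_angles, dtype=complex)
    pi_nm1 = np.zeros(n_angles)
    pi_n = np.ones(n_angles)
    for k, (ak, bk) in enumerate(zip(a, b), start=1):
        tau_n = k * mu * pi_n - (k + 1.0) * pi_nm1
        fac = (2.0 * k + 1.0) / (k * (k + 1.0))
        s1 += fac * (ak * pi_n + bk * tau_n)
        s2 += fac * (ak * tau_n + bk * pi_n)
        pi_np1 = ((2.0 * k + 1.0) * mu * pi_n - (k + 1.0) * pi_nm1) / k
        pi_nm1, pi_n = pi_n, pi_np1
    intensity = 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)

    order = np.argsort(mu)
    phase = TabulatedPhase(mu[order], intensity[order])

    radius_mm = 0.5 * diameter_um * 1e-3
    sigma_sca_mm2 = float(q_sca) * np.pi * radius_mm**2
    return MieResult(float(x), float(m), float(q_sca), sigma_sca_mm2, g, phase)


def mus_from_suspension(volume_fraction: float, diameter_um: float, sigma_sca_mm2: float) -> float:
    """Scattering coefficient (mm^-1) of a dilute monodisperse suspension.

    ``mu_s = N * sigma_sca`` with ``N = f_v / (pi d^3 / 6)``; linear in the
    volume fraction, which must be small enough for independent scattering.
    """
    if volume_fraction < 0.0:
        raise ValueError("volume fraction must be non-negative")
    if diameter_um <= 0.0:
        raise ValueError("diameter must be positive")
    d_mm = diameter_um * 1e-3
    number_density = volume_fraction / (np.pi * d_mm**3 / 6.0)
    return float(number_density * sigma_sca_mm2)


# ---------------------------------------------------------------------------
# Built-in dispersion data (Sellmeier fits) so no external tables are needed.
# ---------------------------------------------------------------------------

def polystyrene_index(wavelength_nm: float) -> float:
    """Polystyrene refractive index (Sellmeier fit, visible/NIR)."""
    lam2 = (wavelength_nm * 1e-3) ** 2
    return float(np.sqrt(1.0 + 1.4435 * lam2 / (lam2 - 0.020216)))


def water_index(wavelength_nm: float) -> float:
    """Water refractive index at ~20 C (four-term Sellmeier fit)."""
    lam2 = (wavelength_nm * 1e-3) ** 2
    terms = (
        5.684027565e-1 * lam2 / (lam2 - 5.101829712e-3)
        + 1.726177391e-1 * lam2 / (lam2 - 1.821153936e-2)
        + 2.086189578e-2 * lam2 / (lam2 - 2.620722293e-2)
        + 1.130748688e-1 * lam2 / (lam2 - 1.069792721e1)
    )
    return float(np.sqrt(1.0 + terms))


def nbk7_index(wavelength_nm: float) -> float:
    """N-BK7 crown glass refractive index (Sellmeier)."""
    lam2 = (wavelength_nm * 1e-3) ** 2
    terms = (
        1.03961212 * lam2 / (lam2 - 0.00600069867)
        + 0.231792344 * lam2 / (lam2 - 0.0200179144)
        + 1.01046945 * lam2 / (lam2 - 103.560653)
    )
    return float(np.sqrt(1.0 + terms))
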