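"""Perturbation-Monte-Carlo path weights and single-run derivatives.

Instead of re-simulating at a perturbed optical parameter ``p' = p (1 + delta)``,
each recorded photon path is re-weighted:

* absorption:  ``w_mua = exp(-l * delta * mu_a)`` with ``l`` the path length in
  the perturbed medium (ratio of Beer-Lambert transmissions);
* scattering:  ``w_mus = (1 + delta)^N_scat * exp(-l * delta * mu_s)`` (per-event
  scattering-probability rescaling times the transmission ratio);
* anisotropy:  ``w_g = prod_i p_HG(u_i; g') / p_HG(u_i; g)`` over the recorded
  scattering cosines.

The perturbed signal estimate is the weighted detector sum, and the derivative
follows from the finite-difference form evaluated on a single run:
``dMC/dp = (S_p(MC) - MC) / (p * delta)``.

These scalar helpers mirror exactly what the transport kernel accumulates
online; they exist for direct evaluation and testing, and
:func:`mc_derivative` exposes the estimator on a finished forward run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phasefunc import hg_pdf

__all__ = [
    "PerturbationSpec",
    "weight_mua",
    "weight_mus",
    "weight_g",
    "mc_derivative",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """One parameter perturbation: tag in {'mua','mus','g'}, fractional step,
    baseline value."""

    tag: str
    delta: float
    value: float

    def __post_init__(self):
        if self.tag not in ("mua", "mus", "g"):
            raise ValueError(f"unknown parameter tag {self.tag!r}")
        if self.delta == 0.0:
            raise ValueError("fractional step must be non-zero")
        if self.tag == "g" and not -1.0 < self.value * (1.0 + self.delta) < 1.0:
            raise ValueError("perturbed g leaves (-1, 1)")


def weight_mua(l_mm, mua: float, delta: float):
    """Absorption perturbation weight ``exp(-l * delta * mu_a)``."""
    l_mm = np.asarray(l_mm, dtype=float)
    return np.exp(-l_mm * delta * mua)


def weight_mus(l_mm, n_scat, mus: float, delta: float):
    """Scattering perturbation weight ``(1+delta)^N_scat exp(-l delta mu_s)``."""
    l_mm = np.asarray(l_mm, dtype=float)
    n_scat = np.asarray(n_scat)
    return (1.0 + delta) ** n_scat * np.exp(-l_mm * delta * mus)


def weight_g(cosines, g: float, delta: float):
    """Anisotropy perturbation weight: product of HG density ratios at
    ``g' = g (1 + delta)`` over the recorded scattering cosines."""
    g_pert = g * (1.0 + delta)
    if not -1.0 < g_pert < 1.0:
        raise ValueError(f"perturbed g = {g_pert} outside (-1, 1)")
    cosines = np.asarray(cosines, dtype=float)
    if cosines.size == 0:
        return 1.0
    return float(np.prod(hg_pdf(g_pert, cosines) / hg_pdf(g, cosines)))


def mc_derivative(result, tag: str) -> np.ndarray:
    """Per-angle derivative of the normalized signal w.r.t. one parameter,
    from the perturbed sums recorded during a single simulation.

    ``result`` is a :class:`goniotwin.forward.ForwardResult`.  Raises if the
    baseline parameter is zero (the multiplicative step is undefined there;
    restart from a small positive value or use an additive perturbation).
    """
    return result.derivative(tag)
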