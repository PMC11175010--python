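"""Scripted numerical experiments on the digital twin.

These reproduce, at configurable scale, the convergence analyses that
validate the inverse solver against its own forward model:

* :func:`scan_error_function` -- the error-function landscape ``E(g) = ||C||``
  with absorption and scattering held at truth, exposing the global minimum
  at the true anisotropy and the spurious negative-g basin;
* :func:`convergence_study` -- repeated fits from random initial parameters,
  with per-basin statistics;
* :func:`systematic_error_study` -- fits with a deliberately wrong fixed
  input (sample thickness or medium refractive index);
* :func:`optical_depth_sweep` -- parameter recovery as the optical depth
  ``tau = mu_s * t`` grows;
* :func:`generate_synthetic_measurement` -- forward run written in the
  measurement file format (the package's stand-in for instrument data).

All photon budgets are desk-scale defaults (minutes on one CPU core); the
full-scale budgets of a GPU-backed run are reachable through the ``scale``
arguments or the CLI ``--full`` flag.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .detection import GonioSignal, write_signal
from .forward import ForwardModel, cuvette_model, instrument_source, slab_model
from .inverse import (
    BoundSpec,
    FitProblem,
    FitResult,
    levenberg_marquardt,
    parameter_error,
)

__all__ = [
    "StudyReport",
    "study_cuvette_model",
    "CUVETTE_TRUTH",
    "budget_for_noise",
    "scan_error_function",
    "convergence_study",
    "systematic_error_study",
    "optical_depth_sweep",
    "generate_synthetic_measurement",
]

#: forward-truth optical parameters of the reference cuvette scenario
CUVETTE_TRUTH = {"mua": 0.1, "mus": 0.15, "g": 0.75}

#: average counting-noise level (Eq.-style mean over angles) of the ideal
#: forward simulation
IDEAL_NOISE = 0.0025


@dataclass
class StudyReport:
    """Reproducible record of one study: every number in ``cases`` can be
    regenerated from ``config`` plus ``seeds``."""

    tag: str
    config: dict
    cases: list
    seeds: dict
    runtime_s: float = 0.0

    def to_text(self) -> str:
        lines = [f"# study = {self.tag}"]
        for k, v in self.config.items():
            lines.append(f"# {k} = {v}")
        for k, v in self.seeds.items():
            lines.append(f"# seed_{k} = {v}")
        lines.append(f"# runtime_s = {self.runtime_s:.1f}")
        if self.cases:
            keys = list(self.cases[0])
            lines.append(" ".join(keys))
            for case in self.cases:
                lines.append(" ".join(f"{case[k]:.6g}" if isinstance(case[k], float)
                                      else str(case[k]) for k in keys))
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())


def study_cuvette_model(thickness_mm: float = 2.0, n_med: float = 1.33,
                        source=None, **kwargs) -> ForwardModel:
    """Default cuvette forward model for the studies (instrument source)."""
    src = source if source is not None else instrument_source()
    return cuvette_model(thickness_mm=thickness_mm, n_med=n_med, source=src,
                         is_frac=kwargs.pop("is_frac", 0.25), **kwargs)


def budget_for_noise(model: ForwardModel, params: Dict[str, float],
                     sigma_target: float, seed: int,
                     n_pilot: int = 4_000_000) -> int:
    """Photon budget at which two matched runs have the target average
    counting noise (mean over angles of sqrt(2/N_i)); calibrated from a pilot
    run via the 1/sqrt(N) law."""
    pilot = model.simulate(params["mua"], params["mus"], params["g"], n_pilot, seed)
    hits = np.maximum(pilot.signal.n_photons, 1)
    sigma_pilot = float(np.mean(np.sqrt(2.0 / hits)))
    return int(n_pilot * (sigma_pilot / sigma_target) ** 2)


def _masked_norm(model, truth_sig, mask, params, n_photons, seed):
    r = model.simulate(params["mua"], params["mus"], params["g"], n_photons, seed)
    floor = 0.5 / (n_photons * r.reference_per_photon)
    mc = np.maximum(r.signal.intensity, floor)[mask]
    e = truth_sig.intensity[mask]
    c = (np.log(mc) - np.log(e)) / np.log(e)
    return float(np.linalg.norm(c))


def _parabolic_refine(g: np.ndarray, e: np.ndarray, i: int) -> float:
    """Vertex of a least-squares parabola through up to 5 points around i.

    A plain 3-point parabola amplifies Monte Carlo noise in the second
    difference; the 5-point least-squares fit is markedly more stable in
    shallow basins.
    """
    if 0 < i < g.size - 1:
        d2 = e[i - 1] - 2.0 * e[i] + e[i + 1]
        if d2 > 0.25 * e[i]:
            # sharp basin: the 3-point vertex is accurate and avoids the
            # asymmetry bias of a wide stencil
            shift = 0.5 * (e[i - 1] - e[i + 1]) / d2
            return float(g[i] + shift * (g[i + 1] - g[i]))
    lo, hi = max(i - 2, 0), min(i + 3, g.size)
    if hi - lo < 3:
        return float(g[i])
    coeff = np.polyfit(g[lo:hi], e[lo:hi], 2)
    if coeff[0] <= 0:
        return float(g[i])
    vertex = -coeff[1] / (2.0 * coeff[0])
    # keep the vertex inside the stencil
    return float(np.clip(vertex, g[lo], g[hi - 1]))


def scan_error_function(
    model: ForwardModel,
    truth: Dict[str, float] = None,
    g_grid: Optional[np.ndarray] = None,
    n_truth: int = 20_000_000,
    n_scan: int = 500_000,
    seed: int = 1,
) -> StudyReport:
    """Scan ``E(g) = ||C||`` with mu_a, mu_s fixed at truth.

    All scan points share one seed (common random numbers), which makes the
    discrete landscape smooth enough for parabolic refinement of its extrema.
    Reports the global minimum, any interior local minima and the separating
    maximum between the two basins.
    """
    t0 = time.time()
    truth = dict(CUVETTE_TRUTH if truth is None else truth)
    if g_grid is None:
        g_grid = np.arange(-0.95, 0.9501, 0.05)
    g_grid = np.asarray(g_grid, dtype=float)
    if np.max(np.diff(g_grid)) > 0.0501:
        import warnings
        warnings.warn("g grid coarser than 0.05: refinement may be unreliable")
    rng = np.random.default_rng(seed)
    truth_seed = int(rng.integers(1, 2**31 - 1))
    scan_seed = int(rng.integers(1, 2**31 - 1))
    truth_res = model.simulate(truth["mua"], truth["mus"], truth["g"], n_truth, truth_seed)
    sig = truth_res.signal
    e = sig.intensity
    mask = (e > 0) & (np.abs(np.log(np.where(e > 0, e, 1.0))) > 1e-9) & (sig.n_photons > 0)
    norms = np.array([
        _masked_norm(model, sig, mask, {**truth, "g": g}, n_scan, scan_seed)
        for g in g_grid
    ])
    cases = [{"g": float(g), "cost_norm": float(n)} for g, n in zip(g_grid, norms)]
    # extrema: interior local minima / maxima by discrete comparison
    minima = [i for i in range(1, g_grid.size - 1)
              if norms[i] <= norms[i - 1] and norms[i] <= norms[i + 1]]
    maxima = [i for i in range(1, g_grid.size - 1)
              if norms[i] >= norms[i - 1] and norms[i] >= norms[i + 1]]
    i_global = int(np.argmin(norms))
    g_global = _parabolic_refine(g_grid, norms, i_global)
    neg = [i for i in minima if g_grid[i] < 0]
    g_local = _parabolic_refine(g_grid, norms, min(neg, key=lambda i: norms[i])) if neg else float("nan")
    between = [i for i in maxima
               if min(g_local, g_global) < g_grid[i] < max(g_local, g_global)]
    g_sep = _parabolic_refine(g_grid, norms, max(between, key=lambda i: norms[i])) if between else float("nan")
    extrema = {"g_global_min": g_global, "g_local_min": g_local, "g_separating_max": g_sep}
    return StudyReport(
        "scan_error_function",
        {"truth": truth, "n_truth": n_truth, "n_scan": n_scan, **extrema},
        cases,
        {"truth": truth_seed, "scan": scan_seed},
        time.time() - t0,
    )


def generate_synthetic_measurement(
    model: ForwardModel,
    params: Dict[str, float],
    n_photons: int,
    seed: int,
    path=None,
) -> GonioSignal:
    """Forward run in measurement form; counting noise reported in the header.

    Deterministic: identical (model, params, budget, seed) give bit-identical
    files.
    """
    res = model.simulate(params["mua"], params["mus"], params["g"], n_photons, seed)
    sig = res.signal
    hits = np.maximum(sig.n_photons, 1)
    sigma = float(np.mean(np.sqrt(2.0 / hits)))
    sig.meta.update({
        "mua_per_mm": params["mua"], "mus_per_mm": params["mus"], "g": params["g"],
        "n_photons_launched": n_photons, "seed": seed,
        "sigma_matched_counts": repr(sigma),
    })
    if path is not None:
        write_signal(sig, path)
    return sig


def _fit_once(measurement: GonioSignal, fit_model: ForwardModel, seed: int,
              n_meas: int, truth: Dict[str, float],
              g_bounds: BoundSpec = None, x0=None,
              iter_frac: int = 8, max_restarts: int = 4,
              max_steps: int = 10, xtol: float = 1e-3,
              n_final: Optional[int] = None) -> FitResult:
    free = {
        "mua": BoundSpec.lower(0.0),
        "mus": BoundSpec.lower(0.0),
        "g": g_bounds if g_bounds is not None else BoundSpec.interval(0.0, 1.0),
    }
    prob = FitProblem(
        measurement=measurement,
        model=fit_model,
        free=free,
        x0=x0,
        n_photons_iter=max(n_meas // iter_frac, 50_000),
        n_photons_final=n_final if n_final is not None else n_meas,
        seed=seed,
        max_steps=max_steps,
        xtol=xtol,
        max_restarts=max_restarts,
    )
    return levenberg_marquardt(prob)


def convergence_study(
    model: ForwardModel,
    truth: Dict[str, float] = None,
    n_starts: int = 8,
    n_photons: int = 20_000_000,
    seed: int = 1,
    g_bounds: BoundSpec = None,
    angles_mask: Optional[np.ndarray] = None,
) -> StudyReport:
    """Repeated fits of one synthetic measurement from random starts.

    With the default positive-g bound every start should reach the global
    basin; with ``g_bounds=BoundSpec.interval(-1, 1)`` starts below the
    separating extremum converge to the spurious negative-g solution.
    """
    t0 = time.time()
    truth = dict(CUVETTE_TRUTH if truth is None else truth)
    rng = np.random.default_rng(seed)
    meas_seed = int(rng.integers(1, 2**31 - 1))
    meas = generate_synthetic_measurement(model, truth, n_photons, meas_seed)
    if angles_mask is not None:
        meas = GonioSignal(meas.angles_deg[angles_mask],
                           meas.intensity[angles_mask],
                           meas.n_photons[angles_mask], meas.reference, dict(meas.meta))
        fit_model = ForwardModel(model.domain_factory, angles_deg=meas.angles_deg,
                                 source=model.source, detector=model.detector,
                                 deltas=model.deltas, is_frac=model.is_frac)
    else:
        fit_model = model
    cases = []
    for k in range(n_starts):
        # restarts are part of the solver's own policy ("retry on
        # unsatisfactory minimization"); each study case exercises it
        fit = _fit_once(meas, fit_model, int(rng.integers(1, 2**31 - 1)),
                        n_photons, truth, g_bounds=g_bounds, max_restarts=2)
        cases.append({
            "start": k,
            **{f"fit_{n}": float(v) for n, v in fit.params.items()},
            "eps_p": parameter_error(fit.params, truth),
            "eps_fit": fit.epsilon_fit,
            "sigma": fit.sigma,
            "basin": "global" if fit.params["g"] > 0 else "local",
            "steps": len(fit.trajectory) - 1,
            "restarts": fit.restarts_used,
        })
    return StudyReport(
        "convergence_study",
        {"truth": truth, "n_photons": n_photons, "n_starts": n_starts,
         "g_bounds": str(g_bounds)},
        cases,
        {"measurement": meas_seed, "study": seed},
        time.time() - t0,
    )


def systematic_error_study(
    truth_model: ForwardModel,
    faulty_models: Dict[str, ForwardModel],
    truth: Dict[str, float] = None,
    n_photons: int = 20_000_000,
    seed: int = 1,
) -> StudyReport:
    """Fits with deliberately wrong fixed inputs (thickness, index...).

    ``faulty_models`` maps a scenario label to the forward model used during
    fitting; the measurement always comes from ``truth_model``.
    """
    t0 = time.time()
    truth = dict(CUVETTE_TRUTH if truth is None else truth)
    rng = np.random.default_rng(seed)
    meas_seed = int(rng.integers(1, 2**31 - 1))
    meas = generate_synthetic_measurement(truth_model, truth, n_photons, meas_seed)
    cases = []
    for label, fit_model in faulty_models.items():
        fit = _fit_once(meas, fit_model, int(rng.integers(1, 2**31 - 1)),
                        n_photons, truth, max_restarts=1)
        cases.append({
            "scenario": label,
            **{f"fit_{n}": float(v) for n, v in fit.params.items()},
            "eps_p": parameter_error(fit.params, truth),
            "eps_fit": fit.epsilon_fit,
            "sigma": fit.sigma,
        })
    return StudyReport(
        "systematic_error_study",
        {"truth": truth, "n_photons": n_photons},
        cases,
        {"measurement": meas_seed, "study": seed},
        time.time() - t0,
    )


def optical_depth_sweep(
    mus_list: Sequence[float] = (0.001, 0.01, 0.1, 0.5, 1.0, 3.0, 5.0, 10.0),
    mua: float = 0.1,
    g: float = 0.65,
    thickness_mm: float = 2.0,
    sigma_target=0.003,
    seed: int = 1,
    source=None,
    max_photons: int = 400_000_000,
) -> StudyReport:
    """Parameter recovery vs optical depth ``tau = mu_s * t``.

    A single index-matched layer (n = 1) is simulated and fitted per mu_s;
    reports per-parameter errors, the reduced-scattering error, fit error and
    noise.  The photon budget per case is calibrated to ``sigma_target``.
    """
    t0 = time.time()
    src = source if source is not None else instrument_source()
    rng = np.random.default_rng(seed)
    targets = (list(sigma_target) if np.ndim(sigma_target) else
               [float(sigma_target)] * len(mus_list))
    cases = []
    for mus, sig_t in zip(mus_list, targets):
        model = slab_model(thickness_mm=thickness_mm, n_med=1.0, source=src, is_frac=0.25)
        truth = {"mua": mua, "mus": mus, "g": g}
        n_meas = min(budget_for_noise(model, truth, sig_t,
                                      int(rng.integers(1, 2**31 - 1))), max_photons)
        meas_seed = int(rng.integers(1, 2**31 - 1))
        meas = generate_synthetic_measurement(model, truth, n_meas, meas_seed)
        x0 = {"mua": mua * 1.5, "mus": mus * 0.7, "g": min(g * 1.2, 0.95)}
        fit = _fit_once(meas, model, int(rng.integers(1, 2**31 - 1)), n_meas,
                        truth, x0=x0, iter_frac=10, max_steps=12, max_restarts=2,
                        n_final=max(n_meas // 2, 200_000))
        musp_t = mus * (1.0 - g)
        musp_f = fit.params["mus"] * (1.0 - fit.params["g"])
        cases.append({
            "mus": mus,
            "tau": mus * thickness_mm,
            "n_photons": n_meas,
            **{f"fit_{n}": float(v) for n, v in fit.params.items()},
            "err_mua": abs(fit.params["mua"] - mua) / mua,
            "err_mus": abs(fit.params["mus"] - mus) / mus,
            "err_g": abs(fit.params["g"] - g) / g,
            "err_musp": abs(musp_f - musp_t) / musp_t,
            "eps_p": parameter_error(fit.params, truth),
            "eps_fit": fit.epsilon_fit,
            "sigma": fit.sigma,
        })
    return StudyReport(
        "optical_depth_sweep",
        {"mua": mua, "g": g, "thickness_mm": thickness_mm,
         "sigma_target": sigma_target},
        cases,
        {"study": seed},
        time.time() - t0,
    )
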