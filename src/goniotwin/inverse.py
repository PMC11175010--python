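"""Inverse solver: recover (mu_a, mu_s, g) from a goniometric signal.

The measured and simulated signals span several orders of magnitude between
the ballistic peak and large-angle scattering, so the residual is formed in
log-relative space,

    C_i = (log MC_i - log E_i) / log E_i ,

and minimized by a Levenberg-Marquardt loop whose Jacobian comes from the
single-run perturbation derivatives (no extra simulations per parameter).
Parameters are optimized in an unbounded internal space linked to the
physical (bounded) space by the MINUIT-style transforms; the chain-rule
factor dPB/dPI multiplies each Jacobian column.  Because the forward model
is stochastic, every iteration inside one fit re-runs the simulation with a
fixed per-fit seed (common random numbers), which makes the cost surface
deterministic for the optimizer; the quality of the converged fit is then
judged against fresh-seed runs.

Fit-quality metrics:

* parameter error  eps_p  = mean over parameters of |p_fit - p_true| / p_true
* fit error        eps_fit = rms of (MC_fit - MC_fwd) / MC_fwd
* simulation noise sigma  = mean over angles of sqrt(1/N_fwd + 1/N_fit)

A converged fit should reach eps_fit of the order of sigma; if it stays above
``3 sigma`` the solver restarts from fresh random initial parameters (up to
``max_restarts`` times).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .detection import GonioSignal
from .forward import ForwardModel, ForwardResult

__all__ = [
    "BoundSpec",
    "FitProblem",
    "FitResult",
    "cost",
    "cost_gradient",
    "to_internal",
    "to_bounded",
    "bound_scale",
    "levenberg_marquardt",
    "parameter_error",
    "fit_error",
    "simulation_noise",
]


# ---------------------------------------------------------------------------
# Bound transforms (internal <-> bounded parameter space)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundSpec:
    """Parameter bounds: kind in {'free', 'lower', 'upper', 'both'}."""

    kind: str = "free"
    a: float = float("nan")
    b: float = float("nan")

    def __post_init__(self):
        if self.kind not in ("free", "lower", "upper", "both"):
            raise ValueError(f"unknown bound kind {self.kind!r}")
        if self.kind == "both" and not self.a < self.b:
            raise ValueError("need a < b for a two-sided bound")

    @staticmethod
    def lower(a: float) -> "BoundSpec":
        return BoundSpec("lower", a=a)

    @staticmethod
    def upper(b: float) -> "BoundSpec":
        return BoundSpec("upper", b=b)

    @staticmethod
    def interval(a: float, b: float) -> "BoundSpec":
        return BoundSpec("both", a=a, b=b)


def to_internal(pb: float, bound: BoundSpec) -> float:
    """Map a bounded parameter value to the internal unbounded space."""
    if bound.kind == "free":
        return pb
    if bound.kind == "lower":
        if pb < bound.a:
            raise ValueError(f"value {pb} below lower bound {bound.a}")
        return math.sqrt((pb - bound.a + 1.0) ** 2 - 1.0)
    if bound.kind == "upper":
        if pb > bound.b:
            raise ValueError(f"value {pb} above upper bound {bound.b}")
        return math.sqrt((bound.b - pb + 1.0) ** 2 - 1.0)
    if not bound.a <= pb <= bound.b:
        raise ValueError(f"value {pb} outside [{bound.a}, {bound.b}]")
    return math.asin(2.0 * (pb - bound.a) / (bound.b - bound.a) - 1.0)


def to_bounded(pi: float, bound: BoundSpec) -> float:
    """Map an internal parameter value back to the bounded space."""
    if bound.kind == "free":
        return pi
    if bound.kind == "lower":
        # grouped so that the result is exactly >= a in floating point
        return bound.a + (math.sqrt(pi * pi + 1.0) - 1.0)
    if bound.kind == "upper":
        return bound.b - (math.sqrt(pi * pi + 1.0) - 1.0)
    return bound.a + (bound.b - bound.a) * (math.sin(pi) + 1.0) / 2.0


def bound_scale(pi: float, bound: BoundSpec) -> float:
    """Chain-rule factor dPB/dPI at the internal value ``pi``."""
    if bound.kind == "free":
        return 1.0
    if bound.kind == "lower":
        return pi / math.sqrt(pi * pi + 1.0)
    if bound.kind == "upper":
        return -pi / math.sqrt(pi * pi + 1.0)
    return (bound.b - bound.a) / 2.0 * math.cos(pi)


# ---------------------------------------------------------------------------
# Cost and metrics
# ---------------------------------------------------------------------------

def cost(mc, e) -> np.ndarray:
    """Log-relative residual ``(log MC - log E) / log E`` elementwise.

    Both signals must be strictly positive and E must not equal 1 anywhere
    (log E = 0 would blow up the denominator; the 0-degree normalization
    point is excluded from fits for that reason).
    """
    mc = np.asarray(mc, dtype=float)
    e = np.asarray(e, dtype=float)
    bad = np.flatnonzero((mc <= 0) | (e <= 0))
    if bad.size:
        raise ValueError(f"non-positive intensity at index {bad[0]}")
    log_e = np.log(e)
    if np.any(log_e == 0.0):
        raise ValueError("log E = 0 encountered; exclude that angle from the mask")
    return (np.log(mc) - log_e) / log_e


def cost_gradient(mc, e, dmc_dp, scale: float = 1.0) -> np.ndarray:
    """Jacobian column ``dC/dPI = dMC/dp / (MC log E) * dPB/dPI``."""
    mc = np.asarray(mc, dtype=float)
    e = np.asarray(e, dtype=float)
    log_e = np.log(e)
    if np.any(log_e == 0.0):
        raise ValueError("log E = 0 encountered; exclude that angle from the mask")
    return np.asarray(dmc_dp, dtype=float) / (mc * log_e) * scale


def parameter_error(fitted: Dict[str, float], truth: Dict[str, float]) -> float:
    """Mean absolute relative deviation over the three optical parameters."""
    errs = []
    for key in ("mua", "mus", "g"):
        if truth[key] == 0.0:
            raise ValueError(f"truth parameter {key} is zero; relative error undefined")
        errs.append(abs(fitted[key] - truth[key]) / abs(truth[key]))
    return float(np.mean(errs))


def fit_error(mc_fit, mc_forward) -> float:
    """RMS relative deviation between fitted and forward-truth signals."""
    mc_fit = np.asarray(mc_fit, dtype=float)
    mc_forward = np.asarray(mc_forward, dtype=float)
    return float(np.sqrt(np.mean(((mc_fit - mc_forward) / mc_forward) ** 2)))


def simulation_noise(counts_forward, counts_fit) -> float:
    """Counting-noise estimate: mean of sqrt(1/N_fwd + 1/N_fit) over angles."""
    nf = np.asarray(counts_forward, dtype=float)
    ng = np.asarray(counts_fit, dtype=float)
    if np.any(nf <= 0) or np.any(ng <= 0):
        raise ValueError("photon counts must be positive on fitted angles")
    return float(np.mean(np.sqrt(1.0 / nf + 1.0 / ng)))


# ---------------------------------------------------------------------------
# Levenberg-Marquardt with multi-start
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS = {
    "mua": BoundSpec.lower(0.0),
    "mus": BoundSpec.lower(0.0),
    "g": BoundSpec.interval(0.0, 1.0),
}

_DEFAULT_START_RANGES = {
    "mua": (0.01, 1.0),   # log-uniform
    "mus": (0.01, 1.0),   # log-uniform
    "g": (0.05, 0.95),    # uniform
}


@dataclass
class FitProblem:
    """A measured signal plus the forward model and fitting policy."""

    measurement: GonioSignal
    model: ForwardModel
    free: Dict[str, BoundSpec] = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    x0: Optional[Dict[str, float]] = None
    fixed: Dict[str, float] = field(default_factory=dict)
    n_photons_iter: int = 1_000_000
    n_photons_final: Optional[int] = None
    max_steps: int = 15
    xtol: float = 1e-3
    lm_lambda0: float = 1e-3
    max_restarts: int = 5
    seed: int = 0
    start_ranges: Dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_START_RANGES))

    def fitted_mask(self) -> np.ndarray:
        e = self.measurement.intensity
        mask = (e > 0) & (np.abs(np.log(np.where(e > 0, e, 1.0))) > 1e-9)
        mask &= self.measurement.n_photons > 0
        n_free = len(self.free)
        if mask.sum() < n_free:
            raise ValueError("fewer usable angles than free parameters")
        return mask


@dataclass
class FitResult:
    params: Dict[str, float]
    trajectory: list
    cost_norm: float
    epsilon_fit: float
    sigma: float
    converged: bool
    restarts_used: int
    n_simulations: int
    final: Optional[ForwardResult] = None

    def summary(self) -> str:
        pars = ", ".join(f"{k}={v:.6g}" for k, v in self.params.items())
        return (
            f"fit {'converged' if self.converged else 'NOT converged'}: {pars}; "
            f"|C|={self.cost_norm:.4g}, eps_fit={100*self.epsilon_fit:.3g}%, "
            f"sigma={100*self.sigma:.3g}%, restarts={self.restarts_used}, "
            f"simulations={self.n_simulations}"
        )


def _random_start(problem: FitProblem, rng: np.random.Generator) -> Dict[str, float]:
    start = {}
    for name in problem.free:
        lo, hi = problem.start_ranges[name]
        if name in ("mua", "mus"):
            start[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            start[name] = float(rng.uniform(lo, hi))
    return start


def _simulate(problem: FitProblem, params: Dict[str, float], n_photons: int, seed: int):
    full = dict(problem.fixed)
    full.update(params)
    return problem.model.simulate(full["mua"], full["mus"], full["g"], n_photons, seed)


def _floor_intensity(intensity: np.ndarray, res: ForwardResult) -> np.ndarray:
    # guard against empty detector bins during low-budget iterations: half a
    # photon's worth of weight keeps the log finite without noticeable bias
    floor = 0.5 / (res.n_launched * res.reference_per_photon)
    return np.maximum(intensity, floor)


def _one_lm_run(problem: FitProblem, start: Dict[str, float], mask: np.ndarray,
                run_seed: int):
    """One LM descent from a fixed start; common random numbers per run."""
    names = list(problem.free)
    bounds = problem.free
    e = problem.measurement.intensity[mask]
    log_e = np.log(e)
    pi = np.array([to_internal(start[n], bounds[n]) for n in names])
    lam = problem.lm_lambda0
    n_sim = 0

    def evaluate(pi_vec):
        nonlocal n_sim
        params = {n: to_bounded(v, b) for n, v, b in zip(names, pi_vec, map(bounds.get, names))}
        # absurd proposals (mu beyond any physical phantom) are rejected
        # without burning a simulation; the damping loop then shrinks the step
        if any(not np.isfinite(v) for v in params.values()) or \
           params.get("mua", 0.0) > 1e3 or params.get("mus", 0.0) > 1e3:
            return params, None, None, None
        res = _simulate(problem, params, problem.n_photons_iter, run_seed)
        n_sim += 1
        mc = _floor_intensity(res.signal.intensity, res)[mask]
        c = (np.log(mc) - log_e) / log_e
        return params, res, mc, c

    params, res, mc, c = evaluate(pi)
    norm = float(np.linalg.norm(c))
    trajectory = [{**params, "cost_norm": norm}]
    converged = False
    for _ in range(problem.max_steps):
        jac = np.empty((mc.size, len(names)))
        for j, n in enumerate(names):
            dmc = res.derivative(n)[mask]
            jac[:, j] = dmc / (mc * log_e) * bound_scale(pi[j], bounds[n])
        jtj = jac.T @ jac
        jtc = jac.T @ c
        accepted = False
        for _try in range(12):
            aug = jtj + lam * np.diag(np.clip(np.diag(jtj), 1e-12, None))
            try:
                step = np.linalg.solve(aug, -jtc)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            if not np.all(np.isfinite(step)):
                lam *= 10.0
                continue
            # internal coordinates are O(1); cap runaway steps (trust region)
            step = np.clip(step, -20.0, 20.0)
            params_new, res_new, mc_new, c_new = evaluate(pi + step)
            if res_new is None:
                lam *= 10.0
                continue
            norm_new = float(np.linalg.norm(c_new))
            if norm_new < norm:
                accepted = True
                lam = max(lam / 10.0, 1e-12)
                rel = np.max(np.abs(np.array([params_new[n] for n in names])
                                    - np.array([params[n] for n in names]))
                             / np.maximum(np.abs(np.array([params[n] for n in names])), 1e-12))
                pi = pi + step
                params, res, mc, c, norm = params_new, res_new, mc_new, c_new, norm_new
                trajectory.append({**params, "cost_norm": norm})
                if rel < problem.xtol:
                    converged = True
                break
            lam *= 10.0
        if not accepted or converged:
            converged = converged or accepted
            if not accepted:
                converged = True  # damping exhausted: local stationary point
            break
    return params, trajectory, norm, n_sim


def levenberg_marquardt(problem: FitProblem) -> FitResult:
    """Bounded LM fit with random multi-start fallback.

    A run counts as satisfactory when its fresh-seed fit error is below three
    times the counting-noise level of the compared runs; otherwise the solver
    restarts from new random initial parameters.
    """
    mask = problem.fitted_mask()
    rng = np.random.default_rng(problem.seed)
    n_final = problem.n_photons_final or problem.n_photons_iter
    best = None
    total_sims = 0
    restarts = 0
    for attempt in range(problem.max_restarts + 1):
        if attempt == 0 and problem.x0 is not None:
            start = dict(problem.x0)
        else:
            start = _random_start(problem, rng)
        run_seed = int(rng.integers(1, 2**31 - 1))
        params, trajectory, norm, n_sim = _one_lm_run(problem, start, mask, run_seed)
        total_sims += n_sim
        # judge with a fresh seed at the final budget
        final = _simulate(problem, params, n_final, int(rng.integers(1, 2**31 - 1)))
        total_sims += 1
        mc = _floor_intensity(final.signal.intensity, final)[mask]
        eps = fit_error(mc, problem.measurement.intensity[mask])
        counts_fit = np.maximum(final.signal.n_photons[mask], 1)
        counts_meas = np.maximum(problem.measurement.n_photons[mask], 1)
        sigma = simulation_noise(counts_meas, counts_fit)
        result = FitResult(params, trajectory, norm, eps, sigma, eps <= 3.0 * sigma,
                           restarts, total_sims, final)
        if best is None or result.epsilon_fit < best.epsilon_fit:
            best = result
        if result.converged:
            return result
        restarts += 1
    best.restarts_used = restarts
    return best
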