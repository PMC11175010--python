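"""Forward-model orchestration and the scripted studies (desk scale)."""

import numpy as np
import pytest

from goniotwin.detection import read_signal
from goniotwin.forward import cuvette_model, pencil_source, slab_model
from goniotwin.studies import (
    CUVETTE_TRUTH,
    budget_for_noise,
    generate_synthetic_measurement,
    scan_error_function,
)


@pytest.fixture(scope="module")
def model():
    return cuvette_model(source=pencil_source(), is_frac=0.25)


class TestSyntheticMeasurement:
    def test_bit_identical_files_for_same_seed(self, model, tmp_path):
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        generate_synthetic_measurement(model, CUVETTE_TRUTH, 300_000, 7, path=p1)
        generate_synthetic_measurement(model, CUVETTE_TRUTH, 300_000, 7, path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self, model, tmp_path):
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        generate_synthetic_measurement(model, CUVETTE_TRUTH, 300_000, 7, path=p1)
        generate_synthetic_measurement(model, CUVETTE_TRUTH, 300_000, 8, path=p2)
        assert p1.read_bytes() != p2.read_bytes()

    def test_quadrupling_photons_halves_noise(self, model):
        s1 = generate_synthetic_measurement(model, CUVETTE_TRUTH, 500_000, 3)
        s4 = generate_synthetic_measurement(model, CUVETTE_TRUTH, 2_000_000, 4)
        sig1 = float(s1.meta["sigma_matched_counts"])
        sig4 = float(s4.meta["sigma_matched_counts"])
        assert sig1 / sig4 == pytest.approx(2.0, rel=0.10)

    def test_header_sigma_matches_counts(self, model, tmp_path):
        path = tmp_path / "m.txt"
        generate_synthetic_measurement(model, CUVETTE_TRUTH, 400_000, 11, path=path)
        back = read_signal(path)
        recomputed = float(np.mean(np.sqrt(2.0 / np.maximum(back.n_photons, 1))))
        assert float(back.meta["sigma_matched_counts"]) == recomputed


class TestBudgetCalibration:
    def test_budget_scaling_law(self, model):
        n1 = budget_for_noise(model, CUVETTE_TRUTH, 0.02, seed=5)
        n2 = budget_for_noise(model, CUVETTE_TRUTH, 0.01, seed=5)
        assert n2 / n1 == pytest.approx(4.0, rel=0.01)

    def test_calibrated_budget_hits_target(self, model):
        target = 0.01
        n = budget_for_noise(model, CUVETTE_TRUTH, target, seed=5)
        sig = generate_synthetic_measurement(model, CUVETTE_TRUTH, n, 6)
        achieved = float(sig.meta["sigma_matched_counts"])
        assert achieved == pytest.approx(target, rel=0.12)


class TestForwardModel:
    def test_ballistic_transmission_closed_form(self, model):
        import math

        res = model.simulate(0.1, 0.15, 0.75, 2_000_000, 17)
        t_glass = 1 - ((1 - 1.51) / (2.51)) ** 2
        t_med = 1 - ((1.33 - 1.51) / (2.84)) ** 2
        expect = t_glass**2 * t_med**2 * math.exp(-0.25 * 2.0)
        assert res.signal.intensity[0] == pytest.approx(expect, rel=0.01)

    def test_energy_bookkeeping(self, model):
        res = model.simulate(0.1, 0.15, 0.75, 500_000, 23)
        absorbed, side, exited, runaway, entered = res.counters
        # every launched photon ends in exactly one terminal category
        # (entry-reflected photons count as exited)
        assert absorbed + side + exited + runaway == 500_000
        assert runaway == 0
        assert entered <= 500_000

    def test_seed_reproducibility(self, model):
        a = model.simulate(0.1, 0.15, 0.75, 200_000, 9)
        b = model.simulate(0.1, 0.15, 0.75, 200_000, 9)
        np.testing.assert_array_equal(a.signal.n_photons, b.signal.n_photons)
        np.testing.assert_array_equal(a.signal.intensity, b.signal.intensity)

    def test_importance_sampling_unbiased(self):
        """Signals with and without the first-event angle flattening agree
        within Monte Carlo error at every angle."""
        m_is = cuvette_model(source=pencil_source(), is_frac=0.5)
        m_no = cuvette_model(source=pencil_source(), is_frac=0.0)
        n = 4_000_000
        a = m_is.simulate(0.1, 0.15, 0.75, n, 71)
        b = m_no.simulate(0.1, 0.15, 0.75, n, 72)
        se = np.sqrt(a.intensity_se() ** 2 + b.intensity_se() ** 2)
        sel = (a.signal.n_photons > 100) & (b.signal.n_photons > 100)
        z = np.abs(a.signal.intensity - b.signal.intensity)[sel] / se[sel]
        assert np.quantile(z, 0.99) < 3.5

    def test_variance_reduction_factor_exceeds_10(self, model):
        """Azimuth-integrated weighting vs Bernoulli azimuth detection at the
        same photon budget: variance reduced by > 10x at mid/backward angles."""
        from goniotwin.detection import DetectorSpec, azimuthal_weight

        res = model.simulate(0.1, 0.15, 0.75, 1, 1)  # warm model
        rng = np.random.default_rng(5)
        # exit angles drawn from the forward model's scattered distribution
        from goniotwin.sample import cuvette, propagate_reference
        from goniotwin.optics import Bundle

        dom = cuvette(0.1, 0.15, 0.75)
        theta, _, _ = propagate_reference(Bundle.empty(300_000), dom,
                                          np.random.default_rng(2))
        theta = theta[np.isfinite(theta)]
        for angle in (40.0, 60.0, 130.0):
            det = DetectorSpec(angle)
            w = azimuthal_weight(theta, det)
            # chip detection is the Bernoulli version of the same weight:
            # indicator variance E[w] - E[w]^2 vs weighted variance E[w^2] - E[w]^2
            var_w = np.mean(w**2) - np.mean(w) ** 2
            var_b = np.mean(w) - np.mean(w) ** 2
            assert var_b / max(var_w, 1e-300) > 10.0


class TestScan:
    def test_isotropic_truth_minimum_near_zero(self, model):
        """Self-consistency: with isotropic truth the landscape minimum sits
        at g ~ 0."""
        rep = scan_error_function(
            model,
            truth={"mua": 0.1, "mus": 0.3, "g": 0.0},
            g_grid=np.arange(-0.4, 0.41, 0.1),
            n_truth=2_000_000,
            n_scan=150_000,
            seed=3,
        )
        assert abs(rep.config["g_global_min"]) < 0.1

    def test_report_text_roundtrip(self, model, tmp_path):
        rep = scan_error_function(
            model,
            truth={"mua": 0.1, "mus": 0.3, "g": 0.0},
            g_grid=np.arange(-0.2, 0.21, 0.1),
            n_truth=400_000,
            n_scan=100_000,
            seed=3,
        )
        path = tmp_path / "rep.txt"
        rep.write(path)
        text = path.read_text()
        assert "scan_error_function" in text
        assert "cost_norm" in text


def test_convergence_study_positive_g_reaches_global_basin(model):
    """With g restricted to (0, 1), random starts converge to the true
    parameters (the spurious negative-g basin is unreachable)."""
    from goniotwin.studies import convergence_study

    rep = convergence_study(model, n_starts=2, n_photons=4_000_000, seed=11)
    assert len(rep.cases) == 2
    for case in rep.cases:
        assert case["basin"] == "global"
        assert case["eps_p"] < 0.05
        assert 0.0 < case["fit_g"] < 1.0


def test_thickness_misspecification_rescales_coefficients():
    """Fitting with a 10% thicker medium against a thinner truth: the
    attenuation products mu*t are (nearly) preserved, so both fitted
    coefficients drop by ~ t_true/t_fit = 1/1.1 while g barely moves."""
    from goniotwin.inverse import FitProblem, levenberg_marquardt
    from goniotwin.studies import generate_synthetic_measurement

    truth_model = cuvette_model(source=pencil_source(), is_frac=0.25)
    meas = generate_synthetic_measurement(
        truth_model, {"mua": 0.1, "mus": 0.15, "g": 0.75}, 12_000_000, 83
    )
    thick_model = cuvette_model(thickness_mm=2.2, source=pencil_source(), is_frac=0.25)
    fit = levenberg_marquardt(FitProblem(
        measurement=meas, model=thick_model,
        n_photons_iter=1_500_000, n_photons_final=12_000_000,
        seed=89, max_restarts=1, max_steps=10,
    ))
    assert fit.params["mua"] == pytest.approx(0.1 / 1.1, rel=0.06)
    assert fit.params["mus"] == pytest.approx(0.15 / 1.1, rel=0.06)
    assert fit.params["g"] == pytest.approx(0.75, abs=0.02)


def test_slab_model_index_matched_no_reflection():
    model = slab_model(source=pencil_source(), is_frac=0.25)
    res = model.simulate(0.0, 0.001, 0.65, 300_000, 3)
    # n = 1 everywhere: ballistic transmission = exp(-mu_s t), no interface loss
    assert res.signal.intensity[0] == pytest.approx(np.exp(-0.002), rel=0.005)
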