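"""Detection: azimuth-integrated weights, chip model, signals and files."""

import math

import numpy as np
import pytest

from goniotwin.detection import (
    DetectorSpec,
    GonioSignal,
    azimuthal_weight,
    bin_chip_counts,
    default_angle_grid,
    detect_chip,
    detect_integrated,
    normalize_to_reference,
    read_signal,
    write_signal,
)
from goniotwin.optics import Bundle


def brute_force_weight(theta_s_deg, det, n=10**6, seed=0):
    """MC oracle: fraction of uniform azimuths whose direction falls inside
    the detector's acceptance cone."""
    rng = np.random.default_rng(seed)
    ts = math.radians(theta_s_deg)
    td = math.radians(det.theta_deg)
    phi = 2 * np.pi * rng.random(n)
    s = np.stack([np.sin(ts) * np.cos(phi), np.sin(ts) * np.sin(phi),
                  np.full(n, math.cos(ts))])
    axis = np.array([math.sin(td), 0.0, math.cos(td)])
    frac = np.mean(axis @ s >= det.cos_theta_r)
    return frac


class TestAzimuthalWeight:
    def test_half_opening_angle(self):
        det = DetectorSpec(0.0)
        assert det.theta_r_deg == pytest.approx(1.19, abs=0.005)

    def test_outside_window_zero(self):
        det = DetectorSpec(30.0)
        assert azimuthal_weight(28.0, det) == 0.0
        assert azimuthal_weight(32.0, det) == 0.0

    @pytest.mark.parametrize("theta_d,theta_s", [
        (30.0, 30.5), (30.0, 29.2), (5.0, 5.0), (120.0, 120.9),
        (1.0, 0.5), (169.0, 168.2),
    ])
    def test_matches_brute_force_azimuth_mc(self, theta_d, theta_s):
        det = DetectorSpec(theta_d)
        w = azimuthal_weight(theta_s, det)
        n = 10**6
        frac = brute_force_weight(theta_s, det, n=n)
        se = math.sqrt(max(frac * (1 - frac), 1e-12) / n)
        assert abs(w - frac) <= max(3 * se, 2e-4)

    def test_wide_aperture_geometry(self):
        # non-instrument geometry exercises the |Phi| <= -1 branch
        det = DetectorSpec(10.0, distance_mm=20.0, aperture_radius_mm=8.0)
        assert azimuthal_weight(3.0, det) == 1.0  # cone contains whole circle
        frac = brute_force_weight(17.0, det)
        assert abs(azimuthal_weight(17.0, det) - frac) < 2e-3

    def test_degenerate_on_axis(self):
        det0 = DetectorSpec(0.0)
        assert azimuthal_weight(0.5, det0) == 1.0
        assert azimuthal_weight(1.5, det0) == 0.0
        det180 = DetectorSpec(180.0)
        assert azimuthal_weight(179.5, det180) == 1.0

    def test_axial_photon(self):
        assert azimuthal_weight(0.0, DetectorSpec(1.0)) == 1.0
        assert azimuthal_weight(0.0, DetectorSpec(2.0)) == 0.0

    def test_continuity_at_window_edges(self):
        det = DetectorSpec(40.0)
        tr = det.theta_r_deg
        eps = 1e-7
        inside = azimuthal_weight(40.0 + tr - eps, det)
        outside = azimuthal_weight(40.0 + tr + eps, det)
        assert inside < 1e-3 and outside == 0.0

    def test_solid_angle_conservation_isotropic(self, rng):
        """A dense detector tiling weighted by ring measure recovers the
        aperture solid-angle coverage for isotropic radiation (2-sphere
        integration oracle)."""
        det_angles = np.arange(0.5, 180.0, 1.0)
        dets = [DetectorSpec(a) for a in det_angles]
        n = 200_000
        u = 2 * rng.random(n) - 1
        theta_s = np.degrees(np.arccos(u))
        total = 0.0
        for det in dets:
            total += azimuthal_weight(theta_s, det).sum()
        # identity: for an isotropic direction, E[w_det] equals the spherical
        # cap fraction (1 - cos(theta_r)) / 2 of that detector's cone
        expected = sum(n * (1 - det.cos_theta_r) / 2.0 for det in dets)
        assert total == pytest.approx(expected, rel=0.02)


class TestIntegratedDetection:
    def test_locality(self):
        grid = default_angle_grid()
        sig = GonioSignal(grid, np.zeros(grid.size), np.zeros(grid.size, dtype=int))
        dets = [DetectorSpec(a) for a in grid]
        detect_integrated([30.0], dets, sig)
        hit = np.flatnonzero(sig.n_photons)
        assert np.all(np.abs(grid[hit] - 30.0) <= 1.2)
        assert sig.n_photons.sum() >= 1

    def test_nonzero_incidence_rejected(self):
        grid = default_angle_grid()
        sig = GonioSignal(grid, np.zeros(grid.size), np.zeros(grid.size, dtype=int))
        with pytest.raises(ValueError):
            detect_integrated([30.0], [], sig, incident_angle_deg=5.0)

    def test_equivalence_with_bernoulli_chip(self, rng):
        """Integrated-azimuth weighting and explicit azimuth sampling are
        unbiased estimators of the same per-angle expectation."""
        det = DetectorSpec(25.0)
        theta_s = 24.0 + 2.0 * rng.random(200_000)
        w = azimuthal_weight(theta_s, det)
        frac = []
        phi = 2 * np.pi * rng.random(theta_s.size)
        ts = np.radians(theta_s)
        td = math.radians(det.theta_deg)
        sx = np.sin(ts) * np.cos(phi)
        sz = np.cos(ts)
        dot = sx * math.sin(td) + sz * math.cos(td)
        bern = (dot >= det.cos_theta_r).astype(float)
        diff = w.mean() - bern.mean()
        se = np.sqrt(w.var() / w.size + bern.var() / bern.size)
        assert abs(diff) < 3 * se
        # and the weighted estimator has smaller variance
        assert w.var() < bern.var()


class TestChip:
    def test_axial_photon_center_pixel(self, rng):
        det = DetectorSpec(0.0)
        b = Bundle.empty(1)
        rows, cols, hit = detect_chip(b, det, rng)
        assert hit[0]
        chip = det.chip
        assert abs(rows[0] - chip.n_rows // chip.binning / 2) <= 1
        assert abs(cols[0] - chip.n_cols // chip.binning / 2) <= 1

    def test_binning_conserves_counts(self, rng):
        det = DetectorSpec(0.0)
        n = 5000
        b = Bundle.empty(n)
        b.x = 0.2 * rng.standard_normal(n)
        b.y = 0.2 * rng.standard_normal(n)
        rows, cols, hit = detect_chip(b, det, rng)
        img = bin_chip_counts(rows, cols, hit, det.chip)
        assert img.sum() == hit.sum()
        assert img.shape == (120, 192)

    def test_point_source_centroid_matches_paraxial_oracle(self, rng):
        """Off-axis point at the sample plane images to the chip position
        predicted by the ray-transfer matrix of the same prescription."""
        det = DetectorSpec(0.0)
        chip = det.chip
        n = 4000
        b = Bundle.empty(n)
        y0 = 0.6
        b.y[:] = y0
        # small cone of directions toward the detector
        th = 0.004 * np.sqrt(rng.random(n))
        ph = 2 * np.pi * rng.random(n)
        b.ux = th * np.cos(ph)
        b.uy = th * np.sin(ph)
        b.uz = np.sqrt(1 - b.ux**2 - b.uy**2)
        rows, cols, hit = detect_chip(b, det, rng)
        assert hit.sum() > 100
        pix_mm = chip.pixel_um * 1e-3 * chip.binning
        y_centroid = (rows[hit].mean() + 0.5) * pix_mm - 0.5 * chip.n_rows * chip.pixel_um * 1e-3
        # thin-lens oracle with the surrogate's cardinal points
        f = chip.lens_f_mm
        do = chip.lens_z_mm
        di_chip = chip.chip_z_mm - chip.lens_z_mm
        mag = -f / (do - f) * (1.0)  # image magnification for object at do
        y_pred = y0 * (f / (do - f)) * -1.0
        # allow generous tolerance: cover glass shifts the focus slightly
        assert y_centroid == pytest.approx(y_pred, abs=3 * pix_mm)


class TestNormalizationAndFiles:
    def _signal(self, rng, n=150):
        grid = default_angle_grid()
        inten = rng.random(grid.size) + 0.1
        counts = rng.integers(1, 1000, grid.size)
        return GonioSignal(grid, inten, counts, meta={"note": "test"})

    def test_self_normalization_at_zero(self, rng):
        sig = self._signal(rng)
        out = normalize_to_reference(sig, sig)
        assert out.intensity[0] == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        sig = self._signal(rng)
        ref = self._signal(rng)
        a = normalize_to_reference(sig, ref)
        sig2, ref2 = sig.copy(), ref.copy()
        sig2.intensity *= 7.0
        ref2.intensity *= 7.0
        b = normalize_to_reference(sig2, ref2)
        np.testing.assert_allclose(a.intensity, b.intensity)

    def test_zero_reference_rejected(self, rng):
        sig = self._signal(rng)
        ref = sig.copy()
        ref.intensity[:] = 0.0
        with pytest.raises(ValueError):
            normalize_to_reference(sig, ref)

    def test_file_roundtrip_exact(self, tmp_path, rng):
        sig = self._signal(rng)
        sig.reference = 0.1234
        path = tmp_path / "signal.txt"
        write_signal(sig, path)
        back = read_signal(path)
        np.testing.assert_array_equal(back.n_photons, sig.n_photons)
        np.testing.assert_allclose(back.intensity, sig.intensity, rtol=0, atol=0)
        assert back.reference == sig.reference
        assert back.meta["note"] == "test"
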