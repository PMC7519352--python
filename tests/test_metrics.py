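"""FWHM, depth-decay curves, 1/e depths, decay fits, detection limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flotsim import (
    AcquisitionSpec,
    DecayCurve,
    DetectionLimit,
    MeasurementStack,
    VoxelGrid,
    compare_flot_mip,
    depth_profile,
    fit_exponential,
    fwhm,
    limit_of_detection,
    max_detectable_depth,
    one_over_e_depth,
)
from flotsim.metrics import CapillaryTrack


def _curve(depths, values):
    return DecayCurve.from_samples(np.asarray(depths, float),
                                   np.asarray(values, float))


class TestOneOverEDepth:
    def test_analytic_exponential(self):
        z = np.arange(0, 2001, 10.0)
        c = _curve(z, np.exp(-z / 500.0))
        r = one_over_e_depth(c)
        assert r.reached and r.depth_um == pytest.approx(500.0, abs=1.0)

    def test_interpolated_crossing_matches_hand_computation(self):
        c = DecayCurve(np.array([0.0, 480.0, 520.0]),
                       np.array([1.0, 0.40, 0.35]))
        target = 1 / math.e
        expected = 480 + (0.40 - target) / (0.40 - 0.35) * 40.0
        r = one_over_e_depth(c)
        assert r.depth_um == pytest.approx(expected, abs=1e-9)

    def test_never_reached_flags_beyond_range(self):
        c = _curve([0, 100, 200], [1.0, 0.9, 0.8])
        r = one_over_e_depth(c)
        assert not r.reached and r.depth_um == 200.0

    def test_unnormalized_curve_rejected(self):
        c = DecayCurve(np.array([0.0, 10.0]), np.array([0.5, 0.4]))
        with pytest.raises(ValueError, match="normalized"):
            one_over_e_depth(c)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(0.1, 100.0))
    def test_invariant_to_uniform_rescaling_before_normalization(self, scale):
        z = np.arange(0, 1001, 20.0)
        raw = np.exp(-z / 300.0)
        a = one_over_e_depth(_curve(z, raw))
        b = one_over_e_depth(_curve(z, scale * raw))
        assert a.depth_um == pytest.approx(b.depth_um)

    def test_pointwise_dominating_curve_has_deeper_crossing(self):
        z = np.arange(0, 1501, 10.0)
        slow = _curve(z, np.exp(-z / 600.0))
        fast = _curve(z, np.exp(-z / 300.0))
        assert one_over_e_depth(slow).depth_um >= one_over_e_depth(fast).depth_um


class TestFitExponential:
    def test_noise_free_recovery_is_exact(self):
        z = np.arange(0, 1001, 25.0)
        c = _curve(z, 1.0 * np.exp(-2.0 * z / 1000.0))  # mu_eff = 2 /mm
        fit = fit_exponential(c)
        assert fit.I0 == pytest.approx(1.0, abs=1e-9)
        assert fit.mu_eff_per_mm == pytest.approx(2.0, abs=1e-9)

    def test_flat_curve_has_zero_decay(self):
        c = _curve(np.arange(0, 200, 10.0), np.ones(20))
        assert fit_exponential(c).mu_eff_per_mm == pytest.approx(0.0, abs=1e-12)

    def test_median_recovery_under_multiplicative_noise(self):
        z = np.arange(0, 1001, 20.0)
        true = np.exp(-1.5 * z / 1000.0)
        recovered = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = true * (1 + 0.05 * rng.standard_normal(len(z)))
            noisy[0] = 1.0
            recovered.append(fit_exponential(
                DecayCurve(z, np.maximum(noisy, 1e-9))).mu_eff_per_mm)
        assert np.median(recovered) == pytest.approx(1.5, rel=0.10)

    def test_all_nonpositive_rejected(self):
        c = DecayCurve(np.array([0.0, 10.0, 20.0]), np.array([0.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            fit_exponential(c)


class TestFwhm:
    def test_gaussian_closed_form(self):
        x = np.arange(-400.0, 401.0, 2.0)
        prof = np.exp(-0.5 * (x / 50.0) ** 2)
        expected = 2 * math.sqrt(2 * math.log(2)) * 50.0
        assert fwhm(x, prof) == pytest.approx(expected, rel=0.01)

    def test_tophat_convolved_with_gaussian_matches_numeric_oracle(self):
        dx = 1.0
        x = np.arange(-400.0, 401.0, dx)
        top = ((x >= -50) & (x <= 50)).astype(float)
        sig = 30.0 / (2 * math.sqrt(2 * math.log(2)))
        kern = np.exp(-0.5 * (np.arange(-150, 151, dx) / sig) ** 2)
        kern /= kern.sum()
        prof = np.convolve(top, kern, mode="same")
        # numeric half-crossing oracle on the convolved profile
        half = prof.max() / 2
        above = np.nonzero(prof >= half)[0]
        oracle = x[above[-1]] - x[above[0]]
        assert fwhm(x, prof) == pytest.approx(oracle, abs=2 * dx)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(bg=st.floats(0, 50), scale=st.floats(0.1, 10))
    def test_invariant_to_background_and_scale(self, bg, scale):
        x = np.arange(-300.0, 301.0, 5.0)
        prof = np.exp(-0.5 * (x / 60.0) ** 2)
        w0 = fwhm(x, prof)
        w1 = fwhm(x, scale * prof + bg)
        assert w1 == pytest.approx(w0, rel=1e-6)

    def test_truncated_profile_rejected(self):
        x = np.arange(0.0, 100.0, 5.0)
        prof = np.exp(-0.5 * ((x - 100) / 60.0) ** 2)  # peak at the edge
        with pytest.raises(ValueError, match="truncated"):
            fwhm(x, prof)


class TestDepthProfile:
    def _volume(self, fn):
        grid = VoxelGrid(60, 10, 50, 0.02)
        track = CapillaryTrack(
            x_mm=grid.x_centers,
            z_mm=np.clip((grid.x_centers - 0.1) * math.tan(math.radians(23.5)),
                         0, 0.98),
            y_mm=np.full(60, 0.1),
        )
        data = np.zeros(grid.shape)
        for i, (x, z) in enumerate(zip(track.x_mm, track.z_mm)):
            iz = min(int(z / 0.02), 49)
            data[i, 5, iz] = fn(z)
        return grid, track, data

    def test_constant_rod_gives_flat_curve(self):
        grid, track, data = self._volume(lambda z: 1.0)
        c = depth_profile(data, track, grid=grid)
        assert np.allclose(c.intensity, 1.0)

    def test_exponential_rod_reproduced(self):
        grid, track, data = self._volume(lambda z: math.exp(-z / 0.5))
        c = depth_profile(data, track, grid=grid)
        z0 = c.depth_um[0] / 1000.0
        expected = np.exp(-(c.depth_um / 1000.0 - z0) / 0.5)
        np.testing.assert_allclose(c.intensity, expected, rtol=0.05)


class TestDetectionLimit:
    def _blank(self, dark, read, seed=3):
        acq = AcquisitionSpec(n_positions=4, n_offset_px=64, n_along_px=64,
                              photon_scale=np.inf, read_noise=read,
                              dark_level=dark)
        rng = np.random.default_rng(seed)
        frames = np.clip(
            np.rint(dark + read * rng.standard_normal((4, 64, 64))), 0, 4095
        ).astype(np.uint16)
        return MeasurementStack(frames, acq)

    def test_noise_free_blank_threshold_equals_level(self):
        stack = self._blank(100.0, 0.0)
        lod = limit_of_detection(stack)
        assert lod.threshold == pytest.approx(100.0)

    def test_threshold_is_mean_plus_three_sigma(self):
        stack = self._blank(100.0, 5.0)
        lod = limit_of_detection(stack)
        assert lod.N == pytest.approx(100.0, rel=0.01)
        assert lod.threshold == pytest.approx(115.0, rel=0.02)

    def test_sigma_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            DetectionLimit(100.0, -1.0)

    def test_max_detectable_depth_interpolates_threshold_crossing(self):
        z = np.arange(0, 2001, 10.0)
        c = _curve(z, np.exp(-z / 400.0))
        lod = DetectionLimit(100.0, 5.0)
        # curve crosses 3*sigma/surface = 15/1000 at z = 400*ln(1000/15)
        expected = 400.0 * math.log(1000.0 / 15.0)
        got = max_detectable_depth(c, surface_counts=1000.0, lod=lod)
        assert got == pytest.approx(expected, abs=10.0)


class TestCompareReport:
    def test_identical_curves_ratio_one_and_dominates_everywhere(self):
        z = np.arange(0, 1001, 10.0)
        c = _curve(z, np.exp(-z / 400.0))
        rep = compare_flot_mip(c, c)
        assert rep["one_over_e_ratio"] == pytest.approx(1.0)
        assert rep["flot_dominates_from_um"] == 0.0
        assert rep["flot_dominates_to_um"] == 1000.0

    def test_analytic_pair_has_ratio_two(self):
        z = np.arange(0, 2001, 10.0)
        flot = _curve(z, np.exp(-z / 1000.0))
        mipc = _curve(z, np.exp(-z / 500.0))
        rep = compare_flot_mip(flot, mipc)
        assert rep["one_over_e_ratio"] == pytest.approx(2.0, rel=0.01)
        assert rep["mip_fit"]["mu_eff_per_mm"] == pytest.approx(2.0, rel=0.01)

    def test_disjoint_ranges_rejected(self):
        a = _curve([0, 100, 200], [1.0, 0.9, 0.8])
        b = DecayCurve(np.array([300.0, 400.0]), np.array([1.0, 0.9]))
        with pytest.raises(ValueError, match="disjoint"):
            compare_flot_mip(a, b)

    def test_replicate_statistics_reported(self):
        z = np.arange(0, 1001, 10.0)
        reps = []
        for tau in (380.0, 400.0, 420.0):
            reps.append((_curve(z, np.exp(-z / (2 * tau))),
                         _curve(z, np.exp(-z / tau))))
        rep = compare_flot_mip(*reps[0], replicates=reps)
        st_ = rep["replicates"]
        assert st_["n"] == 3
        assert st_["mip_one_over_e_um_mean"] == pytest.approx(400.0, rel=0.02)
        assert st_["flot_one_over_e_um_mean"] > st_["mip_one_over_e_um_mean"]
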