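"""Tests for psychometric fitting, probabilistic labeling and the optimal rater."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

import voxelgeom as vg
from voxelgeom.raters import DegenerateImageError, GridMismatchError


def make_image(values, grid):
    return vg.ImageVolume(np.asarray(values, dtype=float), grid, scaled=True)


@pytest.fixture(scope="module")
def flat_grid():
    # 10 x 10 x 100 voxels of 1 mm: a convenient 10^4-voxel container
    return vg.GridSpec((10.0, 10.0, 100.0), 1.0, 1.0)


class TestLogisticProbability:
    def test_zero_curve_gives_half(self):
        curve = vg.PsychometricCurve(0.0, 0.0)
        assert vg.logistic_probability(curve, 0.3) == pytest.approx(0.5)

    def test_midpoint_gives_half(self):
        curve = vg.PsychometricCurve(-6.0, 12.0)
        assert vg.logistic_probability(curve, curve.midpoint) == pytest.approx(0.5)

    def test_closed_form_value(self):
        curve = vg.PsychometricCurve(-6.0, 12.0)
        assert vg.logistic_probability(curve, 1.0) == pytest.approx(0.997527, abs=5e-7)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_probabilities_in_open_interval(self, i1, i2):
        curve = vg.PsychometricCurve(-2.0, 8.0)
        p1, p2 = curve.probability(i1), curve.probability(i2)
        assert 0.0 < p1 < 1.0
        if i1 <= i2:  # monotone increasing for positive slope
            assert p1 <= p2


class TestFitPsychometric:
    def test_parameter_recovery(self):
        # labels simulated from a known curve are recovered within 3 SE
        rng = np.random.default_rng(2024)
        truth = vg.PsychometricCurve(-6.0, 12.0)
        intensity = rng.uniform(0, 1, size=10_000)
        labels = rng.random(10_000) < truth.probability(intensity)
        fit = vg.fit_psychometric(intensity, labels)
        assert not fit.separated
        se0, se1 = fit.stderr
        assert abs(fit.curve.beta0 - truth.beta0) < 3 * se0
        assert abs(fit.curve.beta1 - truth.beta1) < 3 * se1

    def test_perfect_separation_flagged(self):
        intensity = np.linspace(0, 1, 200)
        labels = intensity > 0.5
        fit = vg.fit_psychometric(intensity, labels)
        assert fit.separated
        assert fit.curve.midpoint == pytest.approx(0.5, abs=0.01)

    def test_symmetric_data_midpoint(self):
        # symmetric sampling around 0.5 with p(0.5)=0.5 pins the midpoint
        rng = np.random.default_rng(7)
        truth = vg.PsychometricCurve(-5.0, 10.0)  # midpoint exactly 0.5
        intensity = np.concatenate([0.5 - rng.uniform(0, 0.5, 5000),
                                    0.5 + rng.uniform(0, 0.5, 5000)])
        labels = rng.random(10_000) < truth.probability(intensity)
        fit = vg.fit_psychometric(intensity, labels)
        assert fit.curve.midpoint == pytest.approx(0.5, abs=0.02)

    def test_fit_is_consistent_as_n_grows(self):
        rng = np.random.default_rng(11)
        truth = vg.PsychometricCurve(-6.0, 12.0)
        errs = []
        for n in (1_000, 100_000):
            intensity = rng.uniform(0, 1, size=n)
            labels = rng.random(n) < truth.probability(intensity)
            fit = vg.fit_psychometric(intensity, labels)
            errs.append(abs(fit.curve.beta1 - truth.beta1))
        assert errs[1] < errs[0]

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            vg.fit_psychometric([], [])
        with pytest.raises(ValueError):
            vg.fit_psychometric([0.1, 0.9], [1, 1])


class TestAverageCurves:
    def test_mean_of_coefficients(self):
        avg = vg.average_curves(
            [vg.PsychometricCurve(-4, 10), vg.PsychometricCurve(-6, 14)]
        )
        assert (avg.beta0, avg.beta1) == (-5.0, 12.0)

    def test_identity_and_permutation_invariance(self):
        curves = [vg.PsychometricCurve(-3, 9), vg.PsychometricCurve(-7, 15)]
        assert vg.average_curves(curves) == vg.average_curves(curves[::-1])
        assert vg.average_curves(curves[:1]) == curves[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vg.average_curves([])


class TestProbabilisticLabel:
    def test_saturated_curves(self, flat_grid):
        img = make_image(np.full(flat_grid.matrix_dims, 0.5), flat_grid)
        all_in = vg.probabilistic_label(img, vg.PsychometricCurve(50.0, 0.0), rng=0)
        none_in = vg.probabilistic_label(img, vg.PsychometricCurve(-50.0, 0.0), rng=0)
        assert all_in.count == img.data.size
        assert none_in.count == 0

    def test_expected_mode_thresholds_at_midpoint(self, flat_grid):
        rng = np.random.default_rng(3)
        img = make_image(rng.random(flat_grid.matrix_dims), flat_grid)
        curve = vg.PsychometricCurve(-6.0, 12.0)
        mask = vg.probabilistic_label(img, curve, mode="expected")
        assert np.array_equal(mask.data, img.data >= curve.midpoint)

    def test_count_within_binomial_envelope(self, flat_grid):
        # over seeded repeats the labeled count behaves binomially
        rng = np.random.default_rng(5)
        img = make_image(rng.random(flat_grid.matrix_dims), flat_grid)
        curve = vg.PsychometricCurve(-3.0, 6.0)
        p = curve.probability(img.data)
        mean, var = p.sum(), (p * (1 - p)).sum()
        counts = np.array(
            [vg.probabilistic_label(img, curve, rng=seed).count for seed in range(100)]
        )
        z99 = 2.576
        lo, hi = mean - z99 * np.sqrt(var), mean + z99 * np.sqrt(var)
        inside = np.sum((counts >= lo) & (counts <= hi))
        assert inside >= 95  # ~99% of 100 repeats, generous floor

    def test_stochastic_monotonicity_in_intensity(self, flat_grid):
        # inclusion frequency rises with intensity for a monotone curve
        levels = np.linspace(0, 1, 10)
        data = np.repeat(levels, np.prod(flat_grid.matrix_dims) // levels.size)
        img = make_image(data.reshape(flat_grid.matrix_dims), flat_grid)
        curve = vg.PsychometricCurve(-4.0, 8.0)
        freq = np.zeros_like(img.data)
        for seed in range(50):
            freq += vg.probabilistic_label(img, curve, rng=seed).data
        rate = np.array([freq[np.isclose(img.data, lv)].mean() / 50 for lv in levels])
        assert np.all(np.diff(rate) > -0.05)  # monotone up to sampling noise

    def test_seed_reproducibility(self, flat_grid):
        rng = np.random.default_rng(9)
        img = make_image(rng.random(flat_grid.matrix_dims), flat_grid)
        curve = vg.PsychometricCurve(-4.0, 8.0)
        a = vg.probabilistic_label(img, curve, rng=42)
        b = vg.probabilistic_label(img, curve, rng=42)
        assert np.array_equal(a.data, b.data)


class TestConjunctMask:
    def test_algebraic_identities(self, flat_grid):
        rng = np.random.default_rng(1)
        a = vg.LabelMask(rng.random(flat_grid.matrix_dims) < 0.3, flat_grid)
        b = vg.LabelMask(rng.random(flat_grid.matrix_dims) < 0.5, flat_grid)
        empty = vg.LabelMask(np.zeros(flat_grid.matrix_dims, bool), flat_grid)
        assert np.array_equal(vg.conjunct_mask(a, a).data, a.data)
        assert vg.conjunct_mask(a, empty).count == 0
        joint = vg.conjunct_mask(a, b)
        assert joint.volume <= min(a.volume, b.volume)

    def test_grid_mismatch_rejected(self, flat_grid):
        other = vg.GridSpec((10.0, 10.0, 100.0), 2.0, 1.0)
        a = vg.LabelMask(np.zeros(flat_grid.matrix_dims, bool), flat_grid)
        b = vg.LabelMask(np.zeros(other.matrix_dims, bool), other)
        with pytest.raises(GridMismatchError):
            vg.conjunct_mask(a, b)


class TestOptimalRater:
    def brute_force_survival(self, values, t):
        return np.mean(values >= t)

    def test_threshold_interpolates_between_levels(self, flat_grid):
        # three-level image: survival is 0.03 at 1.0 and 0.05 at 0.5, so the
        # 0.04 target must interpolate strictly between the two levels
        values = np.concatenate(
            [np.ones(300), np.full(200, 0.5), np.zeros(9500)]
        )
        img = make_image(values.reshape(flat_grid.matrix_dims), flat_grid)
        t = vg.optimal_threshold(img, 0.04)
        assert 0.5 < t < 1.0
        assert t == pytest.approx(0.75)  # linear between the two survival points
        assert self.brute_force_survival(values, 0.5) == pytest.approx(0.05)
        assert self.brute_force_survival(values, 1.0) == pytest.approx(0.03)

    def test_tiny_target_lands_just_below_max(self, flat_grid):
        rng = np.random.default_rng(13)
        values = rng.random(np.prod(flat_grid.matrix_dims))
        img = make_image(values.reshape(flat_grid.matrix_dims), flat_grid)
        n = values.size
        t = vg.optimal_threshold(img, 1.5 / n)
        top2 = np.sort(values)[-2:]
        assert top2[0] <= t <= top2[1]

    def test_constant_image_rejected(self, flat_grid):
        img = make_image(np.full(flat_grid.matrix_dims, 0.5), flat_grid)
        with pytest.raises(DegenerateImageError):
            vg.optimal_threshold(img, 0.1)

    def test_default_design_target_proportion(self):
        # ground-truth proportion of the 36 mm FoV cube
        e = vg.default_ellipsoid()
        assert e.volume / 36.0**3 == pytest.approx(0.003535, abs=5e-6)

    def test_fine_grid_volume_recovery(self, small_ellipsoid, small_fov):
        # at 0.1 mm voxels the discrete mask volume is within 1% of truth
        grid = vg.GridSpec(small_fov, 0.1, 1.0)
        img = vg.reconstruct(vg.analytic_kspace(small_ellipsoid, grid=grid))
        res = vg.optimal_label(img, small_ellipsoid)
        assert res.mask.volume == pytest.approx(small_ellipsoid.volume, rel=0.01)
        assert res.continuous_volume == pytest.approx(small_ellipsoid.volume, rel=1e-12)

    def test_coarse_grid_within_one_voxel_of_optimum(self, ellipsoid):
        grid = vg.GridSpec((36.0,) * 3, 2.0, 1.0)
        img = vg.reconstruct(vg.analytic_kspace(ellipsoid, grid=grid))
        res = vg.optimal_label(img, ellipsoid)
        # brute force over all voxel-count thresholds
        best = np.inf
        for k in range(1, img.data.size):
            best = min(best, abs(k * grid.voxel_volume - ellipsoid.volume))
        achieved = abs(res.mask.volume - ellipsoid.volume)
        assert achieved <= best + grid.voxel_volume

    def test_optimal_on_oracle_recovers_truth_mask(self, small_ellipsoid, small_fov):
        # thresholding the exact partial-volume image recovers the analytic
        # membership mask nearly perfectly at fine resolution
        grid = vg.GridSpec(small_fov, 0.1, 1.0)
        frac = vg.rasterize_oracle(small_ellipsoid, grid=grid, subdivisions=2)
        res = vg.optimal_label(frac, small_ellipsoid)
        membership = vg.LabelMask(
            vg.rasterize_oracle(small_ellipsoid, grid=grid, subdivisions=1).data > 0.5,
            grid,
        )
        assert vg.dice(res.mask, membership) > 0.99


class TestRaterSpec:
    def test_optimal_carries_no_curve(self):
        with pytest.raises(ValueError):
            vg.RaterSpec("optimal", vg.DEFAULT_LIBERAL)

    def test_psychometric_requires_curve(self):
        with pytest.raises(ValueError):
            vg.RaterSpec("liberal")

    def test_default_raters_ordering(self):
        liberal, joint, optimal = vg.default_raters()
        assert liberal.curve.midpoint < joint.curve.midpoint
        assert optimal.kind == "optimal"
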