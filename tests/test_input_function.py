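import numpy as np
import pytest

from petkin.core import BloodSampleTable, ParentFractionTable
from petkin.errors import DataError
from petkin.input_function import (
    build_input_function,
    default_fine_grid,
    fit_parent_fraction_3exp,
    input_function_from_tables,
    merge_blood_curves,
    plasma_over_blood,
)
from petkin.simulate import ParentFractionParams, simulate_parent_fraction


def _abss(values_fn):
    t = np.arange(0.0, 10.0 + 1e-9, 1.0 / 60.0)
    return BloodSampleTable(t, values_fn(t), source="automatic")


def _manual(values_fn, plasma_fn=None, times=(2.0, 4, 6, 8, 10, 15, 20, 30, 45, 60, 90)):
    t = np.asarray(times, float)
    plasma = plasma_fn(t) if plasma_fn else None
    return BloodSampleTable(t, values_fn(t), plasma, "manual")


class TestMergeBloodCurves:
    def test_identical_overlap_gives_unit_factor(self):
        f = lambda t: 10 * np.exp(-0.1 * t) + 1
        merged = merge_blood_curves(_abss(f), _manual(f))
        assert merged.calibration_factor == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(merged(np.array([5.0, 30.0])), f(np.array([5.0, 30.0])), rtol=1e-6)

    def test_doubled_abss_rescaled_by_half(self):
        f = lambda t: 10 * np.exp(-0.1 * t) + 1
        merged = merge_blood_curves(_abss(lambda t: 2 * f(t)), _manual(f))
        assert merged.calibration_factor == pytest.approx(0.5, rel=1e-12)
        assert merged(5.0) == pytest.approx(f(5.0), rel=1e-9)

    def test_no_overlap_warns_and_skips_calibration(self):
        f = lambda t: 10 * np.exp(-0.1 * t) + 1
        late = _manual(f, times=(15.0, 30, 60, 90))
        with pytest.warns(UserWarning, match="cross-calibration"):
            merged = merge_blood_curves(_abss(f), late)
        assert merged.calibration_factor == 1.0
        assert not merged.calibrated

    def test_matches_simulated_truth_after_peak(self, small_study):
        sess = small_study.session("s01", "test")
        merged = merge_blood_curves(sess.abss, sess.manual)
        t = np.linspace(3, 90, 200)
        truth = np.interp(t, sess.true_input.time_min, sess.true_input.whole_blood_kbq_cc)
        rel = np.abs(merged(t) - truth) / np.abs(truth)
        # ABSS samples carry ~2% noise and the late manual samples are
        # 15-30 min apart, so pointwise agreement is a few percent
        assert np.median(rel) < 0.03
        assert rel.max() < 0.12


class TestPlasmaOverBlood:
    def test_unit_ratio_reproduces_blood(self):
        f = lambda t: 10 * np.exp(-0.05 * t)
        ratio = plasma_over_blood(_manual(f, f))
        np.testing.assert_allclose(ratio(np.array([3.0, 50.0, 120.0])), 1.0, rtol=1e-12)

    def test_linear_interpolation_between_samples(self):
        tbl = BloodSampleTable(
            np.array([2.0, 90.0]), np.array([1.0, 1.0]), np.array([1.0, 1.2]), "manual"
        )
        assert plasma_over_blood(tbl)(46.0) == pytest.approx(1.1, rel=1e-12)

    def test_zero_blood_with_plasma_is_data_error(self):
        tbl = BloodSampleTable(
            np.array([2.0, 4.0]), np.array([0.0, 1.0]), np.array([1.0, 1.0]), "manual"
        )
        with pytest.raises(DataError):
            plasma_over_blood(tbl)


class TestParentFractionFit:
    TRUE = ParentFractionParams(c=(0.6, 0.3, 0.1), mu=(0.5, 0.05, 0.0))

    def _samples(self, noise_sd=0.0, rng=None, times=(2.0, 4, 6, 8, 10, 15, 20, 30, 45, 60)):
        t = np.asarray(times, float)
        pf = simulate_parent_fraction(self.TRUE, t)
        if noise_sd:
            pf = np.clip(pf + rng.normal(0, noise_sd, t.size), 0, 1)
        return ParentFractionTable(t, pf)

    def test_noise_free_curve_recovered(self):
        fit = fit_parent_fraction_3exp(self._samples(), 60.0)
        t = np.linspace(0, 90, 500)
        np.testing.assert_allclose(
            fit(t), simulate_parent_fraction(self.TRUE, t), atol=1e-3
        )

    def test_constant_unity_degenerates_cleanly(self):
        tbl = ParentFractionTable(np.array([2.0, 10, 30, 60]), np.ones(4))
        fit = fit_parent_fraction_3exp(tbl, 60.0)
        np.testing.assert_allclose(fit(np.linspace(0, 90, 50)), 1.0, atol=1e-6)

    def test_pf0_anchored_at_one(self):
        fit = fit_parent_fraction_3exp(self._samples(), 60.0)
        assert fit(0.0) == pytest.approx(1.0, abs=1e-9)

    def test_extrapolation_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            fit = fit_parent_fraction_3exp(self._samples(0.02, rng), 45.0)
            tail = fit(np.linspace(45, 90, 200))
            assert np.all(np.diff(tail) <= 1e-12)

    def test_noisy_pf20_within_003_of_truth(self):
        rng = np.random.default_rng(7)
        errors = [
            abs(
                fit_parent_fraction_3exp(self._samples(0.02, rng), 60.0)(20.0)
                - simulate_parent_fraction(self.TRUE, 20.0)
            )
            for _ in range(20)
        ]
        assert np.mean(errors) < 0.02
        assert np.max(errors) < 0.05

    def test_window_restricts_samples(self):
        t = np.array([2.0, 10, 20, 40, 50, 55])
        pf = simulate_parent_fraction(self.TRUE, t)
        pf_out = pf.copy()
        pf_out[-2:] = 0.9  # absurd out-of-window values
        fit45 = fit_parent_fraction_3exp(ParentFractionTable(t, pf_out), 45.0)
        clean = fit_parent_fraction_3exp(ParentFractionTable(t, pf), 45.0)
        assert fit45(30.0) == pytest.approx(clean(30.0), abs=1e-9)

    def test_too_few_samples_is_data_error(self):
        tbl = ParentFractionTable(np.array([2.0, 10, 30]), np.array([0.9, 0.5, 0.2]))
        with pytest.raises(DataError):
            fit_parent_fraction_3exp(tbl, 60.0)


class TestBuildInputFunction:
    def test_unit_ratio_and_fraction_reproduce_blood(self):
        f = lambda t: 10 * np.exp(-0.1 * t) + 1
        merged = merge_blood_curves(_abss(f), _manual(f, f))
        inp = build_input_function(merged, lambda t: np.ones_like(t), lambda t: np.ones_like(t))
        np.testing.assert_allclose(inp.plasma_parent_kbq_cc, merged(inp.time_min), rtol=1e-12)

    def test_fraction_scales_input_pointwise(self):
        f = lambda t: 10 * np.exp(-0.1 * t) + 1
        merged = merge_blood_curves(_abss(f), _manual(f, f))
        inp = build_input_function(merged, lambda t: np.ones_like(t), lambda t: np.full_like(t, 0.15))
        i20 = np.searchsorted(inp.time_min, 20.0)
        assert inp.plasma_parent_kbq_cc[i20] == pytest.approx(0.15 * merged(inp.time_min[i20]))

    def test_multiplicative_in_blood_activity(self):
        f = lambda t: 10 * np.exp(-0.1 * t) + 1
        pf = lambda t: np.exp(-0.05 * t)
        ratio = lambda t: np.full_like(t, 1.1)
        m1 = merge_blood_curves(_abss(f), _manual(f, f))
        m3 = merge_blood_curves(_abss(lambda t: 3 * f(t)), _manual(lambda t: 3 * f(t), lambda t: 3 * f(t)))
        i1 = build_input_function(m1, ratio, pf)
        i3 = build_input_function(m3, ratio, pf)
        np.testing.assert_allclose(i3.plasma_parent_kbq_cc, 3 * i1.plasma_parent_kbq_cc, rtol=1e-12)

    def test_reconstruction_tracks_simulated_truth(self, small_study):
        """Normalized RMS error of the rebuilt parent-plasma input over [1, 60] min."""
        nrms = []
        for sess in small_study.sessions.values():
            rec = input_function_from_tables(sess.abss, sess.manual, sess.parent_samples, 60.0)
            truth = np.interp(
                rec.time_min, sess.true_input.time_min, sess.true_input.plasma_parent_kbq_cc
            )
            m = (rec.time_min >= 1) & (rec.time_min <= 60)
            err = rec.plasma_parent_kbq_cc[m] - truth[m]
            nrms.append(np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(truth[m] ** 2)))
        assert np.median(nrms) < 0.05
        assert np.max(nrms) < 0.15
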