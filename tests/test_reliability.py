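import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from petkin.errors import InvalidArgumentError
from petkin.reliability import (
    absolute_variability,
    icc_oneway,
    summarize_study,
    time_stability,
    var_by_duration,
)
from petkin.simulate import DEFAULT_REGIONS, StudyDesign, simulate_study, simulate_tissue_tac


class TestAbsoluteVariability:
    def test_equal_pair_is_zero(self):
        assert absolute_variability(5.0, 5.0) == 0.0

    def test_reference_value(self):
        assert absolute_variability(4.0, 5.0) == pytest.approx(200 / 9, rel=1e-12)

    @given(a=st.floats(0.1, 100), b=st.floats(0.1, 100), c=st.floats(0.01, 100))
    def test_symmetric_and_scale_invariant(self, a, b, c):
        assert absolute_variability(a, b) == pytest.approx(absolute_variability(b, a))
        assert absolute_variability(c * a, c * b) == pytest.approx(
            absolute_variability(a, b), rel=1e-9
        )

    def test_non_positive_sum_rejected(self):
        with pytest.raises(InvalidArgumentError):
            absolute_variability(0.0, 0.0)


class TestIccOneway:
    def test_perfect_retest_gives_one(self):
        x = np.array([[3.0, 3.0], [5.0, 5.0], [7.0, 7.0]])
        res = icc_oneway(x)
        assert res.icc == 1.0
        assert res.ci_high == 1.0

    def test_null_population_centers_at_zero(self):
        rng = np.random.default_rng(0)
        iccs = [icc_oneway(rng.normal(5.0, 1.0, (6, 2))).icc for _ in range(200)]
        assert abs(np.mean(iccs)) < 0.1

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        subj = rng.normal(5, 1, 8)
        x = subj[:, None] + rng.normal(0, 0.2, (8, 2))
        res = icc_oneway(x)
        assert res.ci_low <= res.icc <= res.ci_high

    @given(scale=st.floats(0.1, 10), shift=st.floats(-50, 50))
    def test_affine_invariance(self, scale, shift):
        x = np.array([[3.0, 3.4], [5.0, 4.6], [7.0, 7.3], [4.0, 4.2]])
        a = icc_oneway(x)
        b = icc_oneway(scale * x + shift)
        assert b.icc == pytest.approx(a.icc, rel=1e-9, abs=1e-12)

    def test_matches_pingouin_icc1(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        x = rng.normal(5, 1, (7, 2)) + rng.normal(0, 0.3, (7, 2))
        ours = icc_oneway(x)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(7), 2),
                "rater": np.tile(["t", "r"], 7),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, "subject", "rater", "score")
        icc1 = ref.iloc[0]  # first row is the one-way single-rater ICC
        assert "1" in str(icc1.Type)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert ours.icc == pytest.approx(icc1.ICC, abs=1e-6)
        assert ours.ci_low == pytest.approx(icc1[ci_col][0], abs=0.01)
        assert ours.ci_high == pytest.approx(icc1[ci_col][1], abs=0.01)

    def test_degenerate_inputs(self):
        with pytest.raises(InvalidArgumentError):
            icc_oneway(np.array([[1.0, 2.0]]))
        assert np.isnan(icc_oneway(np.full((3, 2), 4.0)).icc)


class TestVarianceComponentResponse:
    def test_within_cv_drives_var_up_and_icc_down(self):
        """More session-to-session wobble -> higher VAR, lower ICC (true V_T)."""
        var_means, iccs = [], []
        for wcv in (0.01, 0.08, 0.25):
            vals_var, vals_icc = [], []
            for seed in (1, 2, 3):
                design = StudyDesign(
                    n_subjects=5,
                    regions=DEFAULT_REGIONS[:1],
                    between_subject_cv=0.2,
                    within_subject_cv=wcv,
                    noise_scale=0.0,
                    seed=seed,
                )
                gt = simulate_study(design).ground_truth
                wide = gt.pivot_table(index="subject", columns="session", values="vt")
                vals_var.append(
                    np.mean(absolute_variability(wide["test"].to_numpy(), wide["retest"].to_numpy()))
                )
                vals_icc.append(icc_oneway(wide[["test", "retest"]].to_numpy()).icc)
            var_means.append(np.mean(vals_var))
            iccs.append(np.mean(vals_icc))
        assert var_means[0] < var_means[1] < var_means[2]
        assert iccs[0] > iccs[1] > iccs[2]


class TestTimeStability:
    def test_full_duration_ratio_exactly_100(self, true_input, schedule, noiseless_tacs):
        ts = time_stability(noiseless_tacs["cerebellum"], true_input, "ma1")
        assert ts.ratio_to_full_pct[-1] == 100.0

    def test_noiseless_2tc_stable_beyond_63min(self, true_input, noiseless_tacs):
        ts = time_stability(noiseless_tacs["thalamus"], true_input, "2tc")
        keep = ts.durations_min >= 63.0
        assert np.all(ts.ratio_to_full_pct[keep] >= 98.0)
        assert np.all(ts.ratio_to_full_pct[keep] <= 102.0)

    def test_short_durations_flagged_missing_for_graphical(self, true_input, noiseless_tacs):
        ts = time_stability(noiseless_tacs["pons"], true_input, "logan", t_star_min=27.0)
        assert np.isnan(ts.vt[ts.durations_min < 45.0]).all()
        assert np.isfinite(ts.vt[ts.durations_min >= 45.0]).all()

    def test_wrong_final_duration_rejected(self, true_input, noiseless_tacs):
        with pytest.raises(InvalidArgumentError):
            time_stability(noiseless_tacs["pons"], true_input, "ma1", durations_min=(33.0, 63.0))

    def test_var_by_duration_pairs_sessions(self, true_input, schedule):
        reg = DEFAULT_REGIONS[4]
        t1 = simulate_tissue_tac(reg, true_input, schedule, 0.1, 1)
        t2 = simulate_tissue_tac(reg, true_input, schedule, 0.1, 2)
        a = time_stability(t1, true_input, "ma1")
        b = time_stability(t2, true_input, "ma1")
        var = var_by_duration(a, b)
        ok = np.isfinite(a.vt) & np.isfinite(b.vt)
        assert np.all(var[ok] >= 0)
        assert np.isnan(var[~ok]).all()


class TestSummarizeStudy:
    def _fits(self):
        rows = []
        rng = np.random.default_rng(5)
        for i, subj in enumerate(["s1", "s2", "s3"]):
            base = 5 + i
            for sess in ("test", "retest"):
                rows.append(
                    dict(subject=subj, session=sess, region="pons", model="2tc",
                         vt=base + rng.normal(0, 0.1))
                )
        return pd.DataFrame(rows)

    def test_tables_have_expected_shape(self):
        vt_table, tr_table = summarize_study(self._fits())
        assert len(vt_table) == 1 and len(tr_table) == 1
        row = tr_table.iloc[0]
        assert 0 <= row.var_mean_pct < 10
        assert row.icc_ci_low <= row.icc <= row.icc_ci_high

    def test_region_ordering_convention(self):
        fits = pd.concat(
            [
                self._fits().assign(region="cerebellum"),
                self._fits().assign(region="amygdala"),
                self._fits().assign(region="pons"),
            ]
        )
        vt_table, _ = summarize_study(fits)
        assert list(vt_table.region) == ["pons", "cerebellum", "amygdala"]

    def test_missing_required_columns_rejected(self):
        with pytest.raises(InvalidArgumentError):
            summarize_study(pd.DataFrame({"subject": [], "vt": []}))
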