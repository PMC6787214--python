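import numpy as np
import pytest
from scipy import stats as st

from ecgpsr import (ConfusionCounts, critical_value, diagnosis_measures,
                    mean_ci, paired_t_one_tailed, rm_anova_two_conditions)


class TestDiagnosisMeasures:
    def test_reference_confusion_62_of_65(self):
        # 62/65 positives detected, no false alarms among 65 negatives
        m = diagnosis_measures(ConfusionCounts(tp=62, fp=0, tn=65, fn=3))
        assert m.acc == pytest.approx(97.6923, abs=1e-3)
        assert m.se == pytest.approx(95.3846, abs=1e-3)
        assert m.sp == pytest.approx(100.0)
        assert m.ppv == pytest.approx(100.0)
        assert m.npv == pytest.approx(95.5882, abs=1e-3)

    def test_perfect_classifier(self):
        m = diagnosis_measures(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert (m.se, m.sp, m.acc, m.ppv, m.npv, m.f1) == (100,) * 6
        assert (m.fpr, m.fdr, m.fnr) == (0, 0, 0)

    def test_uniform_counts_give_fifty_percent_everywhere(self):
        m = diagnosis_measures(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        for v in m.as_dict().values():
            assert v == pytest.approx(50.0)

    def test_zero_denominators_reported_as_none(self):
        m = diagnosis_measures(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.se is None and m.ppv is None and m.fdr is None

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, fp=0, tn=0, fn=0)

    def test_complementarity_identities(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            m = diagnosis_measures(ConfusionCounts(int(tp), int(fp),
                                                   int(tn), int(fn)))
            assert m.fpr + m.sp == pytest.approx(100.0)
            assert m.fnr + m.se == pytest.approx(100.0)
            assert m.fdr + m.ppv == pytest.approx(100.0)


class TestMeanCi:
    def test_zero_sd_gives_degenerate_interval(self):
        assert mean_ci(1.5, 0.0, 10) == (1.5, 1.5)

    def test_cohort_example_closed_form(self):
        lcl, ucl = mean_ci(0.037, 0.0135, 65, level=0.95)
        half = st.t.ppf(0.975, 64) * 0.0135 / np.sqrt(65)
        assert lcl == pytest.approx(0.037 - half)
        assert ucl == pytest.approx(0.037 + half)
        # close to the printed (0.034, 0.041) reference interval
        assert lcl == pytest.approx(0.0337, abs=5e-4)
        assert ucl == pytest.approx(0.0404, abs=5e-4)

    def test_higher_level_widens_interval(self):
        a = mean_ci(0.0, 1.0, 20, level=0.95)
        b = mean_ci(0.0, 1.0, 20, level=0.99)
        assert b[0] < a[0] < a[1] < b[1]

    def test_width_scales_inverse_sqrt_n(self):
        w = lambda n: np.diff(mean_ci(0.0, 1.0, n))[0]
        assert w(400) < w(100) < w(25)


class TestPairedT:
    def test_null_case_identical_arrays(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_hand_computed_statistic(self):
        h = np.zeros(3)
        u = np.array([1.0, 2.0, 3.0])
        res = paired_t_one_tailed(h, u)
        d = u - h
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert res.statistic == pytest.approx(expected)
        assert res.df == (2,)

    def test_critical_value_at_df_64(self):
        res = paired_t_one_tailed(np.zeros(65), np.arange(65) / 65 + 0.1)
        assert res.critical == pytest.approx(1.669, abs=5e-4)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(5)
        h = rng.normal(0.04, 0.01, 30)
        u = h + rng.normal(0.1, 0.05, 30)
        res = paired_t_one_tailed(h, u)
        ref = st.ttest_rel(u, h, alternative="greater")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_null_p_values_are_uniform(self):
        # simulate the null: p-values should be U(0,1) (KS test, fixed seed)
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(2000):
            h = rng.normal(0.0, 1.0, 8)
            u = h + rng.normal(0.0, 1.0, 8)
            pvals.append(paired_t_one_tailed(h, u).p_value)
        assert st.kstest(pvals, "uniform").pvalue > 0.01


class TestRmAnova:
    def test_df_for_65_subjects(self):
        rng = np.random.default_rng(1)
        h = rng.normal(0.05, 0.01, 65)
        u = rng.normal(0.18, 0.05, 65)
        res = rm_anova_two_conditions(h, u)
        assert res.df == (1, 64)
        assert res.reject

    def test_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            h = rng.normal(0.0, 1.0, 12)
            u = h + rng.normal(0.5, 1.0, 12)
            f = rm_anova_two_conditions(h, u).statistic
            t = paired_t_one_tailed(h, u).statistic
            assert f == pytest.approx(t ** 2, rel=1e-9)

    def test_agrees_with_pingouin_reference(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        h = rng.normal(0.05, 0.02, 20)
        u = rng.normal(0.15, 0.05, 20)
        res = rm_anova_two_conditions(h, u)
        df = pd.DataFrame({
            "subject": np.tile(np.arange(20), 2),
            "cond": ["h"] * 20 + ["u"] * 20,
            "cv": np.concatenate([h, u]),
        })
        ref = pg.rm_anova(dv="cv", within="cond", subject="subject", data=df)
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)


class TestCriticalValue:
    def test_one_tailed_t_at_64_df(self):
        assert critical_value("t", 0.05, 64) == pytest.approx(1.669, abs=5e-4)

    def test_f_at_1_and_64_df(self):
        assert critical_value("f", 0.05, (1, 64)) == pytest.approx(3.991,
                                                                   abs=5e-4)

    def test_t_limits_to_normal_quantile(self):
        assert critical_value("t", 0.05, 10 ** 7) == pytest.approx(1.645,
                                                                   abs=1e-3)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            critical_value("t", 0.05, 0)
        with pytest.raises(ValueError):
            critical_value("f", 0.05, 5)
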