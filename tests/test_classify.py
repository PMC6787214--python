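import numpy as np
import pytest

from ecgpsr import (LABELS, PUBLISHED_THRESHOLDS, LabeledCVTrace,
                    ThresholdPair, classify_cv, classify_trace,
                    learn_thresholds, patient_extrema, split_train_validate)
from ecgpsr.trends import CVTrace


def trace(cvs, kind="QT"):
    cvs = np.asarray(cvs, dtype=float)
    return CVTrace(means=np.ones_like(cvs), sds=cvs.copy(), cvs=cvs,
                   w=20, kind=kind)


def labeled(cvs, a, b, pid="p"):
    return LabeledCVTrace(trace=trace(cvs), a_index=a, b_index=b,
                          patient_id=pid)


class TestPatientExtrema:
    def test_direct_max_min(self):
        lt = labeled([0.03, 0.05, 0.04, 0.12, 0.11, 0.15], a=2, b=3)
        assert patient_extrema(lt) == (0.05, 0.11)

    def test_monotone_trace_extremes_at_landmarks(self):
        cvs = np.linspace(0.01, 0.2, 10)
        lt = labeled(cvs, a=3, b=6)
        th_max, th_min = patient_extrema(lt)
        assert th_max == pytest.approx(cvs[3])
        assert th_min == pytest.approx(cvs[6])

    def test_landmark_ordering_enforced(self):
        with pytest.raises(ValueError):
            labeled([0.1, 0.2, 0.3], a=2, b=2)


class TestLearnThresholds:
    def test_max_of_maxima_min_of_minima(self):
        pats = [labeled([0.05, 0.11], 0, 1), labeled([0.06, 0.10], 0, 1),
                labeled([0.04, 0.13], 0, 1)]
        pair = learn_thresholds(pats, kind="PR")
        assert pair.th_final_max == pytest.approx(0.06)
        assert pair.th_final_min == pytest.approx(0.10)
        assert not pair.degenerate

    def test_single_patient_equals_own_extrema(self):
        lt = labeled([0.03, 0.02, 0.09, 0.08], a=1, b=2)
        pair = learn_thresholds([lt], kind="QT")
        assert (pair.th_final_max, pair.th_final_min) == patient_extrema(lt)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            learn_thresholds([], kind="QT")

    def test_adding_patients_is_monotone(self):
        rng = np.random.default_rng(0)
        pats = [labeled(np.concatenate([rng.uniform(0.01, 0.05, 3),
                                        rng.uniform(0.08, 0.2, 3)]), 2, 3,
                        pid=str(i)) for i in range(8)]
        prev = learn_thresholds(pats[:1], "QT")
        for n in range(2, 9):
            cur = learn_thresholds(pats[:n], "QT")
            assert cur.th_final_max >= prev.th_final_max
            assert cur.th_final_min <= prev.th_final_min
            prev = cur

    def test_published_defaults_match_reference_table(self):
        assert PUBLISHED_THRESHOLDS["PR"].th_final_max == 0.068
        assert PUBLISHED_THRESHOLDS["PR"].th_final_min == 0.1012
        assert PUBLISHED_THRESHOLDS["QRS"].th_final_max == 0.069
        assert PUBLISHED_THRESHOLDS["QRS"].th_final_min == 0.083
        assert PUBLISHED_THRESHOLDS["QT"].th_final_max == 0.079
        assert PUBLISHED_THRESHOLDS["QT"].th_final_min == 0.082


class TestClassifyCv:
    @pytest.mark.parametrize("cv,label", [
        (0.05, "healthy"),
        (0.068, "healthy"),              # tie goes to the healthy band
        (0.08, "tending_to_unhealthy"),
        (0.1012, "unhealthy"),           # tie goes to the unhealthy band
        (0.15, "unhealthy"),
    ])
    def test_three_band_rule_with_pr_defaults(self, cv, label):
        assert classify_cv(cv, PUBLISHED_THRESHOLDS["PR"]).label == label

    def test_monotone_in_cv(self):
        pair = PUBLISHED_THRESHOLDS["QRS"]
        sev = [classify_cv(cv, pair).severity
               for cv in np.linspace(0.0, 0.2, 200)]
        assert all(b >= a for a, b in zip(sev, sev[1:]))

    def test_degenerate_pair_falls_back_to_midpoint(self):
        pair = ThresholdPair(th_final_max=0.10, th_final_min=0.05, kind="QT")
        assert pair.degenerate
        with pytest.warns(UserWarning):
            lo = classify_cv(0.06, pair)
        with pytest.warns(UserWarning):
            hi = classify_cv(0.09, pair)
        assert lo.label == "healthy" and hi.label == "unhealthy"


class TestClassifyTrace:
    def test_all_below_max_is_healthy(self):
        _, subject = classify_trace(trace([0.01, 0.02]), PUBLISHED_THRESHOLDS["QT"])
        assert subject.label == "healthy"

    def test_boundary_window_makes_subject_unhealthy(self):
        pair = PUBLISHED_THRESHOLDS["QT"]
        _, subject = classify_trace(trace([0.01, pair.th_final_min]), pair)
        assert subject.label == "unhealthy"

    def test_tending_window_dominates_healthy(self):
        _, subject = classify_trace(trace([0.01, 0.080]), PUBLISHED_THRESHOLDS["QT"])
        assert subject.label == "tending_to_unhealthy"

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            classify_trace(trace([]), PUBLISHED_THRESHOLDS["QT"])

    def test_labels_ordering_constant(self):
        assert LABELS == ("healthy", "tending_to_unhealthy", "unhealthy")


class TestSplitTrainValidate:
    def test_65_records_split_52_13(self):
        recs = list(range(65))
        labels = ["pos"] * 33 + ["neg"] * 32
        train, val = split_train_validate(recs, labels, 0.8, seed=1)
        assert (len(train), len(val)) == (52, 13)

    def test_two_records_fraction_half(self):
        train, val = split_train_validate(["a", "b"], ["x", "y"], 0.5, seed=0)
        assert len(train) == 1 and len(val) == 1

    def test_deterministic_for_fixed_seed(self):
        recs = list(range(30))
        labels = ["a"] * 15 + ["b"] * 15
        s1 = split_train_validate(recs, labels, 0.8, seed=9)
        s2 = split_train_validate(recs, labels, 0.8, seed=9)
        assert s1 == s2

    def test_stratification_preserves_class_balance(self):
        recs = list(range(40))
        labels = ["a"] * 20 + ["b"] * 20
        train, _ = split_train_validate(recs, labels, 0.5, seed=2)
        a = sum(1 for r in train if r < 20)
        assert a == 10

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_validate([1, 2], ["a", "b"], 1.5, seed=0)
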