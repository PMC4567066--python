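import numpy as np
import pytest

from tolsense.metrics import (
    DegenerateInputError,
    UndefinedMetricError,
    duration_summary,
    grade,
    group_compare,
    icc_2k,
    overall_agreement,
    sensitivity,
    specificity,
    tol_metrics,
    validation_report,
)

WALK = np.array(["walking", "walking", "sitting", "sitting"], dtype=object)
PRED = np.array(["walking", "sitting", "sitting", "sitting"], dtype=object)


def _confusion_oracle(ref, pred, category):
    """Brute-force per-second confusion counts."""
    tp = fn = tn = fp = 0
    for r, p in zip(ref, pred):
        if r == category:
            tp += p == category
            fn += p != category
        else:
            tn += p != category
            fp += p == category
    return tp, fn, tn, fp


class TestCategoryMetrics:
    def test_sensitivity_hand_count(self):
        assert sensitivity(WALK, PRED, "walking") == 50.0

    def test_specificity_hand_count(self):
        assert specificity(WALK, PRED, "walking") == 100.0

    def test_overall_agreement_hand_count(self):
        assert overall_agreement(WALK, PRED) == 75.0

    def test_perfect_prediction(self):
        for cat in ("walking", "sitting"):
            assert sensitivity(WALK, WALK, cat) == 100.0
            assert specificity(WALK, WALK, cat) == 100.0
        assert overall_agreement(WALK, WALK) == 100.0

    def test_absent_category_not_applicable(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(WALK, PRED, "lying")

    def test_specificity_undefined_when_ref_all_category(self):
        ref = np.array(["walking"] * 4, dtype=object)
        with pytest.raises(UndefinedMetricError):
            specificity(ref, PRED, "walking")

    def test_everything_predicted_as_category_zero_specificity(self):
        pred = np.array(["walking"] * 4, dtype=object)
        assert specificity(WALK, pred, "walking") == 0.0

    def test_disjoint_series_zero_agreement(self):
        assert overall_agreement(WALK, np.array(["lying"] * 4, dtype=object)) == 0.0

    def test_agreement_symmetric(self):
        assert overall_agreement(WALK, PRED) == overall_agreement(PRED, WALK)

    def test_matches_confusion_oracle_on_random_pairs(self):
        rng = np.random.default_rng(12345)
        vocab = ["sitting", "standing", "walking", "lying"]
        for _ in range(200):
            n = rng.integers(5, 60)
            ref = rng.choice(vocab, n).astype(object)
            pred = rng.choice(vocab, n).astype(object)
            for cat in vocab:
                tp, fn, tn, fp = _confusion_oracle(ref, pred, cat)
                if tp + fn:
                    assert sensitivity(ref, pred, cat) == pytest.approx(
                        100.0 * tp / (tp + fn))
                if tn + fp:
                    assert specificity(ref, pred, cat) == pytest.approx(
                        100.0 * tn / (tn + fp))
            assert overall_agreement(ref, pred) == pytest.approx(
                100.0 * sum(r == p for r, p in zip(ref, pred)) / n)


class TestToLMetrics:
    def test_hand_count(self):
        ref = np.array(["standing", "walking", "sitting", "sitting"], dtype=object)
        pred = np.array(["standing", "inactive", "sitting", "sitting"], dtype=object)
        m = tol_metrics(ref, pred)
        assert m["sensitivity"] == 50.0
        assert m["specificity"] == 100.0
        assert m["overall_agreement"] == 75.0

    def test_perfect_and_inverted(self):
        ref = np.array(["standing", "standing", "sitting", "sitting"], dtype=object)
        m = tol_metrics(ref, ref)
        assert (m["sensitivity"], m["specificity"], m["overall_agreement"]) == \
               (100.0, 100.0, 100.0)
        inv = np.array(["sitting", "sitting", "standing", "standing"], dtype=object)
        m = tol_metrics(ref, inv)
        assert (m["sensitivity"], m["specificity"], m["overall_agreement"]) == \
               (0.0, 0.0, 0.0)


class TestGrade:
    @pytest.mark.parametrize("value,expected", [
        (31.8, "insufficient"),
        (42.9, "moderate"),
        (72.1, "good"),
        (87.7, "excellent"),
        (40.0, "insufficient"),
        (60.0, "moderate"),
        (80.0, "good"),
        (80.0001, "excellent"),
        (0.0, "insufficient"),
        (100.0, "excellent"),
    ])
    def test_cutoffs(self, value, expected):
        assert grade(value) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            grade(101.0)


class TestICC:
    def test_duplicated_raters(self):
        m = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        value, ok = icc_2k(m)
        assert value == pytest.approx(1.0) and ok

    def test_hand_anova_oracle(self):
        # rows (1,2),(2,3),(3,4),(4,5): MSR=10/3, MSC=2, MSE=0, n=4
        # ICC(2,k) = MSR / (MSR + (MSC-MSE)/n) = (10/3)/(10/3 + 1/2) = 20/23
        m = np.array([[1, 2], [2, 3], [3, 4], [4, 5]], dtype=float)
        value, _ = icc_2k(m)
        assert value == pytest.approx(20.0 / 23.0, abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(77)
        m = rng.normal(size=(1000, 2))
        value, ok = icc_2k(m)
        assert abs(value) < 0.1 and not ok

    def test_degenerate_input(self):
        with pytest.raises(DegenerateInputError):
            icc_2k(np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]))

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        m = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        df = pd.DataFrame({
            "target": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": m.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="score")
        sel = ref["Type"].isin(["ICC2k", "ICC(A,k)"])
        ref_val = float(ref.loc[sel, "ICC"].iloc[0])
        value, _ = icc_2k(m)
        assert value == pytest.approx(ref_val, abs=1e-9)


class TestGroupCompare:
    def test_identical_groups(self):
        t, p = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.001, 4)
        b = 1 + rng.normal(0, 0.001, 4)
        _, p = group_compare(a, b)
        assert p < 0.01

    def test_matches_closed_form_pooled(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 4.0, 5.0])
        t, _ = group_compare(a, b, equal_var=True)
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 4))
        assert t == pytest.approx(expected)

    def test_small_group_not_applicable(self):
        with pytest.raises(UndefinedMetricError):
            group_compare([1.0], [1.0, 2.0])


class TestDurationSummary:
    def test_standardized_protocol_totals(self):
        s = duration_summary(11285, 20)
        assert s["hours"] == 3.13
        assert s["mean_duration_s"] == 564.25

    def test_free_protocol_hours(self):
        assert duration_summary(35855, 20)["hours"] == 9.96


class TestValidationReport:
    def test_rows_and_na_handling(self):
        ref = np.array(["sitting"] * 5 + ["standing"] * 5, dtype=object)
        pred = np.array(["sitting"] * 5 + ["standing"] * 4 + ["inactive"],
                        dtype=object)
        rep = validation_report(ref, pred)
        frame = rep.to_frame()
        assert list(frame["category"]) == ["TOL", "Sitting", "Standing",
                                           "Walking", "Lying"]
        walking = frame[frame["category"] == "Walking"].iloc[0]
        assert np.isnan(walking["sensitivity"])   # absent category → n/a
        tol = frame[frame["category"] == "TOL"].iloc[0]
        assert tol["sensitivity"] == 80.0

    def test_perfect_prediction_all_excellent(self):
        ref = np.array(["sitting", "standing", "walking", "lying"] * 3,
                       dtype=object)
        rep = validation_report(ref, ref)
        frame = rep.to_frame()
        assert (frame["sensitivity"] == 100.0).all()
        assert (frame["sensitivity_grade"] == "excellent").all()
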