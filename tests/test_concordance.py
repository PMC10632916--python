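"""Epoch-by-epoch concordance: lag recovery, confusion matrices, MCC oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import f1_score, matthews_corrcoef

from hypnoval.concordance import (
    ConcordanceError,
    ConfusionMatrix,
    aggregate_participants,
    align_by_lag,
    binary_metrics,
    confusion_matrix,
    is_satisfactory_ebe,
    one_vs_rest_metrics,
    pool_matrices,
)
from hypnoval.hypnogram import EpochPairs
from conftest import make_hyp


def pairs_of(ref, test):
    return EpochPairs(list(ref), list(test), list(range(len(ref))))


def random_night(rng, n=900):
    stages = np.array(["W", "LS", "DS", "REM"])
    p = [0.3, 0.4, 0.15, 0.15]
    # runs of geometric length give hypnogram-like autocorrelation, which the
    # lag search needs (iid labels have a flat cross-correlation)
    labels = []
    while len(labels) < n:
        labels.extend([stages[rng.choice(4, p=p)]] * int(rng.geometric(0.12)))
    return labels[:n]


class TestAlignByLag:
    def test_pure_shift_recovered(self):
        rng = np.random.default_rng(1)
        labels = random_night(rng)
        ref = make_hyp(labels, vocabulary="FOUR")
        shifted = ["W"] * 3 + labels[:-3]
        test = make_hyp(shifted, vocabulary="FOUR")
        res = align_by_lag(ref, test)
        assert res.lag_epochs == 3
        assert res.concordance_at_lag > 0.98

    def test_identity_gives_zero_lag(self):
        ref = make_hyp(random_night(np.random.default_rng(2)), vocabulary="FOUR")
        res = align_by_lag(ref, ref)
        assert res.lag_epochs == 0 and res.concordance_at_lag == 1.0

    def test_corrupted_shift_recovered_reliably(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 50
        for _ in range(reps):
            labels = random_night(rng)
            lag = int(rng.integers(-10, 11))
            shifted = (["W"] * lag + labels[:-lag]) if lag > 0 else (
                labels[-lag:] + ["W"] * (-lag)) if lag < 0 else list(labels)
            corrupt = [
                lab if rng.random() > 0.10 else str(rng.choice(["W", "LS", "DS", "REM"]))
                for lab in shifted
            ]
            res = align_by_lag(make_hyp(labels, vocabulary="FOUR"),
                               make_hyp(corrupt, vocabulary="FOUR"))
            hits += res.lag_epochs == lag
        assert hits == reps

    def test_short_overlap_error(self):
        h = make_hyp(["W"] * 10, vocabulary="FOUR")
        with pytest.raises(ConcordanceError):
            align_by_lag(h, h, max_lag=10)


class TestConfusionMatrix:
    def test_binary_diagonal(self):
        pairs = pairs_of(["W", "LS"], ["W", "SLEEP"])
        cm = confusion_matrix(pairs, "TWO")
        assert cm.classes == ["W", "SLEEP"]
        assert cm.counts.tolist() == [[1, 0], [0, 1]]

    def test_four_class_off_diagonal(self):
        cm = confusion_matrix(pairs_of(["DS"], ["LS"]), "FOUR")
        i, j = cm.classes.index("DS"), cm.classes.index("LS")
        assert cm.counts[i, j] == 1 and cm.total == 1

    @pytest.mark.parametrize("res", ["TWO", "THREE", "FOUR"])
    def test_total_conserved_at_every_resolution(self, res):
        rng = np.random.default_rng(4)
        ref = [str(s) for s in rng.choice(["W", "LS", "DS", "REM"], 200)]
        test = [str(s) for s in rng.choice(["W", "LS", "DS", "REM"], 200)]
        assert confusion_matrix(pairs_of(ref, test), res).total == 200

    def test_five_stage_reference_tokens_mapped(self):
        cm = confusion_matrix(pairs_of(["N1", "N2", "N3"], ["LS", "LS", "DS"]), "FOUR")
        assert cm.counts[cm.classes.index("LS"), cm.classes.index("LS")] == 2
        assert cm.counts[cm.classes.index("DS"), cm.classes.index("DS")] == 1

    def test_coarsening_never_decreases_diagonal(self):
        rng = np.random.default_rng(5)
        ref = [str(s) for s in rng.choice(["W", "LS", "DS", "REM"], 500)]
        test = [str(s) for s in rng.choice(["W", "LS", "DS", "REM"], 500)]
        p = pairs_of(ref, test)
        diag4 = np.trace(confusion_matrix(p, "FOUR").counts)
        diag3 = np.trace(confusion_matrix(p, "THREE").counts)
        diag2 = np.trace(confusion_matrix(p, "TWO").counts)
        assert diag4 <= diag3 <= diag2


class TestPooling:
    def test_sum_and_scope(self):
        m = confusion_matrix(pairs_of(["W", "LS"], ["W", "LS"]), "FOUR")
        pooled = pool_matrices([m, m])
        assert (pooled.counts == 2 * m.counts).all()
        assert pooled.scope == "pooled"
        assert pool_matrices([m]).counts.tolist() == m.counts.tolist()

    def test_mismatched_resolution_error(self):
        m2 = confusion_matrix(pairs_of(["W"], ["W"]), "TWO")
        m4 = confusion_matrix(pairs_of(["W"], ["W"]), "FOUR")
        with pytest.raises(ConcordanceError):
            pool_matrices([m2, m4])

    def test_pooled_metrics_equal_concatenated_pairs(self):
        rng = np.random.default_rng(6)
        all_ref, all_test, per = [], [], []
        for _ in range(5):
            ref = [str(s) for s in rng.choice(["W", "LS", "DS", "REM"], 120)]
            test = [str(s) for s in rng.choice(["W", "LS", "DS", "REM"], 120)]
            all_ref += ref
            all_test += test
            per.append(confusion_matrix(pairs_of(ref, test), "TWO"))
        pooled = binary_metrics(pool_matrices(per))
        concat = binary_metrics(confusion_matrix(pairs_of(all_ref, all_test), "TWO"))
        assert pooled.as_dict() == concat.as_dict()


class TestBinaryMetrics:
    def test_hand_arithmetic(self):
        cm = ConfusionMatrix(["W", "SLEEP"], [[40, 10], [5, 45]], resolution="TWO")
        m = binary_metrics(cm)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.80)
        assert m.accuracy == pytest.approx(0.85)
        assert m.mcc == pytest.approx((45 * 40 - 10 * 5) / math.sqrt(55 * 50 * 50 * 45))

    def test_perfect_diagonal(self):
        m = binary_metrics(ConfusionMatrix(["W", "SLEEP"], [[50, 0], [0, 50]],
                                           resolution="TWO"))
        assert all(v == 1 for v in m.as_dict().values())

    def test_independent_labels_have_near_zero_mcc(self):
        rng = np.random.default_rng(7)
        ref = rng.choice(["W", "SLEEP"], 100_000, p=[0.3, 0.7])
        test = rng.choice(["W", "SLEEP"], 100_000, p=[0.3, 0.7])
        m = binary_metrics(confusion_matrix(pairs_of(ref, test), "TWO"))
        assert abs(m.mcc) < 0.02

    def test_zero_marginal_makes_mcc_missing(self):
        m = binary_metrics(ConfusionMatrix(["W", "SLEEP"], [[0, 0], [2, 8]],
                                           resolution="TWO"))
        assert math.isnan(m.mcc) and math.isnan(m.specificity)

    @given(st.integers(0, 100_000))
    @settings(derandomize=True, max_examples=150)
    def test_mcc_equals_indicator_correlation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tn, fp, fn, tp = rng.integers(0, 30, 4)
        cm = ConfusionMatrix(["W", "SLEEP"], [[tn, fp], [fn, tp]], resolution="TWO")
        m = binary_metrics(cm)
        ref = np.array([0] * (tn + fp) + [1] * (fn + tp))
        test = np.array([0] * tn + [1] * fp + [0] * fn + [1] * tp)
        if math.isnan(m.mcc):
            assert np.ptp(ref) == 0 or np.ptp(test) == 0
        else:
            assert m.mcc == pytest.approx(np.corrcoef(ref, test)[0, 1], abs=1e-10)
            assert m.mcc == pytest.approx(matthews_corrcoef(ref, test), abs=1e-10)
            assert m.f1 == pytest.approx(f1_score(ref, test, zero_division=0), abs=1e-10)


class TestOneVsRest:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(["W", "LS", "DS", "REM"], np.diag([10, 20, 5, 8]))
        assert all(v == 1 for v in one_vs_rest_metrics(cm, "DS").as_dict().values())

    def test_absent_reference_class_gives_missing_sensitivity(self):
        counts = np.array([[10, 0, 0, 2], [1, 20, 0, 0], [0, 0, 5, 0], [0, 0, 0, 0]])
        m = one_vs_rest_metrics(ConfusionMatrix(["W", "LS", "DS", "REM"], counts), "REM")
        assert math.isnan(m.sensitivity)

    def test_equals_explicit_precollapse(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 40, (4, 4))
        cm = ConfusionMatrix(["W", "LS", "DS", "REM"], counts)
        for target in cm.classes:
            k = cm.classes.index(target)
            tp = counts[k, k]
            fn = counts[k].sum() - tp
            fp = counts[:, k].sum() - tp
            tn = counts.sum() - tp - fn - fp
            collapsed = ConfusionMatrix(["rest", target],
                                        [[tn, fp], [fn, tp]], resolution="TWO")
            assert one_vs_rest_metrics(cm, target).as_dict() == pytest.approx(
                binary_metrics(collapsed, positive=target).as_dict(), nan_ok=True)

    def test_unknown_class_error(self):
        cm = ConfusionMatrix(["W", "SLEEP"], [[1, 0], [0, 1]], resolution="TWO")
        with pytest.raises(ConcordanceError):
            one_vs_rest_metrics(cm, "DS")


class TestAggregation:
    def test_printed_ci_bounds(self):
        # aggregate synthetic per-participant values with the printed moments
        vals = _values_with_moments(18, 0.95, 0.02)
        agg = aggregate_participants(vals, clamp=(0, 1))
        assert tuple(round(v, 2) for v in agg["ci95"]) == (0.94, 0.96)
        vals = _values_with_moments(17, 0.63, 0.12)
        agg = aggregate_participants(vals)
        assert tuple(round(v, 2) for v in agg["ci95"]) == (0.57, 0.69)

    def test_constant_values_give_point_ci(self):
        agg = aggregate_participants([0.5] * 6)
        assert agg["sd"] == 0 and agg["ci95"] == (0.5, 0.5)

    def test_missing_values_excluded_and_counted(self):
        agg = aggregate_participants([0.2, float("nan"), 0.4, 0.6])
        assert agg["n"] == 3 and agg["n_missing"] == 1

    def test_too_few_values(self):
        with pytest.raises(ConcordanceError):
            aggregate_participants([0.5])


def _values_with_moments(n, mean, sd):
    base = np.linspace(-1, 1, n)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


class TestSatisfactoryEbe:
    @pytest.mark.parametrize(
        "stage, mcc, expected",
        [("NREM", 0.53, True), ("SLEEP_WAKE", 0.63, False), ("DS", 0.57, False)],
    )
    def test_thresholds_strict(self, stage, mcc, expected):
        assert is_satisfactory_ebe(stage, mcc) is expected

    def test_unknown_stage(self):
        with pytest.raises(ConcordanceError):
            is_satisfactory_ebe("N1", 0.5)
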