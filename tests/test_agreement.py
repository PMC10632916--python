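"""Summary-agreement statistics against closed forms and independent oracles."""

import math

import numpy as np
import pingouin as pg
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hypnoval.agreement import (
    AgreementError,
    PairedMeasures,
    bland_altman,
    classify_magnitude,
    cohen_d_from_moments,
    cohen_d_paired,
    cohen_d_two_sample,
    compute_agreement,
    icc_consistency,
    is_satisfactory_summary,
    normal_ci,
    normality_check,
    pearson,
    sad,
    smape,
)


def pm(x, y, name="TST"):
    return PairedMeasures(name, np.asarray(x, float), np.asarray(y, float))


class TestBlandAltman:
    def test_constant_differences_collapse_loa(self):
        ba = bland_altman(pm([0, 1, 2], [1, 2, 3]))
        assert ba.bias == 1 and ba.sd_diff == 0
        assert ba.loa_low == ba.loa_high == 1
        assert ba.mdc == 0

    def test_two_point_closed_form(self):
        ba = bland_altman(pm([0, 0], [0, 2]))
        assert ba.bias == pytest.approx(1.0)
        assert ba.sd_diff == pytest.approx(math.sqrt(2))
        assert ba.loa_low == pytest.approx(1 - 1.96 * math.sqrt(2))
        assert ba.loa_high == pytest.approx(1 + 1.96 * math.sqrt(2))

    def test_insufficient_data(self):
        with pytest.raises(AgreementError):
            bland_altman(pm([1], [2]))

    def test_loa_cover_95pct_of_normal_differences(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0, 1, 10_000)
        ba = bland_altman(pm(np.zeros_like(d), d))
        frac = np.mean((d >= ba.loa_low) & (d <= ba.loa_high))
        assert abs(frac - 0.95) < 0.01


class TestSmape:
    def test_identity_is_zero(self):
        assert smape(pm([10, 20, 30], [10, 20, 30])) == 0

    def test_hand_arithmetic_at_tst_scale(self):
        assert smape(pm([386], [506])) == pytest.approx(100 * 120 / 892, abs=1e-9)

    def test_zero_vs_positive_is_maximal(self):
        assert smape(pm([0], [10])) == pytest.approx(100.0)

    @given(
        x=st.lists(st.floats(0, 600), min_size=1, max_size=20),
        y=st.lists(st.floats(0, 600), min_size=1, max_size=20),
    )
    @settings(derandomize=True, max_examples=100)
    def test_symmetry_and_bounds(self, x, y):
        n = min(len(x), len(y))
        a, b = pm(x[:n], y[:n]), pm(y[:n], x[:n])
        v = smape(a)
        assert 0 <= v <= 100
        assert v == pytest.approx(smape(b))
        if v == 0:
            assert np.allclose(a.x, a.y)


class TestSad:
    def test_identity_is_zero(self):
        assert sad(pm([1, 2, 3], [1, 2, 3])) == 0

    def test_table_scale_arithmetic(self):
        # SDs ~65 and ~61 with mean |difference| 130 puts SAD near 2.06
        rng = np.random.default_rng(0)
        x = rng.normal(380, 65, 400)
        y = x + 130
        v = sad(pm(x, y))
        expected = 130 / math.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2)
        assert v == pytest.approx(expected)
        assert v == pytest.approx(2.06, abs=0.08)

    @given(
        x=st.lists(st.floats(1, 500), min_size=3, max_size=15, unique=True),
        c=st.floats(0.1, 50),
    )
    @settings(derandomize=True, max_examples=60)
    def test_scale_invariance_and_swap(self, x, c):
        y = [v * 1.3 + 5 for v in x]
        base = sad(pm(x, y))
        assert sad(pm([c * v for v in x], [c * v for v in y])) == pytest.approx(base, rel=1e-9)
        assert sad(pm(y, x)) == pytest.approx(base)

    def test_zero_pooled_variance_error(self):
        with pytest.raises(AgreementError):
            sad(pm([5, 5, 5], [5, 5, 5]))


class TestCorrelationReliability:
    def test_pearson_affine(self):
        x = [1, 2, 3, 4]
        assert pearson(pm(x, [2 * v + 5 for v in x])) == pytest.approx(1.0)
        assert pearson(pm(x, [-v for v in x])) == pytest.approx(-1.0)

    def test_pearson_closed_form(self):
        assert pearson(pm([1, 2, 3, 4], [2, 1, 4, 3])) == pytest.approx(0.6)

    def test_pearson_constant_error(self):
        with pytest.raises(AgreementError):
            pearson(pm([1, 1, 1], [1, 2, 3]))

    def test_icc_perfect_and_offset_invariance(self):
        x = [1.0, 2, 3, 5]
        assert icc_consistency(pm(x, x)) == pytest.approx(1.0)
        assert icc_consistency(pm(x, [v + 7 for v in x])) == pytest.approx(1.0)

    def test_icc_reversed_is_negative_and_matches_oracle(self):
        p = pm([1, 2, 3], [3, 2, 1])
        v = icc_consistency(p)
        assert v < 0
        assert v == pytest.approx(_icc_oracle(p.x, p.y))

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=120)
    def test_icc_matches_two_way_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 11)
        x = rng.normal(0, 1, n)
        y = x * rng.uniform(0.2, 2) + rng.normal(0, 1, n)
        p = pm(np.round(x, 3), np.round(y, 3))
        try:
            v = icc_consistency(p)
        except AgreementError:
            return
        assert v == pytest.approx(_icc_oracle(p.x, p.y), abs=1e-8)


def _icc_oracle(x, y):
    """Independent consistency-ICC via pingouin's two-way single-measure ICC3."""
    import warnings

    n = len(x)
    df = pd.DataFrame({
        "subject": list(range(n)) * 2,
        "rater": ["a"] * n + ["b"] * n,
        "score": np.concatenate([x, y]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    row = res[res.Type.isin(["ICC3", "ICC(C,1)"])]
    return float(row["ICC"].iloc[0])


class TestEffectSizes:
    def test_paired_d_is_bias_over_sd(self):
        p = pm([0, 0, 0, 0], [30, -10, 20, 0])
        d = p.d
        assert cohen_d_paired(p) == pytest.approx(np.mean(d) / np.std(d, ddof=1))

    def test_paired_d_degenerate(self):
        with pytest.raises(AgreementError):
            cohen_d_paired(pm([1, 2], [3, 4]))  # constant differences

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((18, 27.03, 4.84), (17, 26.42, 4.71), 0.13),   # body-mass index
            ((18, 28.44, 1.46), (17, 28.88, 1.32), -0.32),  # cognitive screen
            ((18, 3.72, 2.67), (17, 3.47, 2.32), 0.10),     # sleepiness scale
        ],
    )
    def test_printed_group_summaries_reproduce_effect_sizes(self, a, b, expected):
        assert round(cohen_d_from_moments(*a, *b), 2) == expected

    def test_two_sample_from_raw_values(self):
        rng = np.random.default_rng(7)
        a = rng.normal(5, 2, 30)
        b = rng.normal(4, 2, 25)
        d = cohen_d_two_sample(a, b)
        assert d == pytest.approx(cohen_d_from_moments(
            30, a.mean(), a.std(ddof=1), 25, b.mean(), b.std(ddof=1)))
        assert cohen_d_two_sample(a, a) == 0


class TestNormalityCheck:
    def test_normal_data_rarely_flagged(self):
        rng = np.random.default_rng(123)
        flags = []
        for _ in range(200):
            d = rng.normal(0, 1, 500)
            flags.append(normality_check(pm(np.zeros(500), d))[2])
        assert np.mean(flags) <= 0.06  # flagged in < 6% of normal repetitions

    def test_exponential_data_always_flagged(self):
        rng = np.random.default_rng(321)
        flags = []
        for _ in range(200):
            d = rng.exponential(1, 500)
            flags.append(normality_check(pm(np.zeros(500), d))[2])
        assert np.mean(flags) >= 0.99

    def test_unsupported_n(self):
        with pytest.raises(AgreementError):
            normality_check(pm([1, 2], [3, 5]))


class TestClassification:
    @pytest.mark.parametrize(
        "v, expected",
        [
            (0.05, "negligible"), (0.1, "small"), (0.29, "small"), (-0.2, "small"),
            (0.35, "moderate"), (0.3, "moderate"), (0.5, "large"), (-1.7, "large"),
        ],
    )
    def test_magnitude_bands(self, v, expected):
        assert classify_magnitude(v) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(AgreementError):
            classify_magnitude(float("nan"))

    @pytest.mark.parametrize(
        "measure, icc, expected",
        [("DS", 0.74, True), ("WASO", 0.42, False), ("DS", 0.63, False)],
    )
    def test_satisfactory_thresholds_strict(self, measure, icc, expected):
        assert is_satisfactory_summary(measure, icc) is expected

    def test_unknown_measure(self):
        with pytest.raises(AgreementError):
            is_satisfactory_summary("TST", 0.9)


class TestCIsAndPanel:
    def test_normal_ci_reproduces_printed_bounds(self):
        assert tuple(round(v, 2) for v in normal_ci(0.95, 0.02, 18)) == (0.94, 0.96)
        assert tuple(round(v, 2) for v in normal_ci(0.63, 0.12, 17)) == (0.57, 0.69)
        assert tuple(round(v, 2) for v in normal_ci(0.41, 0.15, 35)) == (0.36, 0.46)

    def test_full_panel_is_internally_consistent(self):
        rng = np.random.default_rng(5)
        x = rng.normal(380, 60, 20)
        p = pm(x, x + rng.normal(30, 25, 20), name="WASO")
        rep = compute_agreement(p)
        assert rep.loa_low <= rep.bias <= rep.loa_high
        assert 0 <= rep.smape <= 100 and rep.sad >= 0
        assert rep.mdc == pytest.approx(1.96 * rep.sd_diff)
        assert rep.satisfactory in (True, False)
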