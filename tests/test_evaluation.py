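"""Alignment, detection scoring, agreement and reliability statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pulsebench.evaluation import (
    UndefinedScoreError,
    align_and_match,
    feature_agreement,
    hr_error_metrics,
    hr_from_beats,
    icc_2_1,
    score_detection,
    stratified_agreement,
    test_retest as retest_reliability,
)
from pulsebench.hrv import FEATURE_NAMES
from pulsebench.synthgen import SimConfig, simulate_beat_train


def anova_icc_oracle(x: np.ndarray) -> float:
    """From-scratch two-way ANOVA sums of squares, cell by cell."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum(
        (x[i, j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestAlignment:
    def test_pure_shift_recovered(self):
        cfg = SimConfig(duration_s=120, jitter_sd_ms=25, seed=1)
        beats, _ = simulate_beat_train(cfg)
        lag, pairs = align_and_match(beats - 1.0, beats)
        assert lag == pytest.approx(1.0)
        assert len(pairs) == beats.size

    def test_small_jitter_all_matched_at_zero_lag(self):
        rng = np.random.default_rng(2)
        cfg = SimConfig(duration_s=120, jitter_sd_ms=25, seed=2)
        beats, _ = simulate_beat_train(cfg)
        test = np.sort(beats + rng.uniform(-0.05, 0.05, beats.size))
        lag, pairs = align_and_match(test, beats)
        assert abs(lag) <= 0.04
        assert len(pairs) == beats.size

    def test_shift_outside_range_hits_grid_edge(self):
        cfg = SimConfig(duration_s=120, jitter_sd_ms=25, seed=3)
        beats, _ = simulate_beat_train(cfg)
        lag, _ = align_and_match(beats - 12.0, beats)
        assert abs(lag) == pytest.approx(10.0)

    def test_empty_input_raises(self):
        with pytest.raises(UndefinedScoreError):
            align_and_match(np.empty(0), np.array([1.0]))


class TestDetectionScore:
    @pytest.mark.parametrize(
        "tp,fn,fp,sens,ppv,f1",
        [
            (89, 11, 11, 0.89, 0.89, 0.89),
            (100, 0, 0, 1.0, 1.0, 1.0),
            (50, 50, 0, 0.5, 1.0, 2 / 3),
        ],
    )
    def test_formula_arithmetic(self, tp, fn, fp, sens, ppv, f1):
        s = score_detection(tp, n_ref=tp + fn, n_test=tp + fp)
        assert s.sensitivity == pytest.approx(sens)
        assert s.ppv == pytest.approx(ppv)
        assert s.f1 == pytest.approx(f1)

    def test_zero_detections_ppv_and_f1_zero(self):
        s = score_detection(0, n_ref=10, n_test=0)
        assert s.ppv == 0.0 and s.f1 == 0.0

    def test_no_reference_raises(self):
        with pytest.raises(UndefinedScoreError):
            score_detection(0, n_ref=0, n_test=5)

    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
    )
    @settings(max_examples=100, deadline=None)
    def test_f1_identity(self, tp, fn, fp):
        s = score_detection(tp, n_ref=tp + fn + 1, n_test=tp + fp)
        denom = 2 * tp + fp + fn + 1  # +1 mirrors the extra reference beat
        assert s.f1 == pytest.approx(2 * tp / denom, abs=1e-12)


class TestHeartRate:
    @pytest.mark.parametrize("period,bpm", [(0.5, 120.0), (1.0, 60.0)])
    def test_regular_train(self, period, bpm):
        beats = np.arange(0.0, 60.0, period)
        assert hr_from_beats(beats, 30.0) == pytest.approx(bpm)

    def test_single_beat_in_window_missing(self):
        assert np.isnan(hr_from_beats(np.array([10.0, 30.0]), 15.0))

    def test_error_metrics(self):
        ref = np.full(100, 60.0)
        np.testing.assert_allclose(
            list(hr_error_metrics(ref, ref).values())[:4], [0, 0, 0, 0]
        )
        m = hr_error_metrics(ref + 2.0, ref)
        assert m["bias"] == pytest.approx(2.0)
        assert m["mae"] == pytest.approx(2.0)
        assert m["loa_upper"] == pytest.approx(2.0)
        m2 = hr_error_metrics(np.full(10, 66.0), np.full(10, 60.0))
        assert m2["mape_pct"] == pytest.approx(10.0)


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        icc, p = icc_2_1(x)
        assert icc == pytest.approx(1.0)

    def test_hand_matrix_matches_oracle(self):
        m = np.array([[1, 2], [3, 4], [5, 6], [7, 8]], float)
        icc, _ = icc_2_1(m)
        assert icc == pytest.approx(anova_icc_oracle(m), abs=1e-10)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((200, 2))
        icc, _ = icc_2_1(x)
        assert -0.2 <= icc <= 0.2

    @given(
        arrays(
            float,
            st.tuples(
                st.integers(min_value=5, max_value=30),
                st.integers(min_value=2, max_value=4),
            ),
            # dyadic values keep the two summation orders exactly comparable
            elements=st.integers(min_value=-400, max_value=400).map(
                lambda i: i / 4.0
            ),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_property(self, x):
        try:
            icc, _ = icc_2_1(x)
        except UndefinedScoreError:
            return  # degenerate zero-variance draw
        assert icc == pytest.approx(anova_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_absolute_agreement(self):
        # independent library cross-check (ICC(A,1) = two-way random
        # effects, single rater, absolute agreement)
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(15)
        for _ in range(5):
            n = int(rng.integers(6, 25))
            x = rng.normal(size=(n, 2))
            mine, p_mine = icc_2_1(x)
            df = pd.DataFrame(
                {
                    "subj": np.repeat(np.arange(n), 2),
                    "rater": np.tile([0, 1], n),
                    "score": x.ravel(),
                }
            )
            tab = pg.intraclass_corr(
                df, targets="subj", raters="rater", ratings="score"
            ).set_index("Type")
            assert mine == pytest.approx(tab.loc["ICC(A,1)", "ICC"], abs=1e-10)

    def test_missing_rows_dropped(self):
        x = np.array([[1.0, 1.1], [2.0, np.nan], [3.0, 2.9], [4.0, 4.2], [5.0, 4.8]])
        icc, _ = icc_2_1(x)
        icc_ref, _ = icc_2_1(np.delete(x, 1, axis=0))
        assert icc == icc_ref


def _frame(values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({f: values for f in FEATURE_NAMES})


class TestFeatureAgreement:
    def test_identity_pairing(self):
        rng = np.random.default_rng(6)
        f = _frame(rng.normal(1000, 50, 50))
        out = feature_agreement(f, f.copy())
        assert out["mae"].max() == 0.0
        assert out["spearman_rho"].min() == pytest.approx(1.0)
        assert out["icc"].min() == pytest.approx(1.0)
        assert out["bias"].abs().max() == 0.0

    def test_additive_noise_mae_half_normal(self):
        rng = np.random.default_rng(7)
        sigma = 5.0
        base = rng.normal(1000, 50, 500)
        out = feature_agreement(_frame(base + rng.normal(0, sigma, 500)), _frame(base))
        expected = sigma * np.sqrt(2 / np.pi)
        assert out["mae"].iloc[0] == pytest.approx(expected, rel=0.10)

    def test_anti_monotone_rho(self):
        a = np.arange(20.0)
        out = feature_agreement(_frame(a), _frame(-a))
        assert out["spearman_rho"].iloc[0] == pytest.approx(-1.0)

    def test_fewer_than_two_epochs_raises(self):
        with pytest.raises(UndefinedScoreError):
            feature_agreement(_frame(np.array([1.0])), _frame(np.array([1.0])))

    def test_bland_altman_nominal_coverage(self):
        rng = np.random.default_rng(8)
        base = rng.normal(1000, 50, 1000)
        delta = rng.normal(0, 10, 1000)
        out = feature_agreement(_frame(base + delta), _frame(base))
        row = out.iloc[0]
        inside = (delta >= row.loa_lower) & (delta <= row.loa_upper)
        assert 0.93 <= inside.mean() <= 0.97


class TestReliability:
    def test_duplicated_day_icc_one(self):
        rng = np.random.default_rng(9)
        f = _frame(rng.normal(900, 60, 40))
        out = retest_reliability(f, f.copy())
        assert out["icc"].min() == pytest.approx(1.0)

    def test_known_between_day_correlation(self):
        rng = np.random.default_rng(10)
        c = 0.7
        shared = rng.standard_normal(300)
        d1 = np.sqrt(c) * shared + np.sqrt(1 - c) * rng.standard_normal(300)
        d2 = np.sqrt(c) * shared + np.sqrt(1 - c) * rng.standard_normal(300)
        out = retest_reliability(_frame(d1), _frame(d2))
        assert out["icc"].iloc[0] == pytest.approx(c, abs=0.1)

    def test_misaligned_pairing_degrades_icc(self):
        # circadian-structured day: synchronized pairing beats a one-epoch shift
        rng = np.random.default_rng(11)
        profile = 100.0 * np.sin(np.linspace(0, np.pi, 60))
        d1 = profile + rng.normal(0, 20, 60)
        d2 = profile + rng.normal(0, 20, 60)
        sync = retest_reliability(_frame(d1), _frame(d2))["icc"].iloc[0]
        shifted = retest_reliability(_frame(d1[:-5]), _frame(d2[5:]))["icc"].iloc[0]
        assert sync > shifted


class TestStratification:
    def test_single_level_equals_unstratified(self):
        rng = np.random.default_rng(12)
        a = _frame(rng.normal(1000, 50, 30))
        b = _frame(rng.normal(1000, 50, 30))
        whole = feature_agreement(a, b)
        strat = stratified_agreement(a, b, ["rest"] * 30)
        pd.testing.assert_frame_equal(whole, strat["rest"])

    def test_noisy_stratum_has_larger_error(self):
        rng = np.random.default_rng(13)
        base = rng.normal(1000, 50, 200)
        labels = np.array(["walking"] * 100 + ["rest"] * 100)
        noise = np.where(labels == "walking", 30.0, 2.0)
        a = _frame(base + rng.normal(0, 1, 200) * noise)
        out = stratified_agreement(a, _frame(base), labels)
        assert (
            out["walking"]["mre_pct"].iloc[0] > out["rest"]["mre_pct"].iloc[0]
        )

    def test_tiny_level_skipped(self):
        rng = np.random.default_rng(14)
        a = _frame(rng.normal(1000, 50, 21))
        b = _frame(rng.normal(1000, 50, 21))
        out = stratified_agreement(a, b, ["rest"] * 20 + ["running"])
        assert "running" not in out
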