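"""Coverage, epoch validity, and the R-R -> N-N cleaning pipeline."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsebench.io_formats import LabelTrack, RRStream
from pulsebench.preprocess import (
    EmptySeriesError,
    Epoch,
    clean_rr_to_nn,
    epoch_coverage,
    hourly_coverage,
    malik_mask,
    segment_epochs,
)
from pulsebench.synthgen import SimConfig, degrade_to_device_stream, simulate_beat_train


def _stream(times, rrs):
    return RRStream(np.asarray(times, float), np.asarray(rrs, float))


class TestCoverage:
    def test_fraction_of_epoch(self):
        # 180 intervals of 1000 ms inside a 300 s epoch -> 0.6
        s = _stream(np.arange(180) + 1.0, np.full(180, 1000.0))
        assert epoch_coverage(s, Epoch(0.0, 300.0)) == pytest.approx(0.6)

    def test_empty_epoch_is_zero(self):
        s = _stream([500.0], [1000.0])
        assert epoch_coverage(s, Epoch(0.0, 300.0)) == 0.0

    def test_overcomplete_clipped_to_one(self):
        s = _stream(np.linspace(0, 299, 310), np.full(310, 1000.0))
        assert epoch_coverage(s, Epoch(0.0, 300.0)) == 1.0

    def test_out_of_range_intervals_do_not_count(self):
        s = _stream([1.0, 2.0, 3.0], [1000.0, 2500.0, 100.0])
        assert epoch_coverage(s, Epoch(0.0, 10.0)) == pytest.approx(0.1)


class TestEpochs:
    @pytest.mark.parametrize("coverage,valid", [(0.39, False), (0.40, True)])
    def test_threshold_boundary_inclusive(self, coverage, valid):
        n = int(coverage * 300)
        s = _stream(np.arange(n) + 0.5, np.full(n, 1000.0))
        (ep,) = segment_epochs(s, epoch_len_s=300.0, threshold=0.40)[:1]
        assert ep.valid is valid

    def test_dominant_label_assignment(self):
        s = _stream(np.arange(300) + 0.5, np.full(300, 1000.0))
        labels = LabelTrack(
            np.array([0.0, 180.0]),
            np.array([180.0, 300.0]),
            np.array(["posture", "posture"], object),
            np.array(["upright", "reclined"], object),
        )
        (ep,) = segment_epochs(s, labels=labels)[:1]
        assert ep.labels["posture"] == "upright"

    def test_valid_count_monotone_in_threshold(self):
        cfg = SimConfig(duration_s=4 * 3600.0, jitter_sd_ms=10.0, seed=2,
                        dropout_spec=[(600, 2000), (5000, 6500), (9000, 12000)])
        beats, _ = simulate_beat_train(cfg)
        stream = degrade_to_device_stream(beats, cfg)
        counts = []
        for thr in np.arange(0.4, 1.01, 0.1):
            eps = segment_epochs(stream, threshold=float(thr))
            counts.append(sum(ep.valid for ep in eps))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_hourly_and_day_aggregates(self):
        # 2 h of data; first hour fully covered, second hour half covered
        t = np.concatenate([np.arange(3600), np.arange(3600, 5400)]) + 0.5
        s = _stream(t, np.full(t.size, 1000.0))
        eps = segment_epochs(s)
        table = hourly_coverage(eps).set_index("period")
        assert table.loc["hour_00", "processed_pct"] == 100.0
        assert table.loc["hour_01", "processed_pct"] == 50.0
        assert table.loc["full_day", "processed_pct"] == pytest.approx(75.0)


class TestMalik:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ([1000.0, 1190.0], [False, False]),  # 19% deviation accepted
            ([1000.0, 1210.0], [False, True]),  # 21% flagged
            ([1000.0, 1000.0, 1000.0], [False, False, False]),
            # baseline is the last *accepted* value: one artifact cannot cascade
            ([800.0, 800.0, 1000.0, 800.0], [False, False, True, False]),
        ],
    )
    def test_flagging_rule(self, seq, expected):
        assert malik_mask(np.array(seq)).tolist() == expected

    @given(
        st.lists(st.floats(min_value=700.0, max_value=1300.0), min_size=1, max_size=50)
    )
    @settings(max_examples=50, deadline=None)
    def test_first_never_flagged_and_acceptance_justified(self, seq):
        arr = np.array(seq)
        mask = malik_mask(arr)
        assert not mask[0]
        # every accepted value agrees within 20% with its acceptance
        # baseline: the previous accepted value or its raw predecessor
        prev_accepted = arr[0]
        for i in range(1, arr.size):
            dev_acc = abs(arr[i] - prev_accepted) / prev_accepted
            dev_raw = abs(arr[i] - arr[i - 1]) / arr[i - 1]
            if not mask[i]:
                assert dev_acc <= 0.20 + 1e-12 or dev_raw <= 0.20 + 1e-12
                prev_accepted = arr[i]
            else:
                assert dev_acc > 0.20 and dev_raw > 0.20


class TestCleaning:
    def test_outlier_interpolated_to_midpoint(self):
        s = _stream([1.0, 2.0, 3.0], [800.0, 2500.0, 810.0])
        nn = clean_rr_to_nn(s)
        np.testing.assert_allclose(nn.nn_ms, [800.0, 805.0, 810.0])
        assert nn.provenance.tolist() == ["observed", "interpolated", "observed"]

    def test_ectopic_removed_then_interpolated(self):
        s = _stream([1.0, 2.0, 3.0, 4.0], [800.0, 800.0, 1000.0, 800.0])
        nn = clean_rr_to_nn(s)
        np.testing.assert_allclose(nn.nn_ms, [800.0, 800.0, 800.0, 800.0])

    def test_clean_input_is_identity(self):
        rr = 1000.0 + 10.0 * np.sin(np.arange(50))
        s = _stream(np.arange(50) + 1.0, rr)
        nn = clean_rr_to_nn(s)
        np.testing.assert_allclose(nn.nn_ms, rr)
        assert np.all(nn.provenance == "observed")

    def test_sort_and_dedup_first(self):
        s = _stream([2.0, 1.0, 2.0], [810.0, 800.0, 810.0])
        nn = clean_rr_to_nn(s)
        np.testing.assert_allclose(nn.time_s, [1.0, 2.0])
        np.testing.assert_allclose(nn.nn_ms, [800.0, 810.0])

    def test_no_interpolation_drops_instead(self):
        s = _stream([1.0, 2.0, 3.0], [800.0, 2500.0, 810.0])
        nn = clean_rr_to_nn(s, interpolate=False)
        np.testing.assert_allclose(nn.nn_ms, [800.0, 810.0])

    def test_all_out_of_range_raises(self):
        s = _stream([1.0, 2.0], [2500.0, 2600.0])
        with pytest.raises(EmptySeriesError):
            clean_rr_to_nn(s)

    def test_output_within_physiological_range(self):
        cfg = SimConfig(
            duration_s=1800.0, jitter_sd_ms=20.0, outlier_rate=0.05,
            ectopic_rate=0.02, seed=11,
        )
        beats, truth = simulate_beat_train(cfg)
        stream = degrade_to_device_stream(beats, cfg, ground_truth=truth)
        nn = clean_rr_to_nn(stream)
        assert nn.nn_ms.min() >= 300.0 and nn.nn_ms.max() <= 2000.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotence_on_degraded_streams(self, seed):
        cfg = SimConfig(
            duration_s=1800.0, jitter_sd_ms=15.0, outlier_rate=0.05,
            ectopic_rate=0.02, dup_rate=0.02, shuffle_rate=0.02, seed=seed,
        )
        beats, _ = simulate_beat_train(cfg)
        stream = degrade_to_device_stream(beats, cfg)
        nn = clean_rr_to_nn(stream)
        nn2 = clean_rr_to_nn(RRStream(nn.time_s, nn.nn_ms))
        np.testing.assert_allclose(nn2.nn_ms, nn.nn_ms)
        np.testing.assert_allclose(nn2.time_s, nn.time_s)

    def test_injection_recall_and_false_flags(self):
        cfg = SimConfig(
            duration_s=3600.0, jitter_sd_ms=10.0, outlier_rate=0.05,
            ectopic_rate=0.02, seed=3,
        )
        beats, truth = simulate_beat_train(cfg)
        stream = degrade_to_device_stream(beats, cfg, ground_truth=truth)
        nn = clean_rr_to_nn(stream)
        out_t = np.round(stream.time_s[truth.injected_outlier_idx], 6)
        flagged = np.round(
            np.concatenate([nn.removed_outlier_t, nn.removed_ectopic_t]), 6
        )
        assert np.isin(out_t, flagged).mean() >= 0.99
        ect_t = np.round(truth.true_beats[truth.injected_ectopic_idx + 1], 6)
        assert np.isin(ect_t, flagged).mean() >= 0.99
        # clean low-jitter stream: almost nothing falsely removed
        cfg_clean = dataclasses.replace(cfg, outlier_rate=0.0, ectopic_rate=0.0)
        b2, _ = simulate_beat_train(cfg_clean)
        s2 = degrade_to_device_stream(b2, cfg_clean)
        nn2 = clean_rr_to_nn(s2)
        false_rate = (nn2.removed_outlier_t.size + nn2.removed_ectopic_t.size) / len(s2)
        assert false_rate < 0.01
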