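import numpy as np
import pytest

from pulsebench.synthgen import SimConfig, simulate_beat_train, synthesize_ppg


@pytest.fixture
def metronome_config() -> SimConfig:
    """Perfectly regular 60 BPM beat train, no noise of any kind."""
    return SimConfig(
        duration_s=60.0,
        mean_rr_ms=1000.0,
        lf_amp_ms=0.0,
        hf_amp_ms=0.0,
        jitter_sd_ms=0.0,
        seed=0,
    )


@pytest.fixture
def realistic_config() -> SimConfig:
    """Physiologically plausible resting recording: LF/HF modulation plus
    beat-to-beat jitter at ~60 BPM."""
    return SimConfig(
        duration_s=600.0,
        mean_rr_ms=1000.0,
        lf_amp_ms=30.0,
        hf_amp_ms=20.0,
        jitter_sd_ms=10.0,
        seed=42,
    )


@pytest.fixture
def clean_ppg(realistic_config):
    beats, truth = simulate_beat_train(realistic_config)
    return synthesize_ppg(beats, realistic_config), beats, truth


def f1_against_truth(detected_times: np.ndarray, true_beats: np.ndarray) -> float:
    """Detection F1 vs generator truth at the standard ±150 ms tolerance."""
    from pulsebench.evaluation import align_and_match, score_detection

    if detected_times.size == 0:
        return 0.0
    lag, pairs = align_and_match(detected_times, true_beats)
    return score_detection(pairs, n_ref=true_beats.size, n_test=detected_times.size).f1
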