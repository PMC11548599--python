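"""Synthetic cardiovascular signal generator.

Produces ground-truthed beat trains, device-like R-R streams, and PPG /
ECG waveforms so that every downstream stage (cleaning, HRV features,
beat detection, agreement statistics) can be exercised against a known
truth without access to real wearable recordings.

The beat-to-beat interval model is a sum of sinusoids plus white noise
in the *interval* domain::

    RR(t) = mean_rr + lf_amp*sin(2*pi*lf_freq*t)
                    + hf_amp*sin(2*pi*hf_freq*t + phi) + eps

with ``eps ~ Normal(0, jitter_sd^2)``. The two sinusoids place
controllable modulation power in the conventional low-frequency
(0.04–0.15 Hz) and high-frequency (0.15–0.40 Hz) HRV bands. Ectopic
beats are injected by splitting an interval at 40% of its span (early
beat plus compensatory remainder), which guarantees a successive-interval
deviation above the 20% ectopy threshold downstream cleaning filters on.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io_formats import RRStream, Waveform

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigurationError",
    "simulate_beat_train",
    "degrade_to_device_stream",
    "synthesize_ppg",
    "synthesize_ecg",
]


class ConfigurationError(ValueError):
    """A SimConfig invariant is violated."""


@dataclasses.dataclass
class SimConfig:
    """Parameters of one simulated recording.

    Amplitudes are in milliseconds of interval modulation; rates are
    per-beat probabilities; ``dropout_spec`` / ``motion_spec`` /
    ``flat_spec`` are lists of time windows in seconds from recording
    start. The same config with the same seed always yields bit-identical
    outputs.
    """

    duration_s: float = 600.0
    mean_rr_ms: float = 1000.0
    lf_amp_ms: float = 30.0
    lf_freq_hz: float = 0.1
    hf_amp_ms: float = 20.0
    hf_freq_hz: float = 0.25
    jitter_sd_ms: float = 10.0
    ectopic_rate: float = 0.0
    outlier_rate: float = 0.0
    dropout_spec: Sequence[tuple[float, float]] = ()
    dup_rate: float = 0.0
    shuffle_rate: float = 0.0
    ppg_fs_hz: float = 25.0
    pulse_width_s: float = 0.35
    ppg_amp: float = 1.0
    motion_spec: Sequence[tuple[float, float, float]] = ()
    flat_spec: Sequence[tuple[float, float]] = ()
    baseline_wander_amp: float = 0.0
    baseline_wander_freq_hz: float = 0.05
    ecg_fs_hz: float = 250.0
    circadian_amp_ms: float = 0.0  # slow day/night swing of mean RR
    circadian_period_s: float = 86400.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if not (300.0 < self.mean_rr_ms < 2000.0):
            raise ConfigurationError("mean_rr_ms must lie in (300, 2000) ms")
        for name in ("ectopic_rate", "outlier_rate", "dup_rate", "shuffle_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.lf_amp_ms < 0 or self.hf_amp_ms < 0 or self.jitter_sd_ms < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        if self.ppg_fs_hz < 10:
            raise ConfigurationError("ppg_fs_hz must be >= 10 Hz")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream per stage, all derived from ``seed``.

        The stream tag is hashed with CRC-32 so the mapping is stable
        across processes (Python's str hash is salted per interpreter).
        """
        tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, tag])
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dropout_spec"] = [list(x) for x in self.dropout_spec]
        d["motion_spec"] = [list(x) for x in self.motion_spec]
        d["flat_spec"] = [list(x) for x in self.flat_spec]
        return d


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows, for use as a test oracle."""

    true_beats: np.ndarray  # strictly increasing times, s
    true_nn_ms: np.ndarray  # intervals between true_beats
    injected_ectopic_idx: np.ndarray  # interval indices affected by ectopy
    injected_outlier_idx: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0, dtype=int)
    )
    injected_dup_idx: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0, dtype=int)
    )

    def true_features_per_epoch(self, epoch_len_s: float = 300.0) -> list[dict]:
        """Reference HRV features computed from the clean interval series,
        one dict per contiguous epoch — the oracle downstream estimates
        are judged against."""
        from .hrv import extract_features  # local import to avoid a cycle

        ends = self.true_beats[1:]
        out = []
        n_epochs = int(np.ceil(self.true_beats[-1] / epoch_len_s))
        for k in range(max(n_epochs, 1)):
            m = (ends >= k * epoch_len_s) & (ends < (k + 1) * epoch_len_s)
            if m.sum() < 2:
                out.append({})
                continue
            out.append(extract_features(self.true_nn_ms[m]).as_dict())
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "true_beats_s": self.true_beats.tolist(),
                    "true_nn_ms": self.true_nn_ms.tolist(),
                    "injected_ectopic_idx": self.injected_ectopic_idx.tolist(),
                    "injected_outlier_idx": self.injected_outlier_idx.tolist(),
                    "injected_dup_idx": self.injected_dup_idx.tolist(),
                }
            )
        )


def _interval_ms(t: float, config: SimConfig, rng: np.random.Generator, phi: float) -> float:
    rr = (
        config.mean_rr_ms
        + config.lf_amp_ms * np.sin(2 * np.pi * config.lf_freq_hz * t)
        + config.hf_amp_ms * np.sin(2 * np.pi * config.hf_freq_hz * t + phi)
    )
    if config.circadian_amp_ms:
        # longest RR (lowest HR) in the middle of the night (t=0 is midnight)
        rr += config.circadian_amp_ms * np.cos(
            2 * np.pi * (t - 4 * 3600.0) / config.circadian_period_s
        )
    if config.jitter_sd_ms > 0:
        rr += rng.normal(0.0, config.jitter_sd_ms)
    # keep the clean train physiological even in the noise tails
    return float(np.clip(rr, 310.0, 1990.0))


def simulate_beat_train(config: SimConfig) -> tuple[np.ndarray, GroundTruth]:
    """Generate a beat train by integrating the interval model.

    Returns the beat times (seconds, strictly increasing, including any
    injected ectopic beats) and the :class:`GroundTruth` record. The
    interval series in the ground truth is ``diff(true_beats)`` so the
    conservation invariant ``len(beats) == len(nn) + 1`` holds by
    construction.
    """
    config.validate()
    rng = config.rng("beats")
    phi = float(rng.uniform(0, 2 * np.pi))
    beats = [0.0]
    t = 0.0
    while True:
        rr = _interval_ms(t, config, rng, phi)
        t = t + rr / 1000.0
        if t > config.duration_s:
            break
        beats.append(t)
    beats_arr = np.array(beats)

    # ectopic injection: split interval i at 40% of its span
    ect_rng = config.rng("ectopy")
    n_int = beats_arr.size - 1
    ectopic_interval_idx: list[int] = []
    if config.ectopic_rate > 0 and n_int > 0:
        hit = ect_rng.random(n_int) < config.ectopic_rate
        new_beats = [beats_arr[0]]
        out_idx = 0
        for i in range(n_int):
            a, b = beats_arr[i], beats_arr[i + 1]
            if hit[i]:
                new_beats.append(a + 0.4 * (b - a))
                new_beats.append(b)
                # both split halves deviate >20% from the parent interval
                ectopic_interval_idx.extend([out_idx, out_idx + 1])
                out_idx += 2
            else:
                new_beats.append(b)
                out_idx += 1
        beats_arr = np.array(new_beats)

    nn_ms = np.diff(beats_arr) * 1000.0
    truth = GroundTruth(
        true_beats=beats_arr,
        true_nn_ms=nn_ms,
        injected_ectopic_idx=np.array(sorted(set(ectopic_interval_idx)), dtype=int),
    )
    return beats_arr, truth


def degrade_to_device_stream(
    beats: np.ndarray,
    config: SimConfig,
    ground_truth: GroundTruth | None = None,
    device: str = "sim",
) -> RRStream:
    """Turn a clean beat train into a dirty device-like R-R stream.

    Each interval becomes a record stamped at its *ending* beat. The
    degradations a wearable exhibits are injected at the configured
    rates: exact duplicate records, locally shuffled order, dropout gaps
    (records whose timestamp falls in a gap vanish), and physiologically
    impossible interval values outside 300–2000 ms. Injected positions
    are recorded on ``ground_truth`` when it is supplied.
    """
    config.validate()
    beats = np.asarray(beats, dtype=float)
    if beats.size == 0:
        raise ValueError("beats must be non-empty")
    rng = config.rng("device")
    t = beats[1:].copy()
    rr = np.diff(beats) * 1000.0

    # out-of-range corruption
    outlier_idx = np.empty(0, dtype=int)
    if config.outlier_rate > 0 and rr.size:
        hit = rng.random(rr.size) < config.outlier_rate
        outlier_idx = np.flatnonzero(hit)
        low = rng.random(outlier_idx.size) < 0.5
        vals = np.where(
            low,
            rng.uniform(50.0, 295.0, outlier_idx.size),
            rng.uniform(2010.0, 4000.0, outlier_idx.size),
        )
        rr[outlier_idx] = vals

    # dropout gaps remove whole records
    keep = np.ones(rr.size, dtype=bool)
    for start, end in config.dropout_spec:
        keep &= ~((t >= start) & (t < end))
    t, rr = t[keep], rr[keep]
    outlier_idx = np.flatnonzero(np.isin(np.flatnonzero(keep), outlier_idx))

    # local order shuffle: swap adjacent records
    if config.shuffle_rate > 0 and rr.size >= 2:
        swap = np.flatnonzero(rng.random(rr.size - 1) < config.shuffle_rate)
        order = np.arange(rr.size)
        for i in swap:
            order[i], order[i + 1] = order[i + 1], order[i]
        t, rr = t[order], rr[order]
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        outlier_idx = np.sort(inv[outlier_idx])

    # duplicated records (identical timestamp + value, adjacent)
    dup_idx = np.empty(0, dtype=int)
    if config.dup_rate > 0 and rr.size:
        hit = rng.random(rr.size) < config.dup_rate
        dup_idx = np.flatnonzero(hit)
        reps = np.where(hit, 2, 1)
        offsets = np.cumsum(reps) - reps  # new index of each original record
        outlier_idx = offsets[outlier_idx]
        dup_idx = offsets[dup_idx]
        t = np.repeat(t, reps)
        rr = np.repeat(rr, reps)

    if ground_truth is not None:
        ground_truth.injected_outlier_idx = outlier_idx
        ground_truth.injected_dup_idx = dup_idx
    return RRStream(t, rr, device=device)


# ---------------------------------------------------------------------------
# Waveform synthesis


def _lognormal_pulse(fs: float, width_s: float, amp: float) -> tuple[np.ndarray, int]:
    """Asymmetric log-normal-shaped pulse sampled at ``fs``.

    Returns the template and the index of its peak sample. The shape has
    the fast systolic upstroke and slower diastolic decay typical of a
    peripheral pulse; the exact morphology is a free parameter.
    """
    sigma = 0.45
    mode = 0.35 * width_s  # time-to-peak from pulse foot
    mu = np.log(mode) + sigma**2  # log-normal mode = exp(mu - sigma^2)
    support = 3.0 * width_s
    tau = np.arange(1, int(np.ceil(support * fs)) + 1) / fs
    shape = np.exp(-((np.log(tau) - mu) ** 2) / (2 * sigma**2))
    shape = amp * shape / shape.max()
    return shape, int(np.argmax(shape))


def _qrs_template(fs: float, amp: float = 1.0) -> tuple[np.ndarray, int]:
    """Sharp biphasic QRS-like spike: R wave with small Q and S troughs."""
    tau = np.arange(-0.06 * fs, 0.06 * fs + 1) / fs
    r = np.exp(-(tau**2) / (2 * 0.008**2))
    q = -0.25 * np.exp(-((tau + 0.025) ** 2) / (2 * 0.006**2))
    s = -0.3 * np.exp(-((tau - 0.025) ** 2) / (2 * 0.006**2))
    shape = amp * (r + q + s)
    return shape, int(np.argmax(shape))


def _add_pulses(
    n: int, fs: float, beats: np.ndarray, template: np.ndarray, peak_idx: int
) -> np.ndarray:
    x = np.zeros(n)
    for tb in beats:
        peak_sample = int(round(tb * fs))
        start = peak_sample - peak_idx
        lo = max(start, 0)
        hi = min(start + template.size, n)
        if hi > lo:
            x[lo:hi] += template[lo - start : hi - start]
    return x


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float = 0.5, hi: float = 8.0
) -> np.ndarray:
    white = rng.standard_normal(n)
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(2, [lo, hi], btype="band", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_ppg(beats: np.ndarray, config: SimConfig) -> Waveform:
    """Render a PPG waveform from a beat train.

    Each beat contributes one pulse template whose maximum coincides
    with the beat time (within one sample). Baseline wander, band-limited
    motion bursts, and exact-constant flat segments (sensor saturation)
    are added per config. Flat segments *replace* the signal so the
    downstream flat-run rule triggers exactly.
    """
    config.validate()
    beats = np.asarray(beats, dtype=float)
    if beats.size == 0:
        raise ValueError("beats must be non-empty")
    if beats.min() < 0 or beats.max() > config.duration_s:
        raise ValueError("beats outside [0, duration_s]")
    fs = config.ppg_fs_hz
    n = int(round(config.duration_s * fs))
    template, peak_idx = _lognormal_pulse(fs, config.pulse_width_s, config.ppg_amp)
    x = _add_pulses(n, fs, beats, template, peak_idx)

    if config.baseline_wander_amp > 0:
        t = np.arange(n) / fs
        x += config.baseline_wander_amp * np.sin(
            2 * np.pi * config.baseline_wander_freq_hz * t
        )
    rng = config.rng("ppg-noise")
    for start, end, amp in config.motion_spec:
        lo, hi = int(round(start * fs)), min(int(round(end * fs)), n)
        if hi > lo:
            x[lo:hi] += amp * _bandlimited_noise(rng, hi - lo, fs)
    for start, end in config.flat_spec:
        lo, hi = int(round(start * fs)), min(int(round(end * fs)), n) + 1
        hi = min(hi, n)
        if hi > lo:
            x[lo:hi] = x[lo]
    return Waveform(x, fs_hz=fs, channel_label="ppg")


def synthesize_ecg(beats: np.ndarray, config: SimConfig) -> Waveform:
    """Render an ECG-like waveform: one QRS complex per beat."""
    config.validate()
    beats = np.asarray(beats, dtype=float)
    if beats.size == 0:
        raise ValueError("beats must be non-empty")
    if beats.min() < 0 or beats.max() > config.duration_s:
        raise ValueError("beats outside [0, duration_s]")
    fs = config.ecg_fs_hz
    n = int(round(config.duration_s * fs))
    template, peak_idx = _qrs_template(fs)
    x = _add_pulses(n, fs, beats, template, peak_idx)
    rng = config.rng("ecg-noise")
    for start, end, amp in config.motion_spec:
        lo, hi = int(round(start * fs)), min(int(round(end * fs)), n)
        if hi > lo:
            x[lo:hi] += amp * _bandlimited_noise(rng, hi - lo, fs, lo=1.0, hi=40.0)
    return Waveform(x, fs_hz=fs, channel_label="ecg")


# ---------------------------------------------------------------------------
# Study-level helpers


def simulate_label_track(duration_s: float, seed: int = 0):
    """Plausible label streams for one simulated day starting at midnight.

    Sleep from midnight to 08:00 (supine / lying left in blocks), awake
    for the rest of the day alternating rest, walking and cycling with
    upright posture. Purely a stratification fixture: real annotation
    streams are far less regular.
    """
    from .io_formats import LabelTrack

    rng = np.random.default_rng(seed)
    starts, ends, kinds, values = [], [], [], []

    def add(s, e, kind, value):
        starts.append(s)
        ends.append(min(e, duration_s))
        kinds.append(kind)
        values.append(value)

    sleep_end = min(8 * 3600.0, duration_s)
    add(0.0, sleep_end, "sleep_state", "asleep")
    t = 0.0
    postures = ["supine", "lying left", "lying right"]
    while t < sleep_end:
        block = float(rng.uniform(1800, 5400))
        add(t, min(t + block, sleep_end), "posture", str(rng.choice(postures)))
        t += block
    if duration_s > sleep_end:
        add(sleep_end, duration_s, "sleep_state", "awake")
        t = sleep_end
        acts = ["rest", "walking", "rest", "cycling"]
        i = 0
        while t < duration_s:
            block = float(rng.uniform(1200, 3600))
            add(t, min(t + block, duration_s), "activity", acts[i % len(acts)])
            add(t, min(t + block, duration_s), "posture", "upright")
            t += block
            i += 1
    return LabelTrack(
        np.array(starts), np.array(ends), np.array(kinds, object), np.array(values, object)
    )


def simulate_day_pair(
    n_epochs: int,
    between_day_corr: float,
    epoch_len_s: float = 300.0,
    base: SimConfig | None = None,
    epoch_offset_sd_ms: float = 60.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Two days of per-epoch N-N series sharing a daily profile.

    Each time-of-day epoch e carries a latent mean-RR offset
    ``sqrt(c)*shared_e + sqrt(1-c)*indep_{e,d}`` so that epoch-mean
    features correlate across days at the configured ``c`` (up to the
    small within-epoch sampling noise). Returns per-epoch interval
    arrays (ms) for day 1 and day 2, synchronized by position.
    """
    if not (0.0 <= between_day_corr <= 1.0):
        raise ConfigurationError("between_day_corr must lie in [0, 1]")
    base = base or SimConfig(duration_s=epoch_len_s)
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n_epochs)
    days: list[list[np.ndarray]] = []
    c = between_day_corr
    for d in range(2):
        indep = rng.standard_normal(n_epochs)
        offsets = epoch_offset_sd_ms * (np.sqrt(c) * shared + np.sqrt(1 - c) * indep)
        nn_per_epoch = []
        for e in range(n_epochs):
            cfg = dataclasses.replace(
                base,
                duration_s=epoch_len_s,
                mean_rr_ms=float(np.clip(base.mean_rr_ms + offsets[e], 400, 1800)),
                seed=(seed * 1000003 + d * 4099 + e) & 0x7FFFFFFF,
            )
            _, truth = simulate_beat_train(cfg)
            nn_per_epoch.append(truth.true_nn_ms)
        days.append(nn_per_epoch)
    return days[0], days[1]
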