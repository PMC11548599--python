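"""Beat detection from raw PPG waveforms.

Seven deterministic detectors sharing a common pre/post-processing
contract: the waveform is zero-phase band-pass filtered (0.5–8 Hz by
default), segmented into detector-specific windows, each window is run
through the detector kernel, window outputs are merged with duplicate
removal, and beats falling inside flat (saturated) signal runs longer
than 0.2 s are discarded.

Detector kernels:

* ``ampd`` / ``msptd`` — local-maxima scalogram across scales; the scale
  capturing the most maxima picks the truncation level, and samples that
  are maxima at every retained scale are beats. MSPTD additionally
  computes the minima scalogram for pulse onsets and refines indices
  within a 5%-of-fs neighbourhood.
* ``erma`` — squared signal with event-related moving averages (111 ms
  peak MA vs 667 ms beat MA plus a 2%-of-mean offset).
* ``heartpy`` — normalised/squared signal vs an adaptive rolling-mean
  threshold, constrained to 40–180 BPM with peak-to-peak plausibility
  rejection.
* ``qppgfast`` — streaming slope detector (170 ms slope window, adaptive
  running-peak threshold with one-tenth increments, one-third secondary
  threshold, 340 ms lockout, threshold decay after silence).
* ``spar`` — symmetric-projection attractor reconstruction over 20 s
  windows: autocorrelation cycle length (40–200 BPM), delay-coordinate
  projection, rotation maximising crossing regularity, beats at line
  crossings.
* ``abd`` — PSD-guided band-pass plus smoothed-derivative filtering with
  a 75th-percentile threshold, interbeat-interval false-positive pruning
  and missed-beat insertion.

All detectors report beat times at the pulse *peak* for comparability.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps

from .io_formats import Waveform

__all__ = [
    "DETECTOR_NAMES",
    "BeatSeries",
    "DetectorSpec",
    "prefilter",
    "flat_segments",
    "detect_beats",
    "run_detector",
    "kernel_scalogram_peaks",
    "kernel_erma",
    "kernel_spar",
    "kernel_heartpy",
    "kernel_qppgfast",
    "kernel_abd",
]

DETECTOR_NAMES = ("abd", "ampd", "erma", "heartpy", "msptd", "qppgfast", "spar")

# window length / overlap per detector; None means one continuous pass
_WINDOW_SCHEME: dict[str, tuple[float | None, float]] = {
    "ampd": (6.0, 0.2),
    "msptd": (6.0, 0.2),
    "spar": (20.0, 0.15),  # overlap is the inter-window reconciliation
    "erma": (60.0, 0.0),
    "abd": (60.0, 0.0),
    "heartpy": (60.0, 0.0),
    "qppgfast": (None, 0.0),
}


@dataclasses.dataclass
class BeatSeries:
    """Detected (or reference) heartbeat event times in seconds."""

    times_s: np.ndarray
    detector: str = ""
    discarded_segments: list[tuple[float, float, str]] = dataclasses.field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclasses.dataclass
class DetectorSpec:
    name: str
    window_s: float | None = None
    overlap_frac: float | None = None
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in DETECTOR_NAMES:
            raise ValueError(
                f"unknown detector {self.name!r}; choose from {DETECTOR_NAMES}"
            )
        default_win, default_ovl = _WINDOW_SCHEME[self.name]
        if self.window_s is None:
            self.window_s = default_win
        if self.overlap_frac is None:
            self.overlap_frac = default_ovl
        if self.window_s is not None and self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Shared pre/post-processing


def prefilter(
    w: Waveform, low_hz: float = 0.5, high_hz: float = 8.0, order: int = 4
) -> Waveform:
    """Zero-phase Butterworth band-pass to the cardiac frequency range."""
    if w.fs_hz < 10:
        raise ValueError("prefilter requires fs >= 10 Hz")
    if high_hz >= w.fs_hz / 2:
        raise ValueError(
            f"passband upper edge {high_hz} Hz >= Nyquist {w.fs_hz / 2} Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="band", fs=w.fs_hz, output="sos")
    y = sps.sosfiltfilt(sos, w.samples)
    return Waveform(y, fs_hz=w.fs_hz, start_time=w.start_time, channel_label=w.channel_label)


def flat_segments(w: Waveform, min_flat_s: float = 0.2) -> list[tuple[float, float]]:
    """Maximal runs of consecutive equal samples lasting *more than* 0.2 s.

    A run of k equal samples spans (k-1)/fs seconds; a span of exactly
    ``min_flat_s`` is not flagged.
    """
    x = w.samples
    if x.size < 2:
        return []
    eq = np.diff(x) == 0.0
    out = []
    i = 0
    n = eq.size
    while i < n:
        if eq[i]:
            j = i
            while j < n and eq[j]:
                j += 1
            span = (j - i) / w.fs_hz  # j - i + 1 samples -> (j-i)/fs seconds
            if span > min_flat_s:
                out.append((i / w.fs_hz, j / w.fs_hz))
            i = j
        else:
            i += 1
    return out


def _iter_windows(n: int, fs: float, window_s: float | None, overlap: float):
    if window_s is None:
        yield 0, n
        return
    win = int(round(window_s * fs))
    hop = max(int(round(win * (1 - overlap))), 1)
    start = 0
    while start < n:
        end = min(start + win, n)
        if end - start >= 4:
            yield start, end
        if end == n:
            break
        start += hop


def detect_beats(
    w: Waveform,
    spec: DetectorSpec,
    flat: Sequence[tuple[float, float]] | None = None,
) -> BeatSeries:
    """Run one detector over a (prefiltered) waveform.

    Overlapping-window duplicates closer than a quarter of the median
    interbeat interval collapse to the earlier detection. ``flat`` is
    the list of saturated segments measured on the *raw* signal (the
    band-pass destroys exact flatness); beats inside them are removed
    and the segments reported as discarded.
    """
    kernel = _KERNELS[spec.name]
    fs = w.fs_hz
    x = w.samples
    idx_all: list[np.ndarray] = []
    for start, end in _iter_windows(x.size, fs, spec.window_s, spec.overlap_frac):
        local = kernel(x[start:end], fs, **spec.params)
        if local.size:
            idx_all.append(local + start)
    if idx_all:
        idx = np.unique(np.concatenate(idx_all))
        times = idx / fs
        times = _merge_duplicates(times)
    else:
        times = np.empty(0)

    discarded = [(s, e, "flat") for s, e in (flat or [])]
    for s, e, _ in discarded:
        times = times[(times < s) | (times > e)]
    return BeatSeries(times_s=times, detector=spec.name, discarded_segments=discarded)


def _merge_duplicates(times: np.ndarray) -> np.ndarray:
    if times.size < 3:
        return times
    ibi = np.diff(times)
    min_sep = 0.25 * float(np.median(ibi))
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= min_sep:
            keep.append(t)
    return np.array(keep)


def run_detector(
    raw: Waveform,
    name: str,
    low_hz: float = 0.5,
    high_hz: float = 8.0,
    spec: DetectorSpec | None = None,
) -> BeatSeries:
    """Convenience path: flat detection on raw, band-pass, detect."""
    flat = flat_segments(raw)
    filt = prefilter(raw, low_hz=low_hz, high_hz=min(high_hz, 0.45 * raw.fs_hz))
    if spec is None:
        spec = DetectorSpec(name)
    return detect_beats(filt, spec, flat=flat)


# ---------------------------------------------------------------------------
# AMPD / MSPTD


def _scalogram(x: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Boolean local-maxima scalogram: rows are scales 1..len//2.

    The strict comparisons carry a small epsilon (relative to the raw
    signal amplitude, supplied by the caller) so that float noise from
    detrending an exactly monotonic or constant signal cannot fabricate
    maxima.
    """
    n = x.size
    max_scale = n // 2
    lms = np.zeros((max_scale, n), dtype=bool)
    for k in range(1, max_scale + 1):
        seg = x[k:-k] if k < n - k else x[k:k]
        if seg.size == 0:
            continue
        is_max = (seg > x[: n - 2 * k] + eps) & (seg > x[2 * k :] + eps)
        lms[k - 1, k : n - k] = is_max
    return lms


def kernel_scalogram_peaks(
    x: np.ndarray,
    fs: float | None = None,
    refine: bool = False,
    return_onsets: bool = False,
):
    """Multi-scale local-maxima scalogram peak picking (AMPD core).

    The optimal scale lambda is the one capturing the most local maxima
    (ties break to the smallest scale); peaks are samples that are
    maxima at every scale up to lambda. With ``refine=True`` each index
    is moved to the local extremum within a 5%-of-fs neighbourhood
    (MSPTD refinement); ``return_onsets`` also runs the minima
    scalogram.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        empty = np.empty(0, dtype=int)
        return (empty, empty) if return_onsets else empty
    xd = sps.detrend(x, type="linear")
    eps = 1e-10 * float(np.ptp(x)) if np.ptp(x) > 0 else 0.0

    def _pick(sig: np.ndarray) -> np.ndarray:
        lms = _scalogram(sig, eps=eps)
        counts = lms.sum(axis=1)
        if counts.max() == 0:
            return np.empty(0, dtype=int)
        lam = int(np.argmax(counts)) + 1  # scale with most maxima, ties -> smallest
        return np.flatnonzero(lms[:lam].all(axis=0))

    peaks = _pick(xd)
    if refine and fs:
        peaks = _refine_extrema(x, peaks, int(round(0.05 * fs)), mode="max")
    if return_onsets:
        onsets = _pick(-xd)
        if refine and fs:
            onsets = _refine_extrema(x, onsets, int(round(0.05 * fs)), mode="min")
        return peaks, onsets
    return peaks


def _refine_extrema(
    x: np.ndarray, idx: np.ndarray, half_width: int, mode: str
) -> np.ndarray:
    if half_width < 1 or idx.size == 0:
        return idx
    out = []
    for i in idx:
        lo, hi = max(i - half_width, 0), min(i + half_width + 1, x.size)
        seg = x[lo:hi]
        j = int(np.argmax(seg) if mode == "max" else np.argmin(seg))
        out.append(lo + j)
    return np.unique(np.array(out, dtype=int))


def _kernel_ampd(x: np.ndarray, fs: float) -> np.ndarray:
    return kernel_scalogram_peaks(x, fs, refine=False)


def _kernel_msptd(x: np.ndarray, fs: float) -> np.ndarray:
    peaks, _onsets = kernel_scalogram_peaks(x, fs, refine=True, return_onsets=True)
    return peaks


# ---------------------------------------------------------------------------
# ERMA


def _moving_average(z: np.ndarray, width: int) -> np.ndarray:
    width = max(width, 1)
    kernel = np.ones(width) / width
    return np.convolve(z, kernel, mode="same")


def kernel_erma(x: np.ndarray, fs: float) -> np.ndarray:
    """Event-related moving averages over the squared signal.

    Candidate blocks are where the 111 ms moving average exceeds the
    667 ms moving average plus 2% of the squared signal's mean; blocks
    at least 111 ms wide yield one beat at the block maximum. The
    decision compares homogeneous quadratic quantities, so the output is
    invariant to an overall amplitude scale.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        return np.empty(0, dtype=int)
    z = np.square(np.clip(x, 0.0, None))
    w_peak = max(int(round(0.111 * fs)), 1)
    w_beat = max(int(round(0.667 * fs)), w_peak + 1)
    ma_peak = _moving_average(z, w_peak)
    ma_beat = _moving_average(z, w_beat)
    theta = 0.02 * z.mean()
    active = ma_peak > (ma_beat + theta)
    beats = []
    i = 0
    n = active.size
    while i < n:
        if active[i]:
            j = i
            while j < n and active[j]:
                j += 1
            if j - i >= w_peak:
                beats.append(i + int(np.argmax(z[i:j])))
            i = j
        else:
            i += 1
    return np.array(beats, dtype=int)


# ---------------------------------------------------------------------------
# HeartPy-style adaptive rolling-mean detector


def kernel_heartpy(x: np.ndarray, fs: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < int(fs):
        return np.empty(0, dtype=int)
    rng_amp = x.max() - x.min()
    if rng_amp == 0:
        return np.empty(0, dtype=int)
    xn = (x - x.min()) / rng_amp
    xn = xn**2  # emphasise peaks
    rol = _moving_average(xn, max(int(round(0.75 * fs)), 1))
    mn = xn.mean()

    best: np.ndarray | None = None
    best_rrsd = np.inf
    for ma_perc in (5, 10, 15, 20, 30, 40, 50):
        thr = rol + mn * ma_perc / 100.0
        peaks = _peaks_above(xn, thr)
        if peaks.size < 2:
            continue
        bpm = 60.0 * peaks.size / (x.size / fs)
        if not (40.0 <= bpm <= 180.0):
            continue
        rrsd = float(np.std(np.diff(peaks)))
        if 0 < rrsd < best_rrsd:
            best_rrsd = rrsd
            best = peaks
    if best is None:
        return np.empty(0, dtype=int)

    # peak-to-peak plausibility: band of max(300 ms, 30% of mean PP)
    pp = np.diff(best) / fs * 1000.0
    mean_pp = pp.mean()
    band = max(300.0, 0.3 * mean_pp)
    unreliable = np.concatenate(([False], np.abs(pp - mean_pp) > band))
    # local segments with > 3 unreliable detections within 10 beats are
    # discarded (the surrounding reliable stretches are kept)
    discard = np.zeros(best.size, dtype=bool)
    for i in range(best.size):
        lo = max(0, i - 9)
        if unreliable[lo : i + 1].sum() > 3:
            discard[lo : i + 1] = True
    return best[~(unreliable | discard)]


def _peaks_above(x: np.ndarray, thr: np.ndarray) -> np.ndarray:
    above = x > thr
    peaks = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            peaks.append(i + int(np.argmax(x[i:j])))
            i = j
        else:
            i += 1
    return np.array(peaks, dtype=int)


# ---------------------------------------------------------------------------
# qppgfast streaming slope detector


def kernel_qppgfast(x: np.ndarray, fs: float) -> np.ndarray:
    """Slope-threshold onset detector with adaptive running-peak threshold.

    Slope over a 170 ms window; the primary threshold tracks the running
    peak by one-tenth increments, a secondary threshold sits at one
    third of it, a 340 ms lockout follows each detection, and the
    threshold decays during prolonged silence. Detections are refined
    forward to the pulse peak for comparability with the other
    detectors.
    """
    x = np.asarray(x, dtype=float)
    wl = max(int(round(0.17 * fs)), 1)
    lockout = max(int(round(0.34 * fs)), 1)
    if x.size < 3 * wl:
        return np.empty(0, dtype=int)
    slope = np.empty_like(x)
    slope[:wl] = 0.0
    slope[wl:] = x[wl:] - x[:-wl]

    init_span = min(x.size, int(2 * fs))
    run_peak = max(slope[:init_span].max(), 1e-12)
    peak_floor = 0.05 * run_peak
    last_beat = -lockout
    silence_limit = int(2.0 * fs)
    beats = []
    i = wl
    n = x.size
    while i < n:
        if i - last_beat > silence_limit:
            # prolonged silence: let the running peak decay toward the floor
            run_peak = max(run_peak * 0.999, peak_floor)
        thr = 0.5 * run_peak
        if i - last_beat > silence_limit:
            thr = thr / 3.0  # secondary threshold for low-amplitude beats
        if slope[i] > thr and i - last_beat >= lockout:
            j_end = min(i + wl, n)
            j = i + int(np.argmax(slope[i:j_end]))
            run_peak = run_peak + (slope[j] - run_peak) / 10.0
            # refine to the pulse peak following the upstroke
            k_end = min(j + int(round(0.3 * fs)) + 1, n)
            beat = j + int(np.argmax(x[j:k_end]))
            beats.append(beat)
            last_beat = beat
            i = max(j + 1, beat)
        i += 1
    return np.unique(np.array(beats, dtype=int))


# ---------------------------------------------------------------------------
# SPAR attractor detector


def kernel_spar(x: np.ndarray, fs: float) -> np.ndarray:
    """Symmetric-projection attractor reconstruction beat detector.

    Autocorrelation picks the average cycle length within the 40–200 BPM
    band (windows with no admissible peak are skipped). The signal is
    embedded with two delays of tau/3, projected onto the plane normal
    to (1,1,1), rotated by the angle giving the most regular crossing
    pattern, and beats are read off the upward zero crossings, refined
    to the nearest pulse peak.
    """
    x = np.asarray(x, dtype=float)
    if x.size < int(2 * fs):
        return np.empty(0, dtype=int)
    xd = sps.detrend(x, type="linear")
    ac = np.correlate(xd, xd, mode="full")[xd.size - 1 :]
    lag_lo = int(np.ceil(60.0 / 200.0 * fs))
    lag_hi = int(np.floor(60.0 / 40.0 * fs))
    if lag_hi >= ac.size or lag_hi <= lag_lo:
        return np.empty(0, dtype=int)
    # the dominant periodicity (global autocorrelation peak away from lag
    # zero) must itself be physiologically plausible; a rhythm outside
    # 40-200 BPM makes the window inadmissible rather than mis-estimated
    search_hi = min(int(3.0 * fs), ac.size - 1)
    rel_all = sps.argrelmax(ac[lag_lo : search_hi + 1], order=1)[0]
    if rel_all.size == 0:
        return np.empty(0, dtype=int)
    dominant = lag_lo + int(rel_all[np.argmax(ac[lag_lo + rel_all])])
    if dominant > lag_hi or ac[dominant] < 0.1 * ac[0]:
        return np.empty(0, dtype=int)  # no admissible periodicity
    lag = dominant
    tau = lag / fs

    d = max(lag // 3, 1)
    if x.size <= 2 * d + 2:
        return np.empty(0, dtype=int)
    z1, z2, z3 = xd[2 * d :], xd[d : xd.size - d], xd[: xd.size - 2 * d]
    v = (z1 + z2 - 2 * z3) / np.sqrt(6.0)
    w = (z1 - z2) / np.sqrt(2.0)

    expected = (x.size / fs) / tau
    best_score = np.inf
    best_cross: np.ndarray | None = None
    for theta in np.linspace(0, np.pi, 18, endpoint=False):
        r = np.cos(theta) * v + np.sin(theta) * w
        cross = np.flatnonzero((r[:-1] <= 0) & (r[1:] > 0))
        if cross.size < 2:
            continue
        intervals = np.diff(cross)
        cv = intervals.std() / max(intervals.mean(), 1e-12)
        score = cv + abs(cross.size - expected) / max(expected, 1.0)
        if score < best_score:
            best_score = score
            best_cross = cross
    if best_cross is None:
        return np.empty(0, dtype=int)
    beats = best_cross + 2 * d
    return _refine_extrema(x, beats, max(lag // 2, 1), mode="max")


# ---------------------------------------------------------------------------
# ABD: PSD-guided band-pass + derivative filtering


def kernel_abd(x: np.ndarray, fs: float) -> np.ndarray:
    """PSD-guided band-pass with derivative thresholding.

    The dominant cardiac frequency from a periodogram steers a band-pass
    filter; a smoothed first difference is thresholded at its 75th
    percentile; detected upstrokes map to the following pulse peak.
    Interbeat-interval rules prune false positives (interval below half
    the median) and insert missed beats (interval above 1.8x the
    median).
    """
    x = np.asarray(x, dtype=float)
    if x.size < int(4 * fs):
        return np.empty(0, dtype=int)
    freqs, psd = sps.periodogram(sps.detrend(x), fs=fs)
    band = (freqs >= 0.5) & (freqs <= 3.0)
    if not band.any() or psd[band].max() == 0:
        return np.empty(0, dtype=int)
    f0 = float(freqs[band][np.argmax(psd[band])])
    hi = min(3.0 * f0, 0.45 * fs)
    sos = sps.butter(2, [0.5, hi], btype="band", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)

    deriv = _moving_average(np.diff(y, prepend=y[0]), 3)
    thr = np.percentile(deriv, 75)
    cand = _peaks_above(deriv, np.full(deriv.size, thr))
    # map each upstroke to the following signal peak
    peaks = []
    for c in cand:
        k_end = min(c + int(round(0.3 * fs)) + 1, y.size)
        peaks.append(c + int(np.argmax(y[c:k_end])))
    peaks = np.unique(np.array(peaks, dtype=int))
    if peaks.size < 3:
        return peaks

    # false-positive pruning: drop the smaller of any pair closer than
    # half the median interval
    med = float(np.median(np.diff(peaks)))
    pruned = [int(peaks[0])]
    for p in peaks[1:]:
        if p - pruned[-1] < 0.5 * med:
            if y[p] > y[pruned[-1]]:
                pruned[-1] = int(p)
        else:
            pruned.append(int(p))
    peaks = np.array(pruned)

    # missed-beat insertion inside long gaps
    med = float(np.median(np.diff(peaks)))
    inserted = [int(peaks[0])]
    for p in peaks[1:]:
        gap = p - inserted[-1]
        if gap > 1.8 * med:
            lo = inserted[-1] + int(0.3 * med)
            hi_i = p - int(0.3 * med)
            if hi_i > lo:
                inserted.append(lo + int(np.argmax(y[lo:hi_i])))
        inserted.append(int(p))
    return np.unique(np.array(inserted, dtype=int))


_KERNELS: dict[str, Callable[..., np.ndarray]] = {
    "ampd": _kernel_ampd,
    "msptd": _kernel_msptd,
    "erma": kernel_erma,
    "heartpy": kernel_heartpy,
    "qppgfast": kernel_qppgfast,
    "spar": kernel_spar,
    "abd": kernel_abd,
}
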