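"""Reference heartbeat series from ECG.

Two structurally independent R-peak detectors — a classic
Pan–Tompkins-style pipeline and a gradient-energy detector — are run on
the same ECG and merged by consensus: beats found by both within 150 ms
form the reference, and any 20-s segment containing a disagreement is
excluded from scoring altogether. Disagreement between independent
detectors is the operational definition of an unreliable reference
segment.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .io_formats import Waveform
from .ppgbeats import BeatSeries

__all__ = [
    "InsufficientSignalError",
    "detect_r_pt",
    "detect_r_gradient",
    "consensus",
]


class InsufficientSignalError(ValueError):
    pass


def _check(ecg: Waveform) -> None:
    if ecg.duration_s < 2.0:
        raise InsufficientSignalError("ECG shorter than 2 s")


def detect_r_pt(ecg: Waveform) -> BeatSeries:
    """Pan–Tompkins-style R-peak detection.

    Band-pass 5–15 Hz, derivative, squaring, 150 ms moving-window
    integration, adaptive signal/noise thresholds with a 200 ms
    refractory period and a search-back pass for missed beats. Each
    integrated-energy peak is mapped back to the R wave as the absolute
    maximum of the band-passed signal in the preceding 150 ms.
    """
    _check(ecg)
    fs = ecg.fs_hz
    hi = min(15.0, 0.45 * fs)
    sos = sps.butter(2, [5.0, hi], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg.samples)
    deriv = np.diff(bp, prepend=bp[0])
    sq = deriv**2
    mwi = np.convolve(sq, np.ones(max(int(round(0.150 * fs)), 1)), mode="same")

    refractory = int(round(0.200 * fs))
    peaks, _ = sps.find_peaks(mwi, distance=refractory)
    if peaks.size == 0:
        return BeatSeries(np.empty(0), detector="jqrs")

    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5 if mwi.size else 0.0
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5 if mwi.size else 0.0
    beats: list[int] = []
    last_accepted_mwi: list[float] = []
    for p in peaks:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] > thr:
            beats.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
            last_accepted_mwi.append(float(mwi[p]))
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki

    # search-back: gaps above 1.66x the running average interval get a
    # second look at half threshold
    if len(beats) >= 3:
        ibis = np.diff(beats)
        avg_ibi = float(np.mean(ibis))
        filled: list[int] = [beats[0]]
        for b in beats[1:]:
            gap = b - filled[-1]
            if gap > 1.66 * avg_ibi:
                lo, hi_i = filled[-1] + refractory, b - refractory
                if hi_i > lo:
                    seg_peaks = peaks[(peaks >= lo) & (peaks <= hi_i)]
                    thr2 = 0.5 * (npki + 0.25 * (spki - npki))
                    for q in seg_peaks:
                        if mwi[q] > thr2:
                            filled.append(int(q))
                            break
            filled.append(int(b))
        beats = filled

    r_idx = _snap_to_r(
        bp, np.array(beats, dtype=int), int(round(0.150 * fs)), int(round(0.2 * fs))
    )
    return BeatSeries(r_idx / fs, detector="jqrs")


def detect_r_gradient(ecg: Waveform) -> BeatSeries:
    """Gradient-energy R-peak detector (independent of Pan–Tompkins).

    Smoothed derivative energy thresholded at a high percentile, local
    maxima with a 200 ms refractory period, each detection snapped to
    the nearby extremum of the filtered ECG.
    """
    _check(ecg)
    fs = ecg.fs_hz
    hi = min(25.0, 0.45 * fs)
    sos = sps.butter(2, [1.0, hi], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg.samples)
    grad = np.gradient(bp)
    smooth = np.convolve(
        grad**2, np.ones(max(int(round(0.028 * fs)), 1)), mode="same"
    )
    thr = np.percentile(smooth, 98)
    if thr <= 0:
        return BeatSeries(np.empty(0), detector="rpeak-gradient")
    refractory = int(round(0.200 * fs))
    peaks, _ = sps.find_peaks(smooth, height=thr * 0.3, distance=refractory)
    r_idx = _snap_to_r(bp, peaks, int(round(0.100 * fs)), int(round(0.2 * fs)))
    return BeatSeries(r_idx / fs, detector="rpeak-gradient")


def _snap_to_r(
    bp: np.ndarray, idx: np.ndarray, half_width: int, guard_samples: int = 0
) -> np.ndarray:
    """Assign each candidate to the absolute-maximum |signal| sample nearby.

    Detections in the outermost 0.2 s are dropped: the zero-phase filter
    leaves transients there and a boundary-clipped QRS has no reliable
    peak anyway.
    """
    out = []
    for i in idx:
        lo, hi = max(i - half_width, 0), min(i + half_width + 1, bp.size)
        out.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    arr = np.unique(np.array(out, dtype=int))
    if guard_samples > 0:
        arr = arr[(arr >= guard_samples) & (arr <= bp.size - 1 - guard_samples)]
    return arr


def consensus(
    a: BeatSeries,
    b: BeatSeries,
    tol_ms: float = 150.0,
    segment_s: float = 20.0,
) -> BeatSeries:
    """Merge two detectors' outputs into a consensus reference.

    Greedy nearest-neighbour pairing in time order: beats agreeing
    within the tolerance are kept at the midpoint of the pair. Fixed
    20-s tiles (anchored at t=0) containing any unpaired beat from
    either detector contribute no reference beats and are reported as
    ``no_consensus`` segments.
    """
    ta, tb = a.times_s, b.times_s
    tol = tol_ms / 1000.0
    paired: list[float] = []
    unpaired: list[float] = []
    i = j = 0
    while i < ta.size and j < tb.size:
        d = ta[i] - tb[j]
        if abs(d) < tol:
            paired.append(0.5 * (ta[i] + tb[j]))
            i += 1
            j += 1
        elif d < 0:
            unpaired.append(ta[i])
            i += 1
        else:
            unpaired.append(tb[j])
            j += 1
    unpaired.extend(ta[i:])
    unpaired.extend(tb[j:])

    bad_tiles = sorted({int(t // segment_s) for t in unpaired})
    segments = [
        (k * segment_s, (k + 1) * segment_s, "no_consensus") for k in bad_tiles
    ]
    kept = np.array(paired)
    for s, e, _ in segments:
        kept = kept[(kept < s) | (kept >= e)]
    return BeatSeries(kept, detector="consensus", discarded_segments=segments)
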