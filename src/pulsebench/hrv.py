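"""Heart-rate and heart-rate-variability features per epoch.

Twelve features over one epoch of N-N intervals: time domain (mean and
SD of instantaneous heart rate, mean N-N, SDNN, SDSD, RMSSD, CVSD,
CVNN), frequency domain (LF power 0.04–0.15 Hz, HF power 0.15–0.40 Hz,
LF/HF ratio, both in ms^2), and sample entropy as the non-linear
measure.

Conventions (all stated because the literature varies):

* SDs use the sample formula (ddof=1).
* SDSD is computed about a zero mean of the successive differences and
  therefore equals RMSSD exactly; the mean-subtracted variant is
  available via ``sdsd_zero_mean=False``.
* Mean HR is the mean of per-interval instantaneous rates 60000/NN_i,
  not 60000/mean(NN) — consistent with reporting an SD of HR alongside.
* Spectral powers come from a Welch periodogram of the tachogram
  cubic-resampled to a uniform 4 Hz grid and linearly detrended.
* Sample entropy uses m=2, r=0.2*SD(NN), Chebyshev distance,
  self-matches excluded.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import interpolate as spi
from scipy import signal as sps

from .preprocess import NNSeries

__all__ = [
    "FEATURE_NAMES",
    "HRVFeatures",
    "InsufficientDataError",
    "time_domain",
    "frequency_domain",
    "sample_entropy",
    "extract_features",
]

FEATURE_NAMES = (
    "mean_hr_bpm",
    "std_hr_bpm",
    "mean_nn_ms",
    "sdnn_ms",
    "sdsd_ms",
    "rmssd_ms",
    "cvsd",
    "cvnn",
    "lf_ms2",
    "hf_ms2",
    "lf_hf_ratio",
    "sample_entropy",
)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


class InsufficientDataError(ValueError):
    """Too few intervals to compute the requested features."""


@dataclasses.dataclass
class HRVFeatures:
    mean_hr_bpm: float = math.nan
    std_hr_bpm: float = math.nan
    mean_nn_ms: float = math.nan
    sdnn_ms: float = math.nan
    sdsd_ms: float = math.nan
    rmssd_ms: float = math.nan
    cvsd: float = math.nan
    cvnn: float = math.nan
    lf_ms2: float = math.nan
    hf_ms2: float = math.nan
    lf_hf_ratio: float = math.nan
    sample_entropy: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FEATURE_NAMES])


def _nn_array(nn: NNSeries | np.ndarray) -> np.ndarray:
    if isinstance(nn, NNSeries):
        return np.asarray(nn.nn_ms, dtype=float)
    return np.asarray(nn, dtype=float)


def time_domain(nn: NNSeries | np.ndarray, sdsd_zero_mean: bool = True) -> HRVFeatures:
    x = _nn_array(nn)
    if x.size < 2:
        raise InsufficientDataError("time-domain features need >= 2 intervals")
    hr = 60000.0 / x
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d**2)))
    sdsd = rmssd if sdsd_zero_mean else float(np.std(d, ddof=1))
    mean_nn = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    return HRVFeatures(
        mean_hr_bpm=float(np.mean(hr)),
        std_hr_bpm=float(np.std(hr, ddof=1)),
        mean_nn_ms=mean_nn,
        sdnn_ms=sdnn,
        sdsd_ms=sdsd,
        rmssd_ms=rmssd,
        cvsd=rmssd / mean_nn,
        cvnn=sdnn / mean_nn,
    )


def frequency_domain(
    nn: NNSeries | np.ndarray,
    resample_hz: float = 4.0,
    method: str = "welch",
) -> tuple[float, float, float]:
    """LF and HF band powers (ms^2) and their ratio.

    The tachogram is placed on its cumulative-time axis, cubic-resampled
    to a uniform grid, linearly detrended, and integrated over the two
    bands from a Welch periodogram. ``method='lombscargle'`` estimates
    the spectrum directly on the irregular samples instead (useful for
    gappy epochs). An undefined ratio (HF == 0) is returned as NaN.
    """
    x = _nn_array(nn)
    if x.size < 2:
        raise InsufficientDataError("frequency-domain features need >= 2 intervals")
    t = np.cumsum(x) / 1000.0
    t = t - t[0]
    if method == "lombscargle":
        freqs = np.linspace(0.01, HF_BAND[1] + 0.1, 400)
        xa = x - x.mean()
        pgram = sps.lombscargle(t, xa, 2 * np.pi * freqs, normalize=False)
        # lombscargle returns A^2*n/4-scaled peaks; convert to density
        psd = pgram * 4.0 / x.size / (2 * np.pi)
        df = freqs[1] - freqs[0]
        lf = float(np.sum(psd[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])]) * df * 2 * np.pi)
        hf = float(np.sum(psd[(freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])]) * df * 2 * np.pi)
    else:
        if t[-1] <= 0:
            raise InsufficientDataError("zero-span tachogram")
        grid = np.arange(0.0, t[-1], 1.0 / resample_hz)
        if grid.size < 8:
            raise InsufficientDataError("epoch too short for spectral analysis")
        kind = "cubic" if x.size >= 4 else "linear"
        f_interp = spi.interp1d(t, x, kind=kind, fill_value="extrapolate")
        u = f_interp(grid)
        u = sps.detrend(u, type="linear")
        nperseg = min(u.size, 256)
        freqs, psd = sps.welch(u, fs=resample_hz, nperseg=nperseg, detrend=False)
        lf = float(np.trapezoid(psd[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])],
                                freqs[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])]))
        hf = float(np.trapezoid(psd[(freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])],
                                freqs[(freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])]))
    ratio = lf / hf if hf > 0 else math.nan
    return lf, hf, ratio


def sample_entropy(
    nn: NNSeries | np.ndarray, m: int = 2, r_factor: float = 0.2
) -> float:
    """Sample entropy: -ln(A/B) for template lengths m+1 over m.

    A and B count template pairs matching within tolerance
    r = r_factor * SD(series) under the Chebyshev distance, excluding
    self-matches. Returns NaN (with a log record) when either count is
    zero, rather than +/-inf.
    """
    x = _nn_array(nn)
    n = x.size
    if n < m + 2:
        raise InsufficientDataError(f"sample entropy needs >= {m + 2} intervals")
    sd = np.std(x, ddof=1)
    r = r_factor * sd
    if sd == 0:
        return 0.0  # all templates match: A == B

    def _count(mm: int) -> int:
        templates = np.lib.stride_tricks.sliding_window_view(x, mm)
        # pairwise Chebyshev distances between templates
        dist = np.max(
            np.abs(templates[:, None, :] - templates[None, :, :]), axis=-1
        )
        within = dist <= r
        np.fill_diagonal(within, False)
        return int(within.sum()) // 2

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        import logging

        logging.getLogger(__name__).info(
            "sample entropy undefined (A=%d, B=%d, n=%d)", a, b, n
        )
        return math.nan
    return float(-np.log(a / b))


def extract_features(
    nn: NNSeries | np.ndarray, sdsd_zero_mean: bool = True
) -> HRVFeatures:
    """Assemble all twelve features; undefined sub-results stay NaN."""
    x = _nn_array(nn)
    if x.size == 0:
        raise InsufficientDataError("empty N-N series")
    feats = time_domain(x, sdsd_zero_mean=sdsd_zero_mean)
    try:
        feats.lf_ms2, feats.hf_ms2, feats.lf_hf_ratio = frequency_domain(x)
    except InsufficientDataError:
        pass
    try:
        feats.sample_entropy = sample_entropy(x)
    except InsufficientDataError:
        pass
    return feats
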