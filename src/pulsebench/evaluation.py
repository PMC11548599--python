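"""Agreement, detection scoring, and reliability statistics.

Beat-level scoring follows the tolerance-window convention: a detected
beat matching a reference beat within 150 ms is a true positive, with a
prior grid search over time lags (±10 s in 20 ms steps) to absorb
clock offset between devices. Epoch-level agreement between paired
feature series is summarised with MAE, mean relative error, Spearman
rank correlation, ICC(2,1) and Bland–Altman bias with 95% limits of
agreement. Test–retest reliability uses the same ICC on features from
time-synchronized epoch pairs across days.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .hrv import FEATURE_NAMES, HRVFeatures
from .ppgbeats import BeatSeries

__all__ = [
    "DetectionScore",
    "AgreementStats",
    "UndefinedScoreError",
    "align_and_match",
    "score_detection",
    "hr_from_beats",
    "hr_series",
    "hr_error_metrics",
    "icc_2_1",
    "feature_agreement",
    "test_retest",
    "stratified_agreement",
]

log = logging.getLogger(__name__)


class UndefinedScoreError(ValueError):
    """The requested statistic is undefined for the given input."""


@dataclasses.dataclass
class DetectionScore:
    n_ref: int
    n_test: int
    n_correct: int
    lag_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_correct > min(self.n_ref, self.n_test):
            raise ValueError("n_correct exceeds min(n_ref, n_test)")

    @property
    def sensitivity(self) -> float:
        return self.n_correct / self.n_ref

    @property
    def ppv(self) -> float:
        if self.n_test == 0:
            log.info("PPV with zero detections defined as 0")
            return 0.0
        return self.n_correct / self.n_test

    @property
    def f1(self) -> float:
        s, p = self.sensitivity, self.ppv
        if s + p == 0:
            return 0.0
        return 2 * p * s / (p + s)


@dataclasses.dataclass
class AgreementStats:
    mae: float
    mre_pct: float
    spearman_rho: float
    spearman_p: float
    icc: float
    icc_p: float
    bias: float
    loa_upper: float
    loa_lower: float
    n_epochs: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Beat alignment and detection scoring


def _match_stats(
    ref: np.ndarray, test_shifted: np.ndarray, tol_s: float
) -> tuple[int, float]:
    """(count, mean distance) of reference beats whose nearest test beat
    lies strictly within the tolerance."""
    pos = np.searchsorted(test_shifted, ref)
    left = np.clip(pos - 1, 0, test_shifted.size - 1)
    right = np.clip(pos, 0, test_shifted.size - 1)
    d = np.minimum(
        np.abs(ref - test_shifted[left]), np.abs(ref - test_shifted[right])
    )
    hit = d < tol_s
    if not hit.any():
        return 0, tol_s
    return int(hit.sum()), float(d[hit].mean())


def _greedy_match(ref: np.ndarray, test: np.ndarray, tol_s: float) -> list[tuple[int, int]]:
    """One-to-one pairing in time order; each test beat used at most once."""
    pairs = []
    j = 0
    for i, r in enumerate(ref):
        while j < test.size and test[j] <= r - tol_s:
            j += 1
        if j < test.size and abs(test[j] - r) < tol_s:
            pairs.append((i, j))
            j += 1
    return pairs


def align_and_match(
    test: BeatSeries | np.ndarray,
    ref: BeatSeries | np.ndarray,
    tol_ms: float = 150.0,
    lag_range_s: float = 10.0,
    lag_step_ms: float = 20.0,
) -> tuple[float, list[tuple[int, int]]]:
    """Grid-search the clock lag and match beats at the best lag.

    For every candidate lag the number of reference beats with a test
    beat within the tolerance is counted; the lag with the highest count
    wins. Count ties break first to the smallest mean nearest-beat
    distance, then to the smallest absolute lag: a count tie is
    inevitable whenever the two series agree to well within the
    tolerance (every lag error below it matches all beats), and the
    distance criterion is what pins the true offset in that regime.
    Returns the lag (seconds, to be *added* to the test times) and the
    one-to-one (ref_idx, test_idx) matching at that lag.
    """
    t_test = test.times_s if isinstance(test, BeatSeries) else np.asarray(test, float)
    t_ref = ref.times_s if isinstance(ref, BeatSeries) else np.asarray(ref, float)
    if t_test.size == 0 or t_ref.size == 0:
        raise UndefinedScoreError("empty beat series")
    tol = tol_ms / 1000.0
    step = lag_step_ms / 1000.0
    n_steps = int(round(lag_range_s / step))
    lags = np.arange(-n_steps, n_steps + 1) * step
    stats = np.array([_match_stats(t_ref, t_test + lag, tol) for lag in lags])
    counts, dists = stats[:, 0], stats[:, 1]
    tie = counts == counts.max()
    cand, cand_d = lags[tie], dists[tie]
    order = np.lexsort((cand, np.abs(cand), np.round(cand_d, 9)))
    lag = float(cand[order[0]])
    pairs = _greedy_match(t_ref, t_test + lag, tol)
    return lag, pairs


def score_detection(
    matched: Sequence[tuple[int, int]] | int, n_ref: int, n_test: int, lag_s: float = 0.0
) -> DetectionScore:
    if n_ref == 0:
        raise UndefinedScoreError("no reference beats")
    n_correct = matched if isinstance(matched, int) else len(matched)
    return DetectionScore(n_ref=n_ref, n_test=n_test, n_correct=n_correct, lag_s=lag_s)


# ---------------------------------------------------------------------------
# Heart rate from beats


def hr_from_beats(
    beats: BeatSeries | np.ndarray, t: float, window_s: float = 8.0
) -> float:
    """HR (BPM) from the beats in the preceding window ``(t-8, t]``.

    HR = 60*(k-1)/span for k beats spanning ``span`` seconds; fewer than
    two beats give NaN.
    """
    times = beats.times_s if isinstance(beats, BeatSeries) else np.asarray(beats, float)
    m = (times > t - window_s) & (times <= t)
    sel = times[m]
    if sel.size < 2:
        return math.nan
    span = sel[-1] - sel[0]
    if span <= 0:
        return math.nan
    return 60.0 * (sel.size - 1) / span


def hr_series(
    beats: BeatSeries | np.ndarray,
    at_times: np.ndarray,
    window_s: float = 8.0,
) -> np.ndarray:
    return np.array([hr_from_beats(beats, float(t), window_s) for t in at_times])


def hr_error_metrics(
    test_hr: np.ndarray, ref_hr: np.ndarray
) -> dict[str, float]:
    """MAPE, MAE, bias and Bland–Altman LoA for paired HR samples.

    Pairs with a non-finite member are dropped; pairs where the
    reference is zero are excluded from MAPE (logged).
    """
    test_hr = np.asarray(test_hr, float)
    ref_hr = np.asarray(ref_hr, float)
    ok = np.isfinite(test_hr) & np.isfinite(ref_hr)
    test_hr, ref_hr = test_hr[ok], ref_hr[ok]
    if test_hr.size == 0:
        raise UndefinedScoreError("no valid HR pairs")
    delta = test_hr - ref_hr
    nz = ref_hr != 0
    if (~nz).any():
        log.info("excluded %d zero-reference HR pairs from MAPE", int((~nz).sum()))
    mape = float(np.mean(np.abs(delta[nz]) / ref_hr[nz]) * 100.0) if nz.any() else math.nan
    sd = float(np.std(delta, ddof=1)) if delta.size > 1 else 0.0
    bias = float(np.mean(delta))
    return {
        "mape_pct": mape,
        "mae": float(np.mean(np.abs(delta))),
        "bias": bias,
        "loa_upper": bias + 1.96 * sd,
        "loa_lower": bias - 1.96 * sd,
        "n": int(delta.size),
    }


# ---------------------------------------------------------------------------
# ICC(2,1)


def icc_2_1(ratings: np.ndarray) -> tuple[float, float]:
    """Two-way random-effects single-measurement ICC of an n x k matrix.

    Computed from the two-way ANOVA decomposition (Shrout & Fleiss):
    ICC = (MSR - MSE) / (MSR + (k-1)*MSE + k*(MSC - MSE)/n), with the
    p-value from the F test of MSR against MSE. Rows with missing cells
    are dropped pairwise (logged). Identical columns with non-zero row
    variance give exactly 1.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix (subjects x raters)")
    complete = np.all(np.isfinite(x), axis=1)
    if not complete.all():
        log.info("dropping %d incomplete rows", int((~complete).sum()))
    x = x[complete]
    n, k = x.shape
    if n < 2 or k < 2:
        raise UndefinedScoreError("ICC needs >= 2 subjects and >= 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    sst = ssr + ssc + sse
    scale = max(1.0, float(np.max(np.abs(x))) ** 2) * n * k
    if sst <= 1e-20 * scale:  # zero up to float cancellation noise
        raise UndefinedScoreError("zero total variance")
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom
    if mse == 0:
        p = 0.0 if msr > 0 else math.nan
    else:
        f = msr / mse
        p = float(sstats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


# ---------------------------------------------------------------------------
# Epoch-level feature agreement


def _feature_frame(
    feats: Sequence[HRVFeatures] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(feats, pd.DataFrame):
        return feats
    return pd.DataFrame([f.as_dict() for f in feats])


def _agreement_for_pairs(a: np.ndarray, b: np.ndarray) -> AgreementStats:
    """a = test/device values, b = reference values, paired per epoch."""
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise UndefinedScoreError("fewer than 2 mutual epochs")
    delta = a - b
    nz = b != 0
    mre = float(np.mean(np.abs(delta[nz]) / np.abs(b[nz])) * 100.0) if nz.any() else math.nan
    if np.all(a == a[0]) or np.all(b == b[0]):
        rho, rho_p = math.nan, math.nan
    else:
        rho, rho_p = sstats.spearmanr(a, b)
    try:
        icc, icc_p = icc_2_1(np.column_stack([a, b]))
    except UndefinedScoreError:
        icc, icc_p = math.nan, math.nan
    sd = float(np.std(delta, ddof=1))
    bias = float(np.mean(delta))
    return AgreementStats(
        mae=float(np.mean(np.abs(delta))),
        mre_pct=mre,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        icc=icc,
        icc_p=icc_p,
        bias=bias,
        loa_upper=bias + 1.96 * sd,
        loa_lower=bias - 1.96 * sd,
        n_epochs=int(a.size),
    )


def feature_agreement(
    ppg_feats: Sequence[HRVFeatures] | pd.DataFrame,
    ecg_feats: Sequence[HRVFeatures] | pd.DataFrame,
    features: Sequence[str] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Per-feature agreement statistics over mutually valid epochs.

    Inputs are positionally paired: row i of both frames is the same
    epoch measured by the two devices. Output is one row per feature in
    the layout of a device-validation summary table.
    """
    pa = _feature_frame(ppg_feats)
    pe = _feature_frame(ecg_feats)
    if len(pa) != len(pe):
        raise ValueError("feature frames must be paired per epoch")
    if len(pa) < 2:
        raise UndefinedScoreError("fewer than 2 mutual epochs")
    rows = []
    for feat in features:
        try:
            stats = _agreement_for_pairs(
                pa[feat].to_numpy(float), pe[feat].to_numpy(float)
            )
            rows.append({"feature": feat, **stats.as_dict()})
        except UndefinedScoreError:
            rows.append({"feature": feat, "n_epochs": 0})
    return pd.DataFrame(rows).set_index("feature")


def test_retest(
    day1_feats: Sequence[HRVFeatures] | pd.DataFrame,
    day2_feats: Sequence[HRVFeatures] | pd.DataFrame,
    features: Sequence[str] = FEATURE_NAMES,
) -> pd.DataFrame:
    """ICC(2,1) and Spearman rho between synchronized epoch pairs.

    Rows of the two frames must correspond to the same time-of-day
    epoch on the two days (synchronized pairing); unmatched epochs are
    excluded by the caller. ICC is the headline reliability statistic,
    Spearman is reported alongside.
    """
    d1 = _feature_frame(day1_feats)
    d2 = _feature_frame(day2_feats)
    if len(d1) != len(d2):
        raise ValueError("day frames must be paired per synchronized epoch")
    rows = []
    for feat in features:
        a = d1[feat].to_numpy(float)
        b = d2[feat].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < 2:
            rows.append({"feature": feat, "n_pairs": int(a.size)})
            continue
        try:
            icc, icc_p = icc_2_1(np.column_stack([a, b]))
        except UndefinedScoreError:
            icc, icc_p = math.nan, math.nan
        if np.all(a == a[0]) or np.all(b == b[0]):
            rho, rho_p = math.nan, math.nan
        else:
            rho, rho_p = sstats.spearmanr(a, b)
        rows.append(
            {
                "feature": feat,
                "icc": icc,
                "icc_p": icc_p,
                "spearman_rho": float(rho),
                "spearman_p": float(rho_p),
                "n_pairs": int(a.size),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def stratified_agreement(
    ppg_feats: pd.DataFrame,
    ecg_feats: pd.DataFrame,
    strata: Sequence,
    features: Sequence[str] = FEATURE_NAMES,
) -> dict:
    """Agreement recomputed within each level of a stratification factor.

    ``strata`` assigns one level per epoch (row). Levels with fewer than
    2 epochs are skipped with a log record.
    """
    strata = np.asarray(strata, dtype=object)
    if strata.size != len(ppg_feats):
        raise ValueError("strata must assign one level per epoch")
    out: dict = {}
    for level in pd.unique(strata):
        m = strata == level
        if m.sum() < 2:
            log.info("stratum %r skipped (%d epochs)", level, int(m.sum()))
            continue
        out[level] = feature_agreement(
            ppg_feats.loc[m].reset_index(drop=True),
            ecg_feats.loc[m].reset_index(drop=True),
            features=features,
        )
    return out
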