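"""Epoch coverage and R-R to N-N interval cleaning.

The cleaning pipeline turns a dirty device R-R stream into the
normal-to-normal (N-N) interval series that HRV features are computed
from. The fixed order of operations is:

1. sort records by timestamp and drop exact duplicates;
2. mark physiologically impossible intervals (outside 300–2000 ms) missing;
3. linearly interpolate interior missing runs over record index;
4. mark ectopic intervals missing (successive deviation above 20% from
   both the last accepted and the previous raw interval — see
   :func:`malik_mask`);
5. re-interpolate interior missing runs; leading/trailing missing
   values are dropped.

With ``interpolate=False`` steps 3 and 5 drop the missing records
instead of filling them (the ablation switch).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import LabelTrack, RRStream

__all__ = [
    "RR_MIN_MS",
    "RR_MAX_MS",
    "ECTOPIC_DEVIATION",
    "Epoch",
    "NNSeries",
    "EmptySeriesError",
    "epoch_coverage",
    "segment_epochs",
    "hourly_coverage",
    "malik_mask",
    "clean_rr_to_nn",
]

log = logging.getLogger(__name__)

RR_MIN_MS = 300.0
RR_MAX_MS = 2000.0
ECTOPIC_DEVIATION = 0.20

DAY_PARTS = {"00-08": (0, 8), "08-20": (8, 20), "20-24": (20, 24)}


class EmptySeriesError(ValueError):
    """No usable intervals remain after cleaning."""


@dataclasses.dataclass
class Epoch:
    """A fixed-length analysis window with a validity flag."""

    start_s: float
    end_s: float
    coverage: float = 0.0
    valid: bool = False
    labels: dict = dataclasses.field(default_factory=dict)

    @property
    def epoch_len_s(self) -> float:
        return self.end_s - self.start_s


@dataclasses.dataclass
class NNSeries:
    """Cleaned N-N intervals with per-position provenance."""

    time_s: np.ndarray
    nn_ms: np.ndarray
    provenance: np.ndarray  # 'observed' | 'interpolated'
    epoch: Epoch | None = None
    removed_outlier_t: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0)
    )
    removed_ectopic_t: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0)
    )

    def __len__(self) -> int:
        return int(self.nn_ms.size)


# ---------------------------------------------------------------------------
# Coverage and epoching


def _in_range(rr_ms: np.ndarray) -> np.ndarray:
    return (rr_ms >= RR_MIN_MS) & (rr_ms <= RR_MAX_MS)


def epoch_coverage(
    stream: RRStream,
    epoch: Epoch,
    basis: Literal["time", "beats"] = "time",
) -> float:
    """Fraction of an epoch covered by plausible R-R data, clipped to [0, 1].

    ``basis='time'`` (default) sums the in-range intervals whose
    timestamps fall in the epoch and divides by the epoch length;
    ``basis='beats'`` counts in-range records against the number the
    stream's median interval would imply.
    """
    m = (stream.time_s >= epoch.start_s) & (stream.time_s < epoch.end_s)
    rr = stream.rr_ms[m]
    rr = rr[np.isfinite(rr) & _in_range(rr)]
    if rr.size == 0:
        return 0.0
    if basis == "time":
        frac = rr.sum() / 1000.0 / epoch.epoch_len_s
    else:
        all_rr = stream.rr_ms[np.isfinite(stream.rr_ms) & _in_range(stream.rr_ms)]
        nominal_s = np.median(all_rr) / 1000.0
        frac = rr.size / (epoch.epoch_len_s / nominal_s)
    return float(np.clip(frac, 0.0, 1.0))


def _dominant_label(track: LabelTrack, kind: str, start: float, end: float):
    sel = track.select(kind)
    if len(sel) == 0:
        return None
    share: dict = {}
    for s, e, v in zip(sel.start_s, sel.end_s, sel.value):
        overlap = min(e, end) - max(s, start)
        if overlap > 0:
            share[v] = share.get(v, 0.0) + overlap
    if not share:
        return None
    return max(share.items(), key=lambda kv: kv[1])[0]


def segment_epochs(
    stream: RRStream,
    epoch_len_s: float = 300.0,
    threshold: float = 0.40,
    labels: LabelTrack | None = None,
    t0: float = 0.0,
    basis: Literal["time", "beats"] = "time",
) -> list[Epoch]:
    """Tile the stream into contiguous epochs and flag the valid ones.

    An epoch is valid when its coverage meets the threshold
    (inclusive). Each label kind present in ``labels`` is assigned the
    value covering the largest share of the epoch.
    """
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be > 0")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if len(stream) == 0:
        return []
    t_end = float(np.max(stream.time_s))
    n_epochs = int(np.ceil((t_end - t0) / epoch_len_s)) or 1
    epochs = []
    kinds = sorted(set(labels.kind)) if labels is not None else []
    for k in range(n_epochs):
        ep = Epoch(start_s=t0 + k * epoch_len_s, end_s=t0 + (k + 1) * epoch_len_s)
        ep.coverage = epoch_coverage(stream, ep, basis=basis)
        ep.valid = ep.coverage >= threshold
        for kind in kinds:
            lab = _dominant_label(labels, kind, ep.start_s, ep.end_s)
            if lab is not None:
                ep.labels[kind] = lab
        epochs.append(ep)
    return epochs


def hourly_coverage(
    epochs: Sequence[Epoch],
    epoch_len_s: float = 300.0,
    stream: RRStream | None = None,
) -> pd.DataFrame:
    """Per-hour processed coverage plus day-part and full-day aggregates.

    Processed coverage of an hour is the number of valid epochs divided
    by the number of epochs that fit in an hour (12 for 5-min epochs).
    When the raw stream is supplied, raw coverage (summed in-range
    interval time over the hour) is reported alongside. Hour 0 is the
    start of the recording timeline, taken as midnight.
    """
    if not epochs:
        return pd.DataFrame(columns=["period", "processed_pct", "raw_pct"])
    per_hour = int(round(3600.0 / epoch_len_s))
    t_end = max(ep.end_s for ep in epochs)
    n_hours = int(np.ceil(t_end / 3600.0))
    rows = []
    hourly_proc = np.zeros(n_hours)
    hourly_raw = np.full(n_hours, np.nan)
    for h in range(n_hours):
        lo, hi = h * 3600.0, (h + 1) * 3600.0
        n_valid = sum(1 for ep in epochs if ep.valid and lo <= ep.start_s < hi)
        hourly_proc[h] = 100.0 * n_valid / per_hour
        if stream is not None:
            hourly_raw[h] = 100.0 * epoch_coverage(stream, Epoch(lo, hi))
        rows.append(
            {
                "period": f"hour_{h:02d}",
                "processed_pct": hourly_proc[h],
                "raw_pct": hourly_raw[h],
            }
        )
    for name, (lo_h, hi_h) in DAY_PARTS.items():
        hi_h = min(hi_h, n_hours)
        if hi_h <= lo_h:
            continue
        rows.append(
            {
                "period": name,
                "processed_pct": float(np.mean(hourly_proc[lo_h:hi_h])),
                "raw_pct": float(np.mean(hourly_raw[lo_h:hi_h])),
            }
        )
    rows.append(
        {
            "period": "full_day",
            "processed_pct": float(np.mean(hourly_proc)),
            "raw_pct": float(np.mean(hourly_raw)),
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# R-R -> N-N cleaning


def malik_mask(rr_ms: np.ndarray) -> np.ndarray:
    """Flag ectopic intervals by successive-interval deviation above 20%.

    An interval is flagged when it deviates more than 20% from *both*
    the last accepted (unflagged) interval and the immediately
    preceding raw interval; the first element is never flagged. The
    two-baseline rule is what makes the filter cascade-proof in both
    directions: a single artifact cannot drag the acceptance baseline
    with it (the accepted anchor ignores flagged values), and a run of
    artifacts cannot permanently capture the anchor either (the first
    normal interval after the run agrees with its raw predecessor and
    re-anchors the chain).
    """
    rr = np.asarray(rr_ms, dtype=float)
    mask = np.zeros(rr.size, dtype=bool)
    if rr.size == 0:
        return mask
    prev_accepted = rr[0]
    for i in range(1, rr.size):
        dev_acc = abs(rr[i] - prev_accepted) / prev_accepted
        dev_raw = abs(rr[i] - rr[i - 1]) / rr[i - 1]
        if dev_acc > ECTOPIC_DEVIATION and dev_raw > ECTOPIC_DEVIATION:
            mask[i] = True
        else:
            prev_accepted = rr[i]
    return mask


def _interp_interior(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill interior NaN runs over record index.

    Returns (filled values, mask of filled positions). Leading/trailing
    NaNs are left in place for the caller to drop.
    """
    v = values.copy()
    nan = ~np.isfinite(v)
    if not nan.any():
        return v, np.zeros(v.size, dtype=bool)
    idx = np.arange(v.size)
    good = idx[~nan]
    if good.size == 0:
        return v, np.zeros(v.size, dtype=bool)
    interior = nan & (idx > good[0]) & (idx < good[-1])
    v[interior] = np.interp(idx[interior], good, v[good])
    return v, interior


def clean_rr_to_nn(
    stream: RRStream,
    epoch: Epoch | None = None,
    interpolate: bool = True,
) -> NNSeries:
    """Run the full R-R -> N-N cleaning pipeline on one epoch (or stream).

    Raises :class:`EmptySeriesError` when nothing usable survives the
    outlier step; callers exclude such epochs downstream.
    """
    t = stream.time_s
    rr = stream.rr_ms
    if epoch is not None:
        m = (t >= epoch.start_s) & (t < epoch.end_s)
        t, rr = t[m], rr[m]

    # step 1: sort by timestamp (stable) and drop exact duplicates
    order = np.argsort(t, kind="stable")
    t, rr = t[order], rr[order]
    if t.size:
        same_t = np.concatenate(([False], np.isclose(np.diff(t), 0.0)))
        exact_dup = same_t & np.concatenate(([False], np.diff(rr) == 0.0))
        conflict = same_t & ~exact_dup
        if conflict.any():
            warnings.warn(
                f"{int(conflict.sum())} same-timestamp records with differing "
                "rr_ms; keeping the first of each",
                stacklevel=2,
            )
        keep = ~(exact_dup | conflict)
        t, rr = t[keep], rr[keep]

    rr = rr.astype(float).copy()
    prov = np.full(rr.size, "observed", dtype=object)

    # step 2: out-of-range intervals become missing
    bad = ~(_in_range(rr) & np.isfinite(rr))
    removed_outlier_t = t[bad]
    rr[bad] = np.nan
    if not np.isfinite(rr).any():
        raise EmptySeriesError("all intervals out of range")

    # step 3: interpolate (or drop) interior missing runs
    if interpolate:
        rr, filled = _interp_interior(rr)
        prov[filled] = "interpolated"
    else:
        keep = np.isfinite(rr)
        t, rr, prov = t[keep], rr[keep], prov[keep]

    # steps 4+5, iterated to a fixpoint: flag ectopic intervals, then
    # re-interpolate (or drop) and repeat until the values stop
    # changing. Interpolated replacements can change which neighbours
    # an interval is compared against, so a single pass is not a
    # fixpoint of its own output; iterating makes cleaning idempotent
    # by construction (converges in 1-3 passes in practice).
    removed_ectopic: list[np.ndarray] = []
    for _ in range(20):
        present = np.isfinite(rr)
        flags = np.zeros(rr.size, dtype=bool)
        flags[present] = malik_mask(rr[present])
        if not flags.any():
            break
        removed_ectopic.append(t[flags])
        prev = rr.copy()
        rr[flags] = np.nan
        if interpolate:
            rr, filled = _interp_interior(rr)
            prov[filled] = "interpolated"
            same = np.isfinite(rr) & np.isfinite(prev) & np.isclose(rr, prev)
            if same[np.isfinite(rr)].all() and np.isfinite(rr).sum() == np.isfinite(prev).sum():
                break
        else:
            keep = np.isfinite(rr)
            t, rr, prov = t[keep], rr[keep], prov[keep]
    removed_ectopic_t = (
        np.unique(np.concatenate(removed_ectopic)) if removed_ectopic else np.empty(0)
    )
    keep = np.isfinite(rr)
    t, rr, prov = t[keep], rr[keep], prov[keep]
    if rr.size == 0:
        raise EmptySeriesError("no intervals survive cleaning")

    return NNSeries(
        time_s=t,
        nn_ms=rr,
        provenance=prov,
        epoch=epoch,
        removed_outlier_t=removed_outlier_t,
        removed_ectopic_t=removed_ectopic_t,
    )
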