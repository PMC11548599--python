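# Methods

This note documents the models, conventions and numerical choices
behind `pulsebench`, and what the synthetic-data tests do and do not
establish about real wearable data.

## Interval model of the synthetic generator

Beat times are generated by integrating an interval-domain model:

    RR(t) = mean_rr + a_LF·sin(2π f_LF t) + a_HF·sin(2π f_HF t + φ)
            + a_circ·cos(2π (t − 4 h)/24 h) + ε,   ε ~ N(0, σ_jitter²)

with `t_{i+1} = t_i + RR(t_i)/1000`. Defaults: mean RR 1000 ms
(900 ms for the study-day scripts), f_LF = 0.1 Hz with a_LF = 30 ms,
f_HF = 0.25 Hz with a_HF = 20 ms, jitter 10–25 ms depending on the
scenario, φ drawn once per seed. The two sinusoids put controllable
power into the conventional LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz)
HRV bands; a sinusoid of amplitude *a* contributes variance a²/2, which
is the oracle the spectral tests check against. The modulation lives in
the **interval domain** (not an integral-pulse-frequency model): this
is the simplest construction whose band powers are exactly
controllable, at the cost of not reproducing the subtle asymmetries an
IPFM model would give. Intervals are clipped to [310, 1990] ms so the
clean train never trips the physiological-outlier rule by chance.

Ectopy is injected by splitting an interval at 40% of its span (early
beat plus compensatory remainder). Both halves then deviate > 20% from
their predecessor by construction, which is the property the cleaning
filter keys on — injected ectopy is detectable *by design*, so the
cleaning tests measure the filter's bookkeeping, not its clinical
sensitivity to real ectopic morphology.

Device degradation operates on the record stream: exact duplicate
records, adjacent-record order swaps, dropout windows, and replacement
of intervals with out-of-range values (50–295 or 2010–4000 ms), each at
a configured per-record probability. Every injection site is recorded
in the ground truth.

The PPG pulse is a log-normal-shaped template (σ = 0.45, time-to-peak
0.35·pulse_width, width 0.35 s) whose mode coincides with the beat time
— typical peripheral-pulse asymmetry, fast upstroke and slow decay; the
exact morphology is a free parameter because nothing downstream depends
on it beyond having one dominant maximum per beat. Motion artefact is
band-limited (0.5–8 Hz) Gaussian noise confined to configured windows,
i.e. it is *in-band by construction* and cannot be removed by the
band-pass prefilter — the hardest case for the detectors. Saturation is
modelled by replacing (not adding to) the signal with a constant, so
the 0.2 s flat-run rule triggers exactly. The ECG template is a
biphasic QRS-like spike (R Gaussian σ = 8 ms with small Q/S troughs) at
250 Hz; PPG is 25 Hz, a common wrist-device rate.

What the generator does **not** emulate: respiration-coupled amplitude
modulation, SpO₂/accelerometer channels, skin-tone or contact-pressure
effects, realistic arrhythmia morphology, vendor-specific firmware
artifacts. Passing tests therefore demonstrate that the *pipeline
machinery* is correct and well-calibrated, not that any particular
commercial device is accurate.

## Coverage and epoching

Epoch coverage is the summed duration of in-range R-R records with
timestamps inside the epoch divided by the epoch length, clipped to
[0, 1]; a beat-count basis is available as an option since a time basis
is only one reading of "data coverage". Validity is inclusive
(coverage ≥ 0.40), and the 300/2000 ms bounds are kept in range —
boundary behaviour is a convention, stated here once. Epoch tiling is
anchored at the stream start; label kinds are assigned by dominance
(largest overlap share). Hourly processed coverage is valid epochs per
hour divided by 12 (for 5-min epochs), aggregated into night (00–08),
day (08–20), evening (20–24) and full-day parts with t = 0 taken as
midnight.

## R-R → N-N cleaning

Pipeline order is fixed: (1) stable sort by timestamp, drop exact
(timestamp, value) duplicates — same-timestamp conflicts keep the first
record and warn; (2) intervals outside 300–2000 ms become missing;
(3) interior missing runs are linearly interpolated over record index
(wall-time interpolation exists as an option; index-linear is the
simplest reading of gap filling and is what the tests pin down);
(4) ectopy filtering; (5) re-interpolation, with leading/trailing
missing dropped. The ablation switch makes steps 3 and 5 drop instead
of fill.

The ectopy rule flags an interval when it deviates more than 20% from
**both** the last accepted interval and the immediately preceding raw
interval. A single-baseline "last accepted" rule is cascade-prone in a
way that only shows up at scale: a run of consecutive out-of-range
records interpolated in step 3 can form a ramp whose per-step deviation
stays under 20%, walking the acceptance baseline down to an
artifact-level value; from there every normal interval is rejected and
short (ectopic-length) intervals are accepted, inverting the filter's
behaviour for hundreds of beats. The second baseline (previous raw
interval) re-anchors the chain at the first pair of mutually consistent
intervals, bounding any cascade to a handful of beats, while a lone
artifact still cannot drag the baseline because the accepted anchor
ignores flagged values.

Steps 4–5 are iterated to a fixpoint (flag, re-interpolate, repeat
until values stop changing; 1–3 passes in practice, hard cap 20).
Interpolated replacements change which neighbours an interval is
compared against, so one pass is not idempotent on its own output;
iterating makes `clean(clean(x)) = clean(x)` hold by construction.

## HRV features

All SDs use the sample formula (ddof = 1). SDSD is computed about a
zero mean of successive differences and therefore equals RMSSD
identically; this convention is deliberate (a mean-subtracted variant
sits behind a flag) because the two feature definitions coincide for
stationary interval series and reporting both then carries no extra
information. Mean HR is the mean of per-interval instantaneous rates
60000/NN_i — consistent with also reporting an SD of instantaneous HR —
rather than 60000/mean(NN); the alternative is exposed as an option.

Spectral powers: the tachogram is placed on its cumulative-time axis,
cubic-resampled to 4 Hz, linearly detrended, and integrated over the
LF/HF bands from a Welch periodogram (Hann, nperseg = min(n, 256),
trapezoidal band integration). A Lomb–Scargle path exists for gappy
epochs. 4 Hz and Welch are conventions, not derived quantities; the
tests only require that a single-band injected modulation lands ≥ 90%
of its power in the right band and recovers a²/2 within 15%.

Sample entropy: m = 2, r = 0.2·SD(series), Chebyshev distance,
self-matches excluded, SampEn = −ln(A/B). A constant series returns 0
(every template matches); A = 0 or B = 0 returns missing rather than
±∞. The implementation is a vectorised pairwise-distance computation,
checked to 1e-10 against a literal O(n²) counting loop.

## Beat detection

All seven detectors run behind one contract: zero-phase order-4
Butterworth band-pass 0.5–8 Hz (one detector's published band, adopted
globally so every kernel sees the same signal), detector-specific
windows (6 s / 20% overlap for the scalogram methods, 20 s / 15% for
the attractor method, 60 s chunks for the windowless descriptions,
one continuous pass for the streaming detector), merge of window
outputs with duplicates closer than 0.25× the median interbeat interval
collapsed to the earlier detection, and removal of beats inside flat
runs longer than 0.2 s (flatness is measured on the raw signal — the
band-pass destroys exact equality). Beat time is the pulse peak for
every detector, for comparability; onset-type detectors refine forward
to the following maximum.

Scalogram kernel (AMPD/MSPTD): boolean local-maxima matrix over scales
k = 1..⌊n/2⌋ (entry true when a sample exceeds both neighbours at lag
k, with an epsilon of 1e-10 of the raw amplitude so float noise from
detrending cannot fabricate maxima); the optimal scale λ is the row
with the most maxima (ties to the smallest scale); peaks are samples
that are maxima at **every scale up to and including λ** — the
inclusive convention is forced by the degenerate case λ = 1, where a
strictly-smaller-than-λ truncation would retain no scales at all.
A peak within λ samples of a window edge is structurally invisible;
the 20% window overlap exists to recover those. MSPTD adds the minima
scalogram for onsets and a ±5%-of-fs extremum refinement.

The SPAR kernel gates on the **global** autocorrelation peak (0.3–3 s):
if the dominant periodicity falls outside the 40–200 BPM lag band the
window is skipped rather than force-fitted — out-of-range rhythms are
inadmissible, not mis-estimated. The delay embedding uses two delays of
τ/3, projection onto the plane normal to (1,1,1), and an 18-angle
rotation search scored by crossing-interval regularity.

Open kernel details that the published descriptions leave unstated were
implemented as the simplest faithful reading and are flagged here as
assumptions: ABD's derivative filter is a smoothed first difference
with a 75th-percentile threshold; the streaming detector's adaptive
threshold is half the running slope peak (one-tenth update increments,
one-third secondary threshold after 2 s of silence, 340 ms lockout);
HeartPy-style segment rejection discards the local ten-beat stretch
containing more than three implausible peak-to-peak intervals, not the
whole analysis window.

## ECG reference and alignment

The reference is the consensus of two structurally different R-peak
detectors (Pan–Tompkins-style integration pipeline; gradient-energy
percentile detector), paired greedily in time order within 150 ms;
a kept beat is the midpoint of its pair, and any 20-s tile (anchored at
t = 0) containing an unpaired beat from either detector contributes no
reference beats. Detections in the outermost 0.2 s of the record are
dropped (zero-phase filter transients; a boundary-clipped QRS has no
reliable peak).

Lag search scans ±10 s in 20 ms steps, counting reference beats whose
nearest shifted test beat is strictly within 150 ms. Count ties break
first to the smallest mean nearest-beat distance, then to the smallest
absolute lag. The distance tie-break is load-bearing: whenever the two
series agree to well within the tolerance, *every* candidate lag with
error below the tolerance matches every beat and the count saturates —
an |lag|-only rule would then systematically return the tie-set edge
nearest zero instead of the true offset. The exact-recovery test runs
with detection jitter uniform on ±140 ms, deliberately comparable to
the 150 ms tolerance, because that is the regime in which the matched
*count* itself pins the lag; the tie-break then handles the
low-jitter regime.

## Statistics

ICC(2,1) (two-way random effects, absolute agreement, single
measurement) is computed from the ANOVA decomposition with denominator
`MSR + (k−1)·MSE + k·(MSC − MSE)/n`; the p-value is the F test of
MSR/MSE. The implementation is pinned to 1e-10 against an independent
sums-of-squares oracle and cross-checked against `pingouin`'s ICC(A,1)
where available. Matrices whose total variance is zero up to float
cancellation (relative 1e-20) are reported undefined rather than
returning noise-driven values. Bland–Altman limits are bias ± 1.96·SD
of differences (sample SD). PPV with zero detections is defined as 0
so aggregation stays total. Reliability reports both ICC (headline) and
Spearman ρ per feature over synchronized epoch pairs.

## Problem sizes and study conditions

The default test and acceptance workloads were sized once, as the
package's own choice of desk-scale study conditions: detector recovery
on 10-min recordings over 20 seeds; the motion-noise ladder on 2-min
recordings at amplitudes {0, 0.25, 0.5, 1, 2}× pulse height over 20
seeds; cleaning exactness on a 1-h stream with 5% outlier and 2%
ectopic injection; HRV recovery on 5-min epochs over 50 seeds; lag
recovery over 50 random grid lags on a 5-min train; reliability on
200 synchronized epoch pairs at a configured between-day correlation
of 0.6, carried by a shared per-epoch mean-RR profile (SD 60 ms) whose
within-epoch sampling noise is small enough not to attenuate the ICC
appreciably. Dispersion features (SDNN, RMSSD) carry no between-day
signal under this generator, so only mean-level features are expected
to recover the configured correlation — visible in the reliability
driver's output.

## Known limitations

- Interval-domain modulation means PPG pulse *amplitude* carries no
  physiological signal; detectors are only ever tested on timing.
- The noise ladder uses stationary in-band Gaussian bursts; real motion
  artefact is impulsive and correlated with posture changes.
- The ectopy filter is tested against its own definition (deviation
  > 20%); no claim is made about clinically annotated ectopy.
- The two-day reliability generator shares a per-epoch latent level;
  real day-to-day HRV stability has richer structure (sleep staging,
  activity carry-over) that a single correlation parameter cannot
  express.
- Whether epoch coverage should be computed on a time or beat-count
  basis is unresolved upstream; both are implemented, time is the
  default, and all shipped numbers use it.
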