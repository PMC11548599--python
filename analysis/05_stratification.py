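"""Factors that move the wrist device's error: coverage and activity.

Two stratified re-analyses of the simulated study day:

1. coverage-threshold sweep — the epoch-validity threshold is raised
   from 40% to 100% in 10% steps and the wrist-vs-reference relative
   error of each feature is recomputed over the surviving epochs;
2. activity strata — epochs are labelled by their dominant activity and
   sleep state, and agreement is recomputed per level.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pulsebench.evaluation import feature_agreement, stratified_agreement
from pulsebench.hrv import FEATURE_NAMES, extract_features
from pulsebench.io_formats import read_label_track, read_rr_stream
from pulsebench.preprocess import EmptySeriesError, clean_rr_to_nn, segment_epochs

HEADLINE = ("mean_hr_bpm", "mean_nn_ms", "sdnn_ms", "rmssd_ms", "lf_ms2", "sample_entropy")


def features_with_meta(stream, labels, threshold):
    rows = []
    for k, ep in enumerate(
        segment_epochs(stream, epoch_len_s=300.0, threshold=threshold, labels=labels)
    ):
        row = {"epoch": k, "coverage": ep.coverage,
               "sleep": ep.labels.get("sleep_state"),
               "activity": ep.labels.get("activity")}
        if ep.valid:
            try:
                row.update(extract_features(clean_rr_to_nn(stream, ep)).as_dict())
            except EmptySeriesError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def paired(f_ppg, f_ecg):
    merged = f_ppg.merge(f_ecg, on="epoch", suffixes=("_ppg", "_ecg"))
    merged = merged.dropna(subset=[f"{f}_ppg" for f in HEADLINE] + [f"{f}_ecg" for f in HEADLINE])
    a = merged[[f"{f}_ppg" for f in FEATURE_NAMES]].rename(columns=lambda c: c[:-4])
    b = merged[[f"{f}_ecg" for f in FEATURE_NAMES]].rename(columns=lambda c: c[:-4])
    return merged, a, b


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--studydir", type=Path, default=Path("results/study"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    ppg = read_rr_stream(args.studydir / "rr_ppg.csv", "ppg-wrist")
    ecg = read_rr_stream(args.studydir / "rr_ecg.csv", "ecg-patch")
    labels = read_label_track(args.studydir / "labels.csv")

    # 1. coverage threshold sweep
    sweep_rows = []
    for thr in np.arange(0.4, 1.001, 0.1):
        f_ppg = features_with_meta(ppg, labels, float(thr))
        f_ecg = features_with_meta(ecg, labels, float(thr))
        merged, a, b = paired(f_ppg, f_ecg)
        if len(merged) < 2:
            continue
        table = feature_agreement(a, b)
        sweep_rows.append(
            {"threshold_pct": round(100 * thr), "n_epochs": len(merged),
             **{f"mre_{f}": table.loc[f, "mre_pct"] for f in HEADLINE}}
        )
    sweep = pd.DataFrame(sweep_rows)
    args.outdir.mkdir(parents=True, exist_ok=True)
    sweep.to_csv(args.outdir / "coverage_sweep.csv", index=False)
    print("coverage-threshold sweep (relative error %, wrist vs reference):")
    print(sweep.round(2).to_string(index=False))

    # 2. activity / sleep strata at the default 40% threshold
    f_ppg = features_with_meta(ppg, labels, 0.40)
    f_ecg = features_with_meta(ecg, labels, 0.40)
    merged, a, b = paired(f_ppg, f_ecg)
    strata = merged["sleep_ppg"].fillna("unlabelled").to_numpy(object)
    per_level = stratified_agreement(a, b, strata)
    print("\nper sleep-state relative error (%):")
    rows = []
    for level, table in per_level.items():
        rows.append({"stratum": level, "n": int(table["n_epochs"].iloc[0]),
                     **{f: round(table.loc[f, "mre_pct"], 2) for f in HEADLINE}})
    strata_table = pd.DataFrame(rows)
    print(strata_table.to_string(index=False))
    strata_table.to_csv(args.outdir / "strata_agreement.csv", index=False)


if __name__ == "__main__":
    main()
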