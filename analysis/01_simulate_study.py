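"""Simulate one study day of paired wearable recordings.

Generates a ground-truthed 24-hour beat train with circadian and LF/HF
autonomic structure, derives two device R-R streams from it — a clean
ECG-patch-like reference and a wrist-PPG-like stream with dropouts
(concentrated in active daytime hours), duplicate records, occasional
impossible intervals and ectopy — plus a posture/activity/sleep label
track and a 10-minute raw PPG/ECG waveform excerpt for beat-detector
benchmarking. All downstream scripts read from ``results/study/``.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from pulsebench.io_formats import (
    RRStream,
    write_label_track,
    write_rr_stream,
    write_waveform,
)
from pulsebench.synthgen import (
    SimConfig,
    degrade_to_device_stream,
    simulate_beat_train,
    simulate_label_track,
    synthesize_ecg,
    synthesize_ppg,
)

DAY_S = 24 * 3600.0


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/study"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    # daytime dropouts emulate the lower daytime beat-detection coverage
    # wrist devices show in free living (worst during activity hours)
    rng = np.random.default_rng(args.seed)
    dropouts = []
    t = 9 * 3600.0
    while t < 22 * 3600.0:
        gap = float(rng.uniform(300, 1500))
        dropouts.append((t, t + gap))
        t += gap + float(rng.uniform(600, 2400))

    cfg = SimConfig(
        duration_s=DAY_S,
        mean_rr_ms=900.0,
        circadian_amp_ms=120.0,
        lf_amp_ms=30.0,
        hf_amp_ms=20.0,
        jitter_sd_ms=20.0,
        ectopic_rate=0.005,
        outlier_rate=0.01,
        dup_rate=0.005,
        shuffle_rate=0.002,
        dropout_spec=dropouts,
        seed=args.seed,
    )
    beats, truth = simulate_beat_train(cfg)
    ppg_stream = degrade_to_device_stream(beats, cfg, ground_truth=truth, device="ppg-wrist")
    ref_stream = RRStream(beats[1:], np.diff(beats) * 1000.0, device="ecg-patch")

    write_rr_stream(ppg_stream, out / "rr_ppg.csv")
    write_rr_stream(ref_stream, out / "rr_ecg.csv")
    truth.to_json(out / "ground_truth.json")
    write_label_track(simulate_label_track(DAY_S, seed=args.seed), out / "labels.csv")

    # 10-min raw waveform excerpt (03:00-03:10, quiet sleep) for detectors
    excerpt_cfg = SimConfig(
        duration_s=600.0, mean_rr_ms=1000.0, lf_amp_ms=30.0, hf_amp_ms=20.0,
        jitter_sd_ms=10.0, seed=args.seed + 1,
    )
    ex_beats, ex_truth = simulate_beat_train(excerpt_cfg)
    write_waveform(synthesize_ppg(ex_beats, excerpt_cfg), out / "ppg_excerpt.csv")
    write_waveform(synthesize_ecg(ex_beats, excerpt_cfg), out / "ecg_excerpt.csv")
    ex_truth.to_json(out / "ground_truth_excerpt.json")
    (out / "sim_config.json").write_text(json.dumps(cfg.to_dict(), indent=2))

    print(f"day simulated: {beats.size} beats, {len(ppg_stream)} PPG-device records "
          f"({len(ref_stream)} reference records), {len(dropouts)} daytime dropouts")
    print(f"waveform excerpt: 600 s at {excerpt_cfg.ppg_fs_hz:.0f} Hz PPG / "
          f"{excerpt_cfg.ecg_fs_hz:.0f} Hz ECG, {ex_beats.size} true beats")
    print(f"artifacts written to {out}/")


if __name__ == "__main__":
    main()
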