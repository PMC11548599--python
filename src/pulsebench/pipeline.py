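"""End-to-end pipeline: simulate -> detect -> clean -> featurize -> evaluate.

One :class:`RunConfig` drives a reproducible run. Every stage writes its
artifacts under the output directory together with a manifest (config
hash, seed, package version), and a rerun with the identical config
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecgref import consensus, detect_r_gradient, detect_r_pt
from .evaluation import (
    align_and_match,
    feature_agreement,
    score_detection,
    test_retest,
)
from .hrv import FEATURE_NAMES, extract_features
from .io_formats import RRStream, read_rr_stream, read_waveform, write_beats, write_rr_stream, write_waveform
from .ppgbeats import run_detector
from .preprocess import EmptySeriesError, clean_rr_to_nn, segment_epochs
from .synthgen import (
    SimConfig,
    degrade_to_device_stream,
    simulate_beat_train,
    simulate_day_pair,
    synthesize_ecg,
    synthesize_ppg,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclasses.dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 0
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    detectors: tuple[str, ...] = ("msptd", "ampd", "erma")
    epoch_len_s: float = 300.0
    coverage_threshold: float = 0.40
    interpolate: bool = True
    device_noise_ms: float = 10.0  # measurement noise of the PPG-like device
    reliability_epochs: int = 0  # 0 disables the reliability stage
    between_day_corr: float = 0.6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {**dataclasses.asdict(self), "sim": self.sim.to_dict()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _outdir(config: RunConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write_manifest(config: RunConfig, out: Path, stage: str) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def stage_simulate(config: RunConfig) -> dict[str, Path]:
    """Simulate one recording: truth, two R-R streams, PPG and ECG."""
    out = _outdir(config)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    beats, truth = simulate_beat_train(sim)
    stream = degrade_to_device_stream(beats, sim, ground_truth=truth, device="ppg-sim")

    # reference device stream: clean intervals, no degradation
    ref_stream = RRStream(beats[1:], np.diff(beats) * 1000.0, device="ecg-sim")
    # PPG-like device: degraded records with measurement noise
    noisy = stream.rr_ms + sim.rng("device-noise").normal(
        0.0, config.device_noise_ms, stream.rr_ms.size
    )
    dev_stream = RRStream(stream.time_s, np.clip(noisy, 1.0, None), device="ppg-sim")

    ppg = synthesize_ppg(beats, sim)
    ecg = synthesize_ecg(beats, sim)
    paths = {
        "truth": out / "ground_truth.json",
        "rr_ref": out / "rr_ecg.csv",
        "rr_ppg": out / "rr_ppg.csv",
        "ppg": out / "ppg.csv",
        "ecg": out / "ecg.csv",
    }
    truth.to_json(paths["truth"])
    write_rr_stream(ref_stream, paths["rr_ref"])
    write_rr_stream(dev_stream, paths["rr_ppg"])
    write_waveform(ppg, paths["ppg"])
    write_waveform(ecg, paths["ecg"])
    _write_manifest(config, out, "simulate")
    return paths


def stage_detect(config: RunConfig) -> pd.DataFrame:
    """Run the configured PPG detectors and score them against the ECG
    consensus reference."""
    out = _outdir(config)
    ppg_path = out / "ppg.csv"
    ecg_path = out / "ecg.csv"
    if not ppg_path.exists() or not ecg_path.exists():
        raise StageError("detect: missing ppg.csv/ecg.csv (run simulate first)")
    ppg = read_waveform(ppg_path)
    ecg = read_waveform(ecg_path)
    ref = consensus(detect_r_pt(ecg), detect_r_gradient(ecg))
    rows = []
    for name in config.detectors:
        beats = run_detector(ppg, name)
        write_beats(beats.times_s, out / f"beats_{name}.csv", detector=name)
        if len(beats) == 0 or len(ref) == 0:
            rows.append({"detector": name, "f1": 0.0, "n_test": len(beats)})
            continue
        lag, pairs = align_and_match(beats, ref)
        score = score_detection(pairs, n_ref=len(ref), n_test=len(beats), lag_s=lag)
        rows.append(
            {
                "detector": name,
                "n_ref": score.n_ref,
                "n_test": score.n_test,
                "n_correct": score.n_correct,
                "sensitivity": score.sensitivity,
                "ppv": score.ppv,
                "f1": score.f1,
                "lag_s": score.lag_s,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "detection_scores.csv", index=False)
    return df


def stage_features(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Clean both R-R streams and extract per-epoch features."""
    out = _outdir(config)
    frames = {}
    for tag in ("ecg", "ppg"):
        path = out / f"rr_{tag}.csv"
        if not path.exists():
            raise StageError(f"features: missing {path.name} (run simulate first)")
        stream = read_rr_stream(path, device_label=tag)
        epochs = segment_epochs(
            stream,
            epoch_len_s=config.epoch_len_s,
            threshold=config.coverage_threshold,
        )
        rows = []
        for k, ep in enumerate(epochs):
            row: dict = {"epoch": k, "start_s": ep.start_s, "coverage": ep.coverage}
            if ep.valid:
                try:
                    nn = clean_rr_to_nn(stream, ep, interpolate=config.interpolate)
                    row.update(extract_features(nn).as_dict())
                except EmptySeriesError:
                    pass
            rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(out / f"features_{tag}.csv", index=False)
        frames[tag] = df
    return frames


def stage_validate(config: RunConfig) -> pd.DataFrame:
    """Feature agreement between the PPG-like device and the reference."""
    out = _outdir(config)
    frames = {}
    for tag in ("ecg", "ppg"):
        path = out / f"features_{tag}.csv"
        if not path.exists():
            raise StageError(f"validate: missing {path.name} (run features first)")
        frames[tag] = pd.read_csv(path)
    merged = frames["ppg"].merge(frames["ecg"], on="epoch", suffixes=("_ppg", "_ecg"))
    mutual = merged.dropna(subset=[f"{f}_ppg" for f in ("mean_nn_ms",)]).dropna(
        subset=["mean_nn_ms_ecg"]
    )
    ppg = mutual[[f"{f}_ppg" for f in FEATURE_NAMES]].rename(
        columns=lambda c: c[:-4]
    )
    ecg = mutual[[f"{f}_ecg" for f in FEATURE_NAMES]].rename(
        columns=lambda c: c[:-4]
    )
    table = feature_agreement(ppg, ecg)
    table.to_csv(out / "agreement.csv")
    return table


def stage_reliability(config: RunConfig) -> pd.DataFrame:
    """Test–retest ICC between two simulated days of synchronized epochs."""
    out = _outdir(config)
    n = config.reliability_epochs
    if n <= 0:
        raise StageError("reliability: reliability_epochs must be > 0")
    day1, day2 = simulate_day_pair(
        n_epochs=n,
        between_day_corr=config.between_day_corr,
        epoch_len_s=config.epoch_len_s,
        base=config.sim,
        seed=config.seed,
    )
    f1 = pd.DataFrame([extract_features(nn).as_dict() for nn in day1])
    f2 = pd.DataFrame([extract_features(nn).as_dict() for nn in day2])
    table = test_retest(f1, f2)
    table.to_csv(out / "reliability.csv")
    return table


_STAGES = {
    "simulate": stage_simulate,
    "detect": stage_detect,
    "features": stage_features,
    "validate": stage_validate,
    "reliability": stage_reliability,
}


def run(config: RunConfig, stages: tuple[str, ...] = ("simulate", "detect", "features", "validate")) -> dict:
    """Execute the requested stages in order; fail fast with a stage tag."""
    results = {}
    for stage in stages:
        if stage not in _STAGES:
            raise StageError(f"{stage}: unknown stage")
        log.info("running stage %s", stage)
        try:
            results[stage] = _STAGES[stage](config)
        except StageError:
            raise
        except Exception as exc:  # surface which stage broke
            raise StageError(f"{stage}: {exc}") from exc
    return results
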