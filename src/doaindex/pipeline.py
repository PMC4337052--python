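"""End-to-end orchestration: generate -> filter -> entropy -> train ->
predict -> evaluate, as one reproducible run.

Every stage writes plain CSV/JSON artifacts into the run directory so any
stage can be inspected or replaced independently. A single global seed fans
out to per-stage, per-session seeds through ``numpy.random.SeedSequence``
spawning, so adding a stage never perturbs the randomness of earlier
stages, and rerunning an identical configuration reproduces every numeric
output byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ann, evaluate, io_formats, memd, sampen, synthetic_data
from .model import DoaModel, DoaResults

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    seed: int = 1
    n_sessions: int = 12
    duration_s: float = 600.0
    fs: float = 125.0
    artifact_rate: float = 1.0
    sift: memd.SiftConfig = field(default_factory=memd.SiftConfig)
    sampen: sampen.SampEnParams = field(default_factory=sampen.SampEnParams)
    train: ann.TrainConfig = field(default_factory=ann.TrainConfig)
    lag: int = 6
    imf_indices: tuple[int, ...] = (2, 3)
    split_proportions: tuple[int, int, int] = (30, 10, 24)
    threshold: float = evaluate.AWAKE_THRESHOLD
    root_mse: bool = False
    filter_eeg: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["imf_indices"] = list(self.imf_indices)
        d["split_proportions"] = list(self.split_proportions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sift" in d:
            d["sift"] = memd.SiftConfig(**d["sift"])
        if "sampen" in d:
            d["sampen"] = sampen.SampEnParams(**d["sampen"])
        if "train" in d:
            d["train"] = ann.TrainConfig(**d["train"])
        for key in ("imf_indices", "split_proportions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31.

    Stages have fixed ordinals, so the mapping is stable when stages are
    added: ``SeedSequence(global_seed).spawn()`` children are consumed in
    ordinal order and each child is hashed down to a 31-bit integer.
    """
    ordinals = {"generate": 0, "memd": 1, "train": 2}
    ss = np.random.SeedSequence(global_seed)
    children = ss.spawn(len(ordinals))
    child = children[ordinals[stage]].spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % (2**31))


def _log(fh, message: str) -> None:
    fh.write(message + "\n")
    fh.flush()


def generate_cohort(config: RunConfig) -> list[io_formats.SessionBundle]:
    """Generate the run's synthetic sessions from the fanned-out seeds."""
    sessions = []
    for i in range(config.n_sessions):
        traj = synthetic_data.TrajectorySpec(
            duration_s=config.duration_s,
            induction_s=config.duration_s * 0.1,
            maintenance_s=config.duration_s * 0.3,
            emergence_s=config.duration_s * 0.8,
        )
        spec = synthetic_data.GeneratorSpec(
            trajectory=traj,
            fs=config.fs,
            artifact_rate=config.artifact_rate,
            noise_seed=stage_seed(config.seed, "generate", i),
        )
        bundle = synthetic_data.generate_session(spec)
        bundle.meta["session_id"] = f"s{i:02d}"
        sessions.append(bundle)
    return sessions


def run_pipeline(config: RunConfig, out_dir) -> DoaResults:
    """Execute all stages in order and write artifacts under ``out_dir``.

    Layout: ``sessions/<id>/`` (raw sessions), ``entropy/<id>.csv``,
    ``model.json``, ``predictions/<id>.csv``, ``report.csv``, ``run.yaml``
    (the exact configuration used) and ``run.log`` (timings and counts).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run.yaml")
    log = open(out / "run.log", "w")

    t0 = time.time()
    sessions = generate_cohort(config)
    for s in sessions:
        io_formats.write_session(s, out / "sessions" / s.session_id)
    _log(log, f"generate: {len(sessions)} sessions in {time.time() - t0:.1f}s")

    t0 = time.time()
    sift = dataclasses.replace(
        config.sift, noise_seed=stage_seed(config.seed, "memd")
    )
    try:
        model = DoaModel.from_sessions(
            sessions,
            sift_config=sift,
            sampen_params=config.sampen,
            lag=config.lag,
            imf_indices=config.imf_indices,
            split_proportions=config.split_proportions,
            filter_eeg=config.filter_eeg,
        )
    except Exception as exc:  # surface the failing stage and session
        log.close()
        raise RuntimeError(f"filter/entropy stage failed: {exc}") from exc
    entropy_dir = out / "entropy"
    entropy_dir.mkdir(exist_ok=True)
    for sid, track in model.entropy_tracks.items():
        np.savetxt(
            entropy_dir / f"{sid}.csv",
            np.column_stack([track.times, track.values]),
            fmt="%.17g",
            delimiter=",",
            header="time_s,sampen",
            comments="",
        )
    _log(
        log,
        f"filter+entropy: {sum(len(t) for t in model.entropy_tracks.values())} "
        f"epochs in {time.time() - t0:.1f}s",
    )

    t0 = time.time()
    train_cfg = dataclasses.replace(
        config.train, seed=stage_seed(config.seed, "train")
    )
    results = model.fit(train_cfg)
    (out / "model.json").write_text(results.mlp.to_json())
    _log(log, f"train: sessions {model.split.train} in {time.time() - t0:.1f}s")

    t0 = time.time()
    pred_dir = out / "predictions"
    pred_dir.mkdir(exist_ok=True)
    preds = results.predictions()
    for sid, series in preds.items():
        io_formats.write_index_series(series, pred_dir / f"{sid}.csv")
    report = results.evaluate(threshold=config.threshold, root_mse=config.root_mse)
    results._report = report
    report.to_csv(out / "report.csv")
    _log(log, f"predict+evaluate: {len(preds)} test sessions in {time.time() - t0:.1f}s")
    log.close()
    return results
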