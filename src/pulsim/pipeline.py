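"""End-to-end pipeline orchestration with reproducible configs and manifests.

Stages (in dependency order): ``simulate`` writes the synthetic study
(summaries CSV + schedules JSON); ``augment`` builds the encoded dataset
archive; ``train`` fits the surrogate and writes a checkpoint plus a metrics
CSV; ``crossval`` runs the leave-groups-out protocol; ``interpret`` writes
difference maps and region summaries for configured group pairs; ``sweep``
scores the reference schemes across antibody-timing offsets.  Each completed
stage appends a manifest entry (seed, outputs, SHA-256 hashes), and stages
re-read prior artifacts from disk, so a run is resumable stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import insilico, interpret, synthdata
from .model import ModelConfig, SurrogateModel, crossvalidate, train
from .preprocess import Dataset, LQConfig, build_dataset
from .synthdata import DynamicsParams, Study

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "augment", "train", "crossval", "interpret", "sweep")

_ARTIFACTS = {
    "simulate": ("summaries.csv", "schedules.json"),
    "augment": ("dataset.npz",),
    "train": ("model.npz", "model.json", "metrics.csv"),
    "crossval": ("crossval.csv",),
    "interpret": ("region_summary.csv",),
    "sweep": ("sweep.csv",),
}

_UPSTREAM = {
    "simulate": None,
    "augment": "simulate",
    "train": "augment",
    "crossval": "augment",
    "interpret": "train",
    "sweep": "train",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a full run needs: paths, seeds and module parameters."""

    workdir: str = "pulsim_run"
    simulate_seed: int = 11
    augment_seed: int = 23
    train_seed: int = 37
    crossval_seed: int = 51
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    lq: LQConfig = field(default_factory=LQConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_samples: int = 50
    sd_shrink: float = 5.0
    crossval_repeats: int = 5
    crossval_holdout_groups: int = 2
    #: group-id pairs (a, b) whose difference map a-b is summarized
    interpret_pairs: tuple[tuple[str, str], ...] = (("3", "1"), ("7", "3"), ("4", "3"), ("8", "7"))
    sweep_n_drug_days: tuple[int, ...] = (4, 2)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interpret_pairs"] = [list(p) for p in self.interpret_pairs]
        d["sweep_n_drug_days"] = list(self.sweep_n_drug_days)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "dynamics" in d and isinstance(d["dynamics"], Mapping):
            d["dynamics"] = DynamicsParams(**d["dynamics"])
        if "lq" in d and isinstance(d["lq"], Mapping):
            d["lq"] = LQConfig(**d["lq"])
        if "model" in d and isinstance(d["model"], Mapping):
            d["model"] = ModelConfig(**d["model"])
        if "interpret_pairs" in d:
            d["interpret_pairs"] = tuple(
                (str(a), str(b)) for a, b in d["interpret_pairs"]
            )
        if "sweep_n_drug_days" in d:
            d["sweep_n_drug_days"] = tuple(int(n) for n in d["sweep_n_drug_days"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(workdir: Path, stage: str) -> None:
    upstream = _UPSTREAM[stage]
    if upstream is None:
        return
    missing = [
        name for name in _ARTIFACTS[upstream] if not (workdir / name).exists()
    ]
    if missing:
        raise PipelineError(
            f"stage {stage!r} needs artifacts {missing} from stage "
            f"{upstream!r}; rerun {upstream!r} first"
        )


def _load_study(workdir: Path, config: RunConfig) -> Study:
    schedules = synthdata.schedules_from_json(
        (workdir / "schedules.json").read_text()
    )
    summaries = synthdata.summaries_from_frame(
        pd.read_csv(workdir / "summaries.csv", dtype={"group_id": str})
    )
    return Study(params=config.dynamics, schedules=schedules, summaries=summaries)


def _stage_simulate(workdir: Path, config: RunConfig) -> None:
    study = synthdata.generate_study(
        None, seed=config.simulate_seed, params=config.dynamics
    )
    synthdata.summaries_to_frame(study).to_csv(workdir / "summaries.csv", index=False)
    (workdir / "schedules.json").write_text(
        synthdata.schedules_to_json(study.schedules)
    )


def _stage_augment(workdir: Path, config: RunConfig) -> None:
    study = _load_study(workdir, config)
    dataset = build_dataset(
        study, config.n_samples, config.sd_shrink, config.augment_seed, config.lq
    )
    dataset.save(workdir / "dataset.npz")


def _stage_train(workdir: Path, config: RunConfig) -> None:
    dataset = Dataset.load(workdir / "dataset.npz")
    model_config = dataclasses.replace(config.model, seed=config.train_seed)
    result = train(dataset, model_config)
    result.model.save(workdir / "model")
    pd.DataFrame(
        {
            "epoch": np.arange(1, model_config.epochs + 1),
            "train_loss": result.train_curve,
            "val_loss": result.val_curve,
        }
    ).to_csv(workdir / "metrics.csv", index=False)


def _stage_crossval(workdir: Path, config: RunConfig) -> None:
    dataset = Dataset.load(workdir / "dataset.npz")
    folds = crossvalidate(
        dataset,
        config.model,
        n_repeats=config.crossval_repeats,
        n_holdout_groups=config.crossval_holdout_groups,
        seed=config.crossval_seed,
    )
    pd.DataFrame(
        {
            "fold": np.arange(1, len(folds) + 1),
            "holdout_groups": ["+".join(f.holdout_groups) for f in folds],
            "holdout_loss": [f.holdout_loss for f in folds],
            "final_train_loss": [f.result.train_curve[-1] for f in folds],
        }
    ).to_csv(workdir / "crossval.csv", index=False)


def _stage_interpret(workdir: Path, config: RunConfig) -> None:
    model = SurrogateModel.load(workdir / "model")
    study = _load_study(workdir, config)
    from .preprocess import encode_inputs

    summaries = []
    for a, b in config.interpret_pairs:
        for gid in (a, b):
            if gid not in study.schedules:
                raise PipelineError(
                    f"interpret pair ({a}, {b}): group {gid!r} not in study"
                )
        map_a = interpret.extract_hidden_map(
            model, encode_inputs(study.schedules[a], config.lq), provenance=a
        )
        map_b = interpret.extract_hidden_map(
            model, encode_inputs(study.schedules[b], config.lq), provenance=b
        )
        diff = interpret.difference_map(map_a, map_b)
        pd.DataFrame(diff).to_csv(
            workdir / f"diffmap_{a}_minus_{b}.csv", index=False
        )
        regions = [
            r for r in interpret.DEFAULT_REGIONS
            if r.rows[1] <= model.config.hidden_units
        ]
        summ = interpret.region_summary(diff, regions)
        summ.insert(0, "pair", f"{a}-{b}")
        summaries.append(summ)
    pd.concat(summaries, ignore_index=True).to_csv(
        workdir / "region_summary.csv", index=False
    )


def _stage_sweep(workdir: Path, config: RunConfig) -> None:
    model = SurrogateModel.load(workdir / "model")
    tables = []
    for n_days in config.sweep_n_drug_days:
        for spec in insilico.standard_cases(n_drug_days=n_days):
            tables.append(insilico.sweep_offsets(model, spec, config.lq))
    pd.concat(tables, ignore_index=True).to_csv(workdir / "sweep.csv", index=False)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "augment": _stage_augment,
    "train": _stage_train,
    "crossval": _stage_crossval,
    "interpret": _stage_interpret,
    "sweep": _stage_sweep,
}


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] = ALL_STAGES,
) -> dict:
    """Run the requested stages in order; returns and writes the manifest.

    Stages not requested must have left their artifacts in ``workdir`` from a
    prior run, otherwise a :class:`PipelineError` names the stage to rerun.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")
    ordered = [s for s in ALL_STAGES if s in set(stages)]
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(workdir / "run_config.yaml")

    manifest_path = workdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": []}
    )
    for stage in ordered:
        _require(workdir, stage)
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        _STAGE_FNS[stage](workdir, config)
        elapsed = time.perf_counter() - t0
        entry = {
            "stage": stage,
            "seconds": round(elapsed, 3),
            "outputs": {
                name: _sha256(workdir / name)
                for name in _ARTIFACTS[stage]
                if (workdir / name).exists()
            },
        }
        manifest["stages"] = [
            e for e in manifest["stages"] if e["stage"] != stage
        ] + [entry]
        logger.info("stage %s: done in %.2fs", stage, elapsed)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
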