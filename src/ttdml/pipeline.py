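"""End-to-end experiment orchestration.

One :func:`run_experiment` call goes simulate -> preprocess -> train
(ODE-RNN ensemble + baselines) -> evaluate -> interpret, writing every
artifact (cohort CSVs, split manifest, per-seed models, a comparison
table, importance and phenoscape tables) into a run directory together
with the exact config used. A single global seed fans out to
stage-specific seeds by fixed offsets, so a rerun with the same config is
byte-identical on all deterministic outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .baselines import (CriteriaClassifier, MarginalBaseline, StaticMLBaseline,
                        default_criteria, prepare_for_criteria)
from .cohort import read_cohort_dir, write_cohort
from .evaluation import MetricReport, default_tasks, evaluate_model
from .interpretation import build_phenoscape, cluster_and_compare, importance_table
from .model import ModelConfig, train_ensemble
from .preprocessing import (NormalizationStats, PreprocessConfig,
                            prepare_cohort, temporal_split)
from .simulate import SimulationConfig, ground_truth_to_csv, simulate_cohort

logger = logging.getLogger(__name__)

# fixed fan-out offsets from the global seed
_OFFSETS = {"simulate": 0, "ode_rnn": 100, "rnn": 200, "lstm": 300,
            "gru": 400, "static": 500, "importance": 600, "phenoscape": 700}

SEQUENCE_KINDS = ("rnn", "lstm", "gru", "ode_rnn")


@dataclass
class RunConfig:
    seed: int = 0
    cohort_dir: str | None = None           # load instead of simulate
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_seeds: int = 5
    baselines: tuple[str, ...] = ("criteria", "static", "rnn", "lstm", "gru")
    do_importance: bool = False
    importance_n_repeats: int = 5
    importance_variables: tuple[str, ...] | None = None
    do_phenoscape: bool = False
    embedding_method: str = "umap"
    n_clusters: int = 3

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "simulation" in payload and isinstance(payload["simulation"], dict):
            sim = dict(payload["simulation"])
            if "effects" in sim and isinstance(sim["effects"], dict):
                from .simulate import EffectSizes

                sim["effects"] = EffectSizes(**sim["effects"])
            payload["simulation"] = SimulationConfig(**sim)
        if "preprocess" in payload and isinstance(payload["preprocess"], dict):
            pre = dict(payload["preprocess"])
            if pre.get("bin_edges") is not None:
                pre["bin_edges"] = tuple(pre["bin_edges"])
            payload["preprocess"] = PreprocessConfig(**pre)
        if "model" in payload and isinstance(payload["model"], dict):
            payload["model"] = ModelConfig(**payload["model"])
        if "baselines" in payload:
            payload["baselines"] = tuple(payload["baselines"])
        return cls(**payload)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _log_line(log_path: Path, **payload) -> None:
    with open(log_path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps({"t": time.time(), **payload}) + "\n")


def run_experiment(config: RunConfig, out_dir) -> Path:
    """Run the full pipeline into ``out_dir``; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log.jsonl"
    config.to_yaml(out / "config.yaml")
    stage = "simulate"
    try:
        # --- cohort -----------------------------------------------------
        if config.cohort_dir:
            cohort = read_cohort_dir(config.cohort_dir)
            truth = None
        else:
            sim_cfg = replace(config.simulation,
                              seed=config.seed + _OFFSETS["simulate"])
            cohort, truth = simulate_cohort(sim_cfg)
            write_cohort(cohort, out / "cohort")
            ground_truth_to_csv(truth, out / "cohort" / "ground_truth.csv")
        _log_line(log_path, stage=stage, n=len(cohort))

        # --- preprocess -------------------------------------------------
        stage = "preprocess"
        pre = config.preprocess
        train_cohort, test_cohort = temporal_split(cohort, pre.cutoff_year)
        stats = NormalizationStats.fit(train_cohort)
        train = prepare_cohort(train_cohort, stats, pre)
        test = prepare_cohort(test_cohort, stats, pre)
        with open(out / "split.json", "w", encoding="utf-8") as fh:
            json.dump({"cutoff_year": pre.cutoff_year,
                       "train_ids": [p.patient_id for p in train],
                       "test_ids": [p.patient_id for p in test]},
                      fh, sort_keys=True)
        _log_line(log_path, stage=stage, n_train=len(train), n_test=len(test))

        # --- models -----------------------------------------------------
        stage = "train"
        tasks = default_tasks(pre.bin_edges)
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        reports: dict[str, MetricReport] = {}

        marginal = MarginalBaseline(n_classes=len(pre.bin_edges) + 1).fit(train)
        reports["marginal"] = evaluate_model(marginal, test, tasks,
                                             pre.bin_edges, "marginal")

        if "criteria" in config.baselines:
            raw_train = prepare_for_criteria(train_cohort, stats, pre)
            raw_test = prepare_for_criteria(test_cohort, stats, pre)
            crit = CriteriaClassifier(default_criteria(), cohort.vocabulary,
                                      pre.bin_edges).fit(raw_train)
            reports["criteria"] = evaluate_model(crit, raw_test, tasks,
                                                 pre.bin_edges, "criteria")
        if "static" in config.baselines:
            static = StaticMLBaseline(n_classes=len(pre.bin_edges) + 1,
                                      seed=config.seed + _OFFSETS["static"]).fit(train)
            reports["static"] = evaluate_model(static, test, tasks,
                                               pre.bin_edges, "static")
        ensembles = {}
        for kind in SEQUENCE_KINDS:
            if kind != "ode_rnn" and kind not in config.baselines:
                continue
            mc = replace(config.model, seed=config.seed + _OFFSETS[kind],
                         n_classes=len(pre.bin_edges) + 1)
            members = train_ensemble(train, mc, config.n_seeds, kind)
            ensembles[kind] = members
            for i, m in enumerate(members):
                m.save(models_dir / f"{kind}_seed{i}.npz")
            reports[kind] = evaluate_model(members, test, tasks,
                                           pre.bin_edges, kind)
            _log_line(log_path, stage=stage, model=kind,
                      accuracy4=reports[kind].mean["accuracy4"])

        # --- report -----------------------------------------------------
        stage = "evaluate"
        report = {"n_train": len(train), "n_test": len(test),
                  "bin_edges": list(pre.bin_edges),
                  "models": {k: r.to_dict() for k, r in reports.items()}}
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(_plain(report), fh, sort_keys=True, indent=1)
        _comparison_csv(reports, out / "comparison.csv")

        # --- interpretation ---------------------------------------------
        best = ensembles.get("ode_rnn", [None])[0]
        if config.do_importance and best is not None:
            stage = "importance"
            table = importance_table(
                best, test_cohort, stats, tasks,
                variables=(list(config.importance_variables)
                           if config.importance_variables else None),
                config=pre, n_repeats=config.importance_n_repeats,
                seed=config.seed + _OFFSETS["importance"])
            table.to_csv(out / "importance.csv", index=False)
        if config.do_phenoscape and best is not None:
            stage = "phenoscape"
            view = build_phenoscape(
                best, test_cohort, stats, pre,
                method=config.embedding_method, n_clusters=config.n_clusters,
                seed=config.seed + _OFFSETS["phenoscape"])
            view.to_csv(out / "phenoscape.csv")
            means, pvals = cluster_and_compare(view)
            means.to_csv(out / "cluster_means.csv")
            pvals.to_csv(out / "cluster_tests.csv", index=False)
        _log_line(log_path, stage="done")
        return out
    except Exception as exc:
        _log_line(log_path, stage=stage, error=str(exc))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _comparison_csv(reports: dict[str, MetricReport], path: Path) -> None:
    import pandas as pd

    rows = []
    for name, rep in reports.items():
        row = {"model": name}
        for key, val in rep.mean.items():
            row[key] = val
            row[f"{key}_sd"] = rep.sd[key]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
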