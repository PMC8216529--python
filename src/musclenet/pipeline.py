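"""End-to-end orchestration: run configuration and the pipeline stages.

Each stage is an ordinary function taking a :class:`RunConfig` and an output
directory, so the whole analysis is scriptable without the command-line
front-end.  Stages are deterministic given (config, seed): rerunning a stage
with the same inputs produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from musclenet import classify as _classify
from musclenet import coherence as _coherence
from musclenet import features as _features
from musclenet import io as _io
from musclenet import nca as _nca
from musclenet import network as _network
from musclenet import preprocess as _preprocess
from musclenet import synthetic as _synthetic

logger = logging.getLogger(__name__)

TASKS = _synthetic.TASKS


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    run_id: str = "run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    coherence: dict = field(default_factory=dict)
    network: dict = field(default_factory=lambda: {"p_threshold": 0.5})
    nca: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    paper_mode: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def cohort_params(self) -> _synthetic.CohortParams:
        kwargs = dict(self.cohort)
        kwargs.setdefault("seed", self.seed)
        return _synthetic.CohortParams.from_dict(kwargs)

    def preprocess_config(self) -> _preprocess.PreprocessConfig:
        return _preprocess.PreprocessConfig(**self.preprocess)

    def coherence_config(self) -> _coherence.CoherenceConfig:
        kwargs = dict(self.coherence)
        if "bands" in kwargs:
            kwargs["bands"] = tuple(
                _coherence.BandDefinition(**b) for b in kwargs["bands"]
            )
        if "broadband" in kwargs:
            kwargs["broadband"] = tuple(kwargs["broadband"])
        return _coherence.CoherenceConfig(**kwargs)

    def cv_config(self) -> _classify.CvConfig:
        kwargs = {
            k: v
            for k, v in self.classify.items()
            if k in ("n_folds", "stratified", "positive_class")
        }
        kwargs.setdefault("seed", self.seed)
        return _classify.CvConfig(**kwargs)


def preprocess_cohort(
    recordings: list[_synthetic.EmgRecording],
    pre_cfg: _preprocess.PreprocessConfig,
    coh_lo: float = 1.0,
) -> dict:
    """Condition every recording, grouped per (subject, task).

    Returns ``{(subject, task): {"trials": [...], "coh_trials": [...],
    "group", "fs", "labels"}}``.  ``trials`` carry the amplitude-feature
    conditioning, ``coh_trials`` the coherence conditioning (band-pass edge
    lowered to ``coh_lo``).  Subjects missing a task are simply absent from
    that task's entries.
    """
    coh_cfg = _preprocess.coherence_conditioning(pre_cfg, lo=coh_lo)
    grouped: dict[tuple[str, str], list[_synthetic.EmgRecording]] = {}
    for rec in recordings:
        grouped.setdefault((rec.subject_id, rec.task), []).append(rec)
    out = {}
    for key, recs in sorted(grouped.items()):
        recs = sorted(recs, key=lambda r: r.trial_index)
        fs = recs[0].fs
        raw = [r.samples for r in recs]
        out[key] = {
            "trials": _preprocess.preprocess_task(raw, fs, pre_cfg),
            "coh_trials": _preprocess.preprocess_task(raw, fs, coh_cfg),
            "group": recs[0].group,
            "fs": fs,
            "labels": recs[0].channel_labels,
        }
    return out


def feature_tables(
    recordings: list[_synthetic.EmgRecording],
    pre_cfg: _preprocess.PreprocessConfig | None = None,
    coh_cfg: _coherence.CoherenceConfig | None = None,
    processed: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-task feature tables plus the pooled 'combine' view."""
    pre_cfg = pre_cfg or _preprocess.PreprocessConfig()
    coh_cfg = coh_cfg or _coherence.CoherenceConfig()
    if processed is None:
        processed = preprocess_cohort(recordings, pre_cfg)
    tables = {}
    for task in TASKS:
        pp = {}
        coh_pp = {}
        for (subject, t), entry in processed.items():
            if t == task:
                pp[subject] = entry["trials"]
                coh_pp[subject] = entry["coh_trials"]
        tables[task] = _features.build_feature_table(
            recordings, task, pre_cfg, coh_cfg,
            preprocessed=pp, coh_preprocessed=coh_pp,
        )
    tables["combine"] = _features.combine_tasks(
        {t: tables[t] for t in TASKS}
    )
    return tables


def cohort_networks(
    processed: dict,
    band: _coherence.BandDefinition,
    coh_cfg: _coherence.CoherenceConfig | None = None,
    task: str = "curvilinear",
    within_side_only: bool = False,
) -> tuple[list[_network.BandNetwork], dict[str, str]]:
    """Per-subject band networks for one task, plus the subject->group map."""
    nets = []
    groups = {}
    for (subject, t), entry in processed.items():
        if t != task:
            continue
        nets.append(
            _network.build_adjacency(
                entry["coh_trials"],
                entry["fs"],
                entry["labels"],
                band,
                coh_cfg,
                subject=subject,
                task=task,
                within_side_only=within_side_only,
            )
        )
        groups[subject] = entry["group"]
    return nets, groups


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, out_dir, overwrite: bool = False) -> Path:
    out_dir = _io.ensure_dir(out_dir)
    params = cfg.cohort_params()
    cohort_dir = out_dir / "cohort"
    _io.ensure_dir(cohort_dir)
    manifest = _synthetic.generate_cohort(params, cohort_dir, overwrite=overwrite)
    logger.info("simulated %d recordings into %s", len(manifest), cohort_dir)
    return cohort_dir / "manifest.csv"


def _load_processed(cfg: RunConfig, out_dir):
    manifest = Path(out_dir) / "cohort" / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(
            f"{manifest} not found: run the 'simulate' stage first"
        )
    recordings = _io.load_cohort(manifest)
    coh_lo = min(b.lo for b in cfg.coherence_config().bands)
    processed = preprocess_cohort(
        recordings, cfg.preprocess_config(), coh_lo=coh_lo
    )
    return recordings, processed


def stage_features(cfg: RunConfig, out_dir) -> dict[str, Path]:
    out_dir = _io.ensure_dir(out_dir)
    recordings, processed = _load_processed(cfg, out_dir)
    tables = feature_tables(
        recordings, cfg.preprocess_config(), cfg.coherence_config(), processed
    )
    paths = {}
    for task, df in tables.items():
        path = out_dir / f"features_{task}.csv"
        df.to_csv(path)
        paths[task] = path
    logger.info("wrote feature tables: %s", sorted(paths))
    return paths


def _read_feature_tables(out_dir) -> dict[str, pd.DataFrame]:
    tables = {}
    for task in (*TASKS, "combine"):
        path = Path(out_dir) / f"features_{task}.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"{path} not found: run the 'features' stage first"
            )
        tables[task] = pd.read_csv(path, index_col=0)
    return tables


def stage_network(cfg: RunConfig, out_dir) -> Path:
    out_dir = _io.ensure_dir(out_dir)
    _, processed = _load_processed(cfg, out_dir)
    coh_cfg = cfg.coherence_config()
    p = float(cfg.network.get("p_threshold", 0.5))
    within = bool(cfg.network.get("within_side_only", False))
    metrics = cfg.network.get("metrics", ["strength", "strength_mean", "bc"])
    rows = []
    net_dir = _io.ensure_dir(out_dir / "networks")
    for task in TASKS:
        for band in coh_cfg.bands:
            nets, groups = cohort_networks(
                processed, band, coh_cfg, task, within_side_only=within
            )
            for metric in metrics:
                res = _network.group_network_analysis(nets, groups, p=p, metric=metric)
                test = res["test"]
                gnames = sorted(res["group_means"])
                rows.append(
                    {
                        "task": task,
                        "band": band.name,
                        "metric": metric,
                        "p_threshold": p,
                        **{f"mean_{g}": res["group_means"][g] for g in gnames},
                        **{f"sd_{g}": res["group_sds"][g] for g in gnames},
                        "t_statistic": test.statistic,
                        "p_value": test.p_value,
                    }
                )
                for g, W in res["group_mean_adjacency"].items():
                    el = _network.edge_list(W, res["nodes"])
                    el.to_csv(
                        net_dir / f"group_mean_{task}_{band.name}_{g}.csv",
                        index=False,
                    )
    comparison = pd.DataFrame(rows)
    path = out_dir / "network_group_comparison.csv"
    comparison.to_csv(path, index=False)
    logger.info("wrote %s (%d comparisons)", path, len(comparison))
    return path


def stage_select(cfg: RunConfig, out_dir) -> dict[str, Path]:
    out_dir = _io.ensure_dir(out_dir)
    tables = _read_feature_tables(out_dir)
    cv_cfg = cfg.cv_config()
    nca_params = {
        k: v
        for k, v in cfg.nca.items()
        if k in ("lambda_reg", "sigma", "max_iter", "tol", "patience")
    }
    paths = {}
    for task, df in tables.items():
        std, _ = _nca.standardize(df)
        cols = _nca.feature_columns(std)
        sel = _nca.nca_fit(
            std[cols].to_numpy(), std["group"].to_numpy(), seed=cfg.seed, **nca_params
        )
        wt = _nca.weight_table(sel, cols)
        wpath = out_dir / f"nca_weights_{task}.csv"
        wt.to_csv(wpath, index=False)
        msum = _nca.muscle_weight_summary(sel.weights_, cols)
        msum.to_csv(out_dir / f"nca_muscle_summary_{task}.csv", index=False)
        k_grid = cfg.nca.get("k_grid") or list(
            range(1, min(30, len(cols)) + 1)
        )
        for clf in _classify.CLASSIFIERS:
            curve = _nca.accuracy_vs_k(
                df,
                clf,
                k_grid,
                cv_cfg,
                nca_params=nca_params,
                refit_per_fold=not cfg.paper_mode,
            )
            curve.to_csv(out_dir / f"accuracy_vs_k_{task}_{clf}.csv", index=False)
        paths[task] = wpath
        with open(out_dir / f"nca_hyperparams_{task}.json", "w") as fh:
            json.dump(
                {
                    "lambda_reg": sel.lambda_reg,
                    "sigma": sel.sigma,
                    "max_iter": sel.max_iter,
                    "tol": sel.tol,
                    "patience": sel.patience,
                    "seed": cfg.seed,
                    "n_iterations": int(sel.n_iter_),
                    "paper_mode": cfg.paper_mode,
                },
                fh,
                indent=2,
            )
    logger.info("wrote NCA weights and accuracy-vs-k curves")
    return paths


def stage_classify(cfg: RunConfig, out_dir) -> Path:
    out_dir = _io.ensure_dir(out_dir)
    tables = _read_feature_tables(out_dir)
    cv_cfg = cfg.cv_config()
    nca_k = int(cfg.classify.get("nca_k", 16))
    reports = _classify.task_comparison(tables, cv_cfg, nca_k=nca_k)
    rep_dir = _io.ensure_dir(out_dir / "reports")
    for (task, clf, subset), rep in reports.items():
        with open(rep_dir / f"{task}_{clf}_{subset}.json", "w") as fh:
            json.dump(rep.to_dict(), fh, indent=2)
    summary = _classify.summary_table(reports)
    path = out_dir / "classification_summary.csv"
    summary.to_csv(path, index=False)
    for task in ("curvilinear", "rectilinear"):
        per_muscle = _classify.per_muscle_evaluation(
            tables[task], "svm", cv_cfg, task=task, nca_k=None
        )
        rows = [
            {
                "muscle": m,
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
            for m, r in per_muscle.items()
        ]
        pd.DataFrame(rows).to_csv(out_dir / f"per_muscle_{task}.csv", index=False)
    logger.info("wrote %s (%d rows)", path, len(summary))
    return path


def stage_all(cfg: RunConfig, out_dir, overwrite: bool = False) -> Path:
    out_dir = _io.ensure_dir(out_dir)
    cfg.to_yaml(out_dir / "config.yaml")
    stage_simulate(cfg, out_dir, overwrite=overwrite)
    stage_features(cfg, out_dir)
    stage_network(cfg, out_dir)
    stage_select(cfg, out_dir)
    stage_classify(cfg, out_dir)
    return write_output_manifest(out_dir)


def write_output_manifest(out_dir) -> Path:
    """SHA-256 manifest of every produced file, for reproducibility checks."""
    out_dir = Path(out_dir)
    rows = []
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "output_manifest.csv":
            rows.append(
                {
                    "path": str(path.relative_to(out_dir)),
                    "sha256": _io.file_sha256(path),
                }
            )
    manifest = pd.DataFrame(rows)
    path = out_dir / "output_manifest.csv"
    manifest.to_csv(path, index=False)
    return path
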