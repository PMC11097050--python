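"""End-to-end orchestration of the five workflow stages.

Stages: (1) ingest or simulate the five EHR tables, (2) extract decision
points per outcome variable, (3) build features and train the similarity
model, (4) construct filter and precision cohorts, (5) analyze treatment
options and outcomes.  Every stage appends a JSON line (stage name, row
counts in/out, wall time) to ``run_log.jsonl`` in the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import features as feat
from . import outcomes as out_mod
from . import similarity as sim
from .decision_points import OUTCOME_SPECS, extract_decision_points, dps_to_frame
from .ingest import EventTables, load_tables, write_tables
from .synthetic import SimConfig, simulate_population, write_ground_truth


@dataclass
class PipelineConfig:
    """All tunables of the workflow, with the study defaults."""

    outcomes: tuple[str, ...] = ("hba1c", "glucose")
    window_min_days: int = 90
    window_max_days: int = 365
    active_window_days: int = 180
    train_frac: float = 0.30
    min_nonmissing: float = 0.8
    impute_k: int = 2
    alphas: tuple[float, ...] = feat.DEFAULT_ALPHA_GRID
    n_models: int = 200
    subsample: float = 0.75
    min_stable_count: int = 150
    lmnn_k_grid: tuple[int, ...] = sim.DEFAULT_K_GRID
    lmnn_max_rows: int = 800
    lmnn_max_iter: int = 150
    knn_n_grid: tuple[int, ...] = sim.DEFAULT_N_GRID
    cutoff: float = 2.0
    min_cohort_size: int = 200
    min_option_frac: float = 0.01
    min_option_count: int = 10
    alpha: float = 0.05
    top_k: int = 20
    seed: int = 0
    simulate: SimConfig | None = None

    def to_yaml(self, path: Path | str) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if payload.get("simulate") is not None:
            sim_payload = dict(payload["simulate"])
            if "treatment_menu" in sim_payload:
                sim_payload["treatment_menu"] = tuple(sim_payload["treatment_menu"])
            payload["simulate"] = SimConfig(**sim_payload)
        for key in ("outcomes", "alphas", "lmnn_k_grid", "knn_n_grid"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _RunLog:
    def __init__(self, path: Path | None):
        self.path = path
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text("")

    def record(self, stage: str, **fields) -> None:
        if self.path is None:
            return
        entry = {"stage": stage, **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")


def prepare_features(dps_frame: pd.DataFrame, cfg: PipelineConfig, seed: int):
    """Stage-3 front half: matrix, completeness filter, imputation, split, scaling."""
    matrix = feat.build_features(dps_frame)
    matrix, dropped = feat.filter_missing(matrix, cfg.min_nonmissing)
    matrix = feat.impute_knn(matrix, cfg.impute_k)
    train, score = feat.split_train_score(matrix, cfg.train_frac, seed=seed)
    scaler = feat.fit_scaler(train)
    return feat.apply_scaler(train, scaler), feat.apply_scaler(score, scaler), scaler, dropped


def run_outcome_scenario(
    tables: EventTables, outcome: str, cfg: PipelineConfig, out_dir: Path | None, log: _RunLog
) -> dict:
    """Stages 2-5 for one target outcome variable."""
    seed = cfg.seed
    spec = OUTCOME_SPECS[outcome]
    t0 = time.perf_counter()
    dps = extract_decision_points(tables, spec, cfg.active_window_days)
    dps_frame = dps_to_frame(dps)
    log.record(
        f"extract_dps[{outcome}]",
        n_patients=len(tables.registry),
        n_dps=len(dps_frame),
        seconds=round(time.perf_counter() - t0, 3),
    )
    if out_dir is not None and len(dps_frame):
        dps_frame.to_csv(out_dir / f"dps_{outcome}.csv", index=False)
    if len(dps_frame) < 50:
        raise StageError(f"extract_dps[{outcome}]", ValueError("too few DPs to model"))

    t0 = time.perf_counter()
    train, score, scaler, dropped = prepare_features(dps_frame, cfg, seed)
    stability = feat.stability_select(
        train,
        alphas=cfg.alphas,
        n_models=cfg.n_models,
        subsample=cfg.subsample,
        min_count=cfg.min_stable_count,
        seed=seed,
    )
    sim_features = feat.similarity_feature_set(stability, train)
    log.record(
        f"select_features[{outcome}]",
        n_train=len(train.y),
        n_score=len(score.y),
        dropped_incomplete=dropped,
        alpha=stability.alpha,
        f1_at_alpha=stability.f1_at_alpha,
        n_stable=len(stability.stable_features),
        seconds=round(time.perf_counter() - t0, 3),
    )

    t0 = time.perf_counter()
    model = sim.train_similarity(
        train.X[sim_features],
        train.y,
        k_grid=cfg.lmnn_k_grid,
        seed=seed,
        max_iter=cfg.lmnn_max_iter,
        max_rows=cfg.lmnn_max_rows,
        scaler=scaler,
    )
    best_n, best_wf, f1_raw, f1_t = sim.evaluate_knn(
        model,
        train.X,
        train.y,
        score.X,
        score.y,
        n_grid=cfg.knn_n_grid,
        seed=seed,
    )
    log.record(
        f"train_similarity[{outcome}]",
        lmnn_k=model.lmnn_k,
        knn_n=best_n,
        knn_weights=best_wf,
        f1_raw=f1_raw,
        f1_transformed=f1_t,
        seconds=round(time.perf_counter() - t0, 3),
    )
    if out_dir is not None:
        model.to_json(out_dir / f"similarity_{outcome}.json")

    # Stage 4: filter cohorts on the scoring set; one example precision cohort.
    t0 = time.perf_counter()
    score_dps = dps_frame.loc[score.X.index].copy()
    score_dps["filter_key"] = cohort_mod.attach_filter_keys(score_dps)
    cohorts = cohort_mod.build_filter_cohorts(score_dps, cfg.min_cohort_size)
    precision = None
    eligible_keys = [k for k in cohorts.members if cohorts.eligible(k)]
    if eligible_keys:
        key = max(eligible_keys, key=lambda k: len(cohorts.members[k]))
        ids = cohorts.members[key]
        query_id = ids[0]
        features_scaled = score.X.loc[ids, model.features]
        pre = cohort_mod.score_cohort(
            model, features_scaled, features_scaled.loc[query_id], query_id=query_id, key=key
        )
        precision = cohort_mod.apply_cutoff(
            pre,
            cfg.cutoff,
            dp_frame=pd.concat([score_dps.loc[ids], score.X.loc[ids]], axis=1),
            covariates=model.features,
        )
    log.record(
        f"precision_cohort[{outcome}]",
        n_cohorts=len(cohorts.members),
        n_eligible=len(eligible_keys),
        seconds=round(time.perf_counter() - t0, 3),
    )
    if out_dir is not None:
        cohorts.chart.to_csv(out_dir / f"filter_cohorts_{outcome}.csv", index=False)

    # Stage 5: outcomes analysis, global and (if available) personalized.
    t0 = time.perf_counter()
    global_table = out_mod.global_analysis(
        score_dps,
        min_frac=cfg.min_option_frac,
        min_count=cfg.min_option_count,
        alpha=cfg.alpha,
        top_k=cfg.top_k,
    )
    sankey = None
    cohort_table = None
    if precision is not None and len(precision.members):
        member_dps = score_dps.loc[precision.members["dp_id"]]
        cohort_summaries = out_mod.summarize_options(
            member_dps,
            min_frac=cfg.min_option_frac,
            min_count=cfg.min_option_count,
            alpha=cfg.alpha,
        )
        cohort_table = out_mod.summaries_to_frame(cohort_summaries)
        sankey = out_mod.sankey_export(cohort_summaries, cohort_label=precision.filter_key)
    log.record(
        f"outcomes[{outcome}]",
        n_options_global=len(global_table),
        seconds=round(time.perf_counter() - t0, 3),
    )
    if out_dir is not None:
        global_table.to_csv(out_dir / f"global_options_{outcome}.csv", index=False)
        if cohort_table is not None:
            cohort_table.to_csv(out_dir / f"cohort_options_{outcome}.csv", index=False)
        if sankey is not None:
            (out_dir / f"sankey_{outcome}.json").write_text(json.dumps(sankey, indent=2))

    return {
        "dps": dps_frame,
        "train": train,
        "score": score,
        "stability": stability,
        "model": model,
        "knn": {"n": best_n, "weights": best_wf, "f1_raw": f1_raw, "f1_transformed": f1_t},
        "filter_cohorts": cohorts,
        "precision_cohort": precision,
        "global_table": global_table,
        "cohort_table": cohort_table,
        "sankey": sankey,
    }


def run_pipeline(
    config: PipelineConfig,
    data_dir: Path | str | None = None,
    out_dir: Path | str | None = None,
) -> dict:
    """Run all five stages; returns the per-outcome artifact dictionary."""
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_path / "config.yaml")
    log = _RunLog(out_path / "run_log.jsonl" if out_path is not None else None)

    t0 = time.perf_counter()
    try:
        if config.simulate is not None:
            tables, truth = simulate_population(config.simulate)
            if out_path is not None:
                write_tables(tables, out_path / "tables")
                write_ground_truth(truth, out_path / "tables")
        elif data_dir is not None:
            tables = load_tables(data_dir)
            truth = None
        else:
            raise ValueError("either a data directory or a simulation config is required")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("ingest", exc) from exc
    log.record(
        "ingest",
        n_patients=len(tables.registry),
        n_measurements=len(tables.measurements),
        seconds=round(time.perf_counter() - t0, 3),
    )

    results: dict = {"tables": tables, "ground_truth": truth, "outcomes": {}}
    for outcome in config.outcomes:
        results["outcomes"][outcome] = run_outcome_scenario(tables, outcome, config, out_path, log)
    return results
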