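"""Preprocessing and end-to-end pipeline orchestration.

Preprocessing mirrors a typical survey workflow: columns carrying any
missing value are dropped outright (rows are never dropped), groups of
item columns can be summed into single score columns, and an explicit
drop-list removes items judged duplicated by the analyst — duplicate
detection is never automatic.

``run_all`` wires the stages together: (optional) generation ->
preprocessing -> QUBO sweep + MLR baseline ranking -> boosted-tree
validation -> comparison report, writing every artifact to disk stamped
with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annealer import AnnealSchedule
from .info_theory import BinningRule
from .ranking import FeatureRanking, sweep
from .synthetic import GeneratorConfig, SurveyTable, generate, read_csv, write_csv
from .validation import EvaluationConfig, compare_methods, evaluate_feature_sets, mlr_ranking

__all__ = [
    "PipelineConfig",
    "drop_missing_columns",
    "sum_item_group",
    "run_all",
]

log = logging.getLogger(__name__)


def drop_missing_columns(table: SurveyTable) -> SurveyTable:
    """Remove every feature column containing at least one missing value.

    Row count is unchanged and surviving cell values are untouched.  The
    removal list is logged.  Raises if no feature column survives or the
    target itself has missing entries.
    """
    if table.target.isna().any():
        raise ValueError("target column has missing values")
    na_cols = [c for c in table.features.columns if table.features[c].isna().any()]
    if na_cols:
        log.info("drop_missing_columns: removing %d column(s): %s", len(na_cols), na_cols)
    kept = table.features.drop(columns=na_cols)
    if kept.shape[1] == 0:
        raise ValueError("all feature columns contain missing values")
    return SurveyTable(features=kept.astype("int64"), target=table.target.copy())


def sum_item_group(table: SurveyTable, item_columns: list[str], new_name: str) -> SurveyTable:
    """Sum a group of item columns into one score column.

    The new column replaces the first source column in place; the other
    source columns are removed and the order of all remaining columns is
    preserved.  A single-column group amounts to a rename.
    """
    for col in item_columns:
        if col not in table.features.columns:
            raise ValueError(f"sum_item_group: column {col!r} not in table")
    summed = table.features[item_columns].sum(axis=1)
    cols = list(table.features.columns)
    insert_at = cols.index(item_columns[0])
    remaining = [c for c in cols if c not in item_columns]
    out = table.features[remaining].copy()
    out.insert(loc=min(insert_at, len(remaining)), column=new_name, value=summed)
    return SurveyTable(features=out, target=table.target.copy())


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to rerun the pipeline, JSON round-trippable."""

    input_csv: str | None = None
    generator: GeneratorConfig | None = GeneratorConfig()
    mode: str = "literal"
    n_bins: int = 10
    schedule: AnnealSchedule = AnnealSchedule()
    evaluation: EvaluationConfig = EvaluationConfig()
    sum_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    drop_columns: tuple[str, ...] = ()
    seed: int = 0
    output_dir: str = "pipeline_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["evaluation"]["conditions"] = list(self.evaluation.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorConfig(**d["generator"])
        if "schedule" in d:
            d["schedule"] = AnnealSchedule(**d["schedule"])
        if "evaluation" in d:
            ev = dict(d["evaluation"])
            ev["conditions"] = tuple(ev.get("conditions", (10, 20, 30, 40, 50)))
            ev["xgb_params"] = dict(ev.get("xgb_params", {}))
            d["evaluation"] = EvaluationConfig(**ev)
        d["sum_groups"] = {k: tuple(v) for k, v in d.get("sum_groups", {}).items()}
        d["drop_columns"] = tuple(d.get("drop_columns", ()))
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stamp(config: PipelineConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed}


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns a name -> path map of artifacts.

    Idempotent given the same configuration: artifacts are rewritten
    byte-identically.  Stage failures propagate with the stage named;
    artifacts of completed stages are retained on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # re-raise with the stage named
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            return result

        return deco

    @stage("load")
    def table_and_labels():
        if config.input_csv is not None:
            return read_csv(config.input_csv), None
        if config.generator is None:
            raise ValueError("config needs input_csv or a generator block")
        gen = dataclasses.replace(config.generator, seed=config.seed)
        return generate(gen)

    table, labels = table_and_labels

    @stage("preprocess")
    def preprocessed():
        t = drop_missing_columns(table) if table.has_missing else table
        for new_name, cols in config.sum_groups.items():
            t = sum_item_group(t, list(cols), new_name)
        if config.drop_columns:
            t = SurveyTable(
                features=t.features.drop(columns=list(config.drop_columns)),
                target=t.target.copy(),
            )
        return t

    data_path = out / "data.csv"
    write_csv(preprocessed, data_path, labels)
    artifacts["data"] = data_path

    @stage("qa_sweep")
    def qa() -> FeatureRanking:
        schedule = dataclasses.replace(config.schedule, seed=config.seed)
        return sweep(
            preprocessed,
            mode=config.mode,
            schedule=schedule,
            binning=BinningRule(n_bins=config.n_bins),
        )

    qa_path = out / "qa_ranking.tsv"
    qa.to_tsv(qa_path)
    artifacts["qa_ranking"] = qa_path

    @stage("mlr")
    def mlr() -> FeatureRanking:
        return mlr_ranking(preprocessed)

    mlr_path = out / "mlr_ranking.tsv"
    mlr.to_tsv(mlr_path)
    artifacts["mlr_ranking"] = mlr_path

    @stage("validation")
    def reports():
        ev = dataclasses.replace(
            config.evaluation,
            seed=config.seed,
            conditions=tuple(c for c in config.evaluation.conditions if c <= preprocessed.p),
        )
        rep_qa = evaluate_feature_sets(preprocessed, qa, ev, method="qa")
        rep_mlr = evaluate_feature_sets(preprocessed, mlr, ev, method="mlr")
        return rep_qa, rep_mlr

    rep_qa, rep_mlr = reports
    eval_path = out / "evaluation.tsv"
    pd.concat([rep_qa.to_long_frame(), rep_mlr.to_long_frame()]).to_csv(
        eval_path, sep="\t", index=False
    )
    artifacts["evaluation"] = eval_path

    @stage("report")
    def summary():
        tests = compare_methods(rep_qa, rep_mlr)
        return {
            **_stamp(config),
            "mode": config.mode,
            "qa_sweep": {k: v for k, v in qa.metadata.items() if k != "k_values"},
            "t_tests": tests.to_dict(orient="records"),
            "timings_s": timings,
        }

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    artifacts["summary"] = summary_path

    config_path = out / "config.json"
    config.to_json(config_path)
    artifacts["config"] = config_path
    return artifacts
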