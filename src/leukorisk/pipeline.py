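"""End-to-end orchestration: discover -> triage -> (COXEN) -> train ->
predict -> evaluate, with per-stage artifacts and a machine-readable
manifest.

The configuration is a single YAML/JSON file; defaults match the printed
analysis thresholds (q <= 0.01 discovery, COXEN p < 0.001, three principal
components, equal LDA priors).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import coxen, discovery, evaluation, io, predictor, simulate, triage
from .datamodel import ExpressionMatrix, intersect_probes

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error annotated with the pipeline stage where it occurred."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: str = "leukorisk_run"
    # either a synthetic cohort ...
    synthetic: Optional[simulate.CohortConfig] = simulate.CohortConfig()
    # ... or a directory containing a written cohort (cohort.json manifest)
    data_dir: Optional[str] = None
    training_dataset: str = "FH1"
    test_datasets: Optional[Tuple[str, ...]] = None  # default: all others
    q_threshold: float = 0.01
    allowed_categories: Tuple[str, ...] = tuple(sorted(triage.DEFAULT_ALLOWED_CATEGORIES))
    use_coxen: bool = True
    coxen_alpha: float = 0.001
    coxen_sample_scope: str = "controls"
    priors: str = "equal"
    n_components: int = 3
    write_inputs: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if not 0 < self.coxen_alpha <= 1:
            raise ValueError("coxen_alpha must be in (0, 1]")
        if self.synthetic is None and self.data_dir is None:
            raise ValueError("either a synthetic config or a data_dir is required")


def load_config(path) -> PipelineConfig:
    """Read a YAML (or JSON) pipeline configuration file."""
    blob = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(blob)


def config_from_dict(blob: dict) -> PipelineConfig:
    blob = dict(blob)
    synthetic = blob.pop("synthetic", "default")
    if synthetic == "default":
        synthetic_cfg = simulate.CohortConfig() if "data_dir" not in blob else None
    elif synthetic is None:
        synthetic_cfg = None
    else:
        synthetic_cfg = simulate.CohortConfig(**synthetic)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(blob) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "test_datasets" in blob and blob["test_datasets"] is not None:
        blob["test_datasets"] = tuple(blob["test_datasets"])
    if "allowed_categories" in blob:
        blob["allowed_categories"] = tuple(blob["allowed_categories"])
    return PipelineConfig(synthetic=synthetic_cfg, **blob)


@dataclass
class RunReport:
    rows: List[dict]
    manifest: dict
    output_dir: Path
    report_path: Path


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "notes": []}

    # -- inputs ----------------------------------------------------------
    if config.synthetic is not None:
        cohort = _stage("simulate")(simulate.generate_cohort, config.synthetic)
        matrices, metadata, annotations = cohort.matrices, list(cohort.metadata), cohort.annotations
        if config.write_inputs:
            simulate.write_cohort(cohort, out / "inputs")
    else:
        matrices, metadata, annotations = _stage("load")(simulate.read_cohort, config.data_dir)
    if config.training_dataset not in matrices:
        raise StageError(
            "load", KeyError(f"training dataset {config.training_dataset!r} not found")
        )
    train = matrices[config.training_dataset]
    test_ids = config.test_datasets or tuple(
        d for d in matrices if d != config.training_dataset
    )
    manifest["stages"]["inputs"] = {
        "datasets": {d: m.n_samples for d, m in matrices.items()},
        "n_probes": train.n_probes,
        "training_dataset": config.training_dataset,
        "test_datasets": list(test_ids),
    }

    # -- discovery -------------------------------------------------------
    records = _stage("discovery")(
        discovery.discover_biomarkers, train, metadata, config.q_threshold
    )
    discovery.write_discovery_tsv(records, out / "discovery.tsv", annotations)
    n_flagged = sum(r.significant for r in records)
    manifest["stages"]["discovery"] = {
        "n_tested": len(records),
        "n_flagged": n_flagged,
        "q_threshold": config.q_threshold,
    }
    logger.info("stage discovery: %d probes in, %d flagged", len(records), n_flagged)

    # -- triage ----------------------------------------------------------
    universal = _stage("triage")(
        triage.filter_by_function,
        records,
        annotations,
        set(config.allowed_categories),
        config.training_dataset,
    )
    io.write_json(
        {"probe_ids": list(universal.probe_ids), "source": universal.source,
         "training_dataset_id": universal.training_dataset_id},
        out / "panel_universal.json",
    )
    manifest["stages"]["triage"] = {"panel_size": len(universal)}
    logger.info("stage triage: %d -> %d probes", n_flagged, len(universal))

    # -- per-test-set model fit, prediction, evaluation -------------------
    rows: List[dict] = []
    for test_id in test_ids:
        test = matrices[test_id]
        common_train, common_test = _stage("intersect")(intersect_probes, train, test)
        panel_probes = [p for p in universal.probe_ids if p in set(common_train.probe_ids)]
        if len(panel_probes) < len(universal):
            manifest["notes"].append(
                f"{test_id}: {len(universal) - len(panel_probes)} panel probes "
                "absent from the test platform; dropped"
            )
        effective = triage.BiomarkerPanel(
            tuple(panel_probes), "universal", config.training_dataset,
            f"universal panel restricted to {test_id} platform",
        )
        rows.append(
            _fit_predict_evaluate(
                common_train, common_test, effective, metadata, config, out,
                panel_label="universal",
            )
        )
        if config.use_coxen:
            try:
                coxen_panel = _stage("coxen")(
                    coxen.select_coxen_panel,
                    common_train,
                    common_test,
                    effective,
                    config.coxen_alpha,
                    config.coxen_sample_scope,
                    metadata,
                )
            except StageError as exc:
                if isinstance(exc.original, coxen.EmptySelectionError):
                    note = f"{test_id}: COXEN selection empty at alpha={config.coxen_alpha}; row skipped"
                    manifest["notes"].append(note)
                    logger.warning(note)
                    continue
                raise
            io.write_json(
                {"probe_ids": list(coxen_panel.probe_ids), "source": "coxen",
                 "training_dataset_id": config.training_dataset},
                out / f"panel_coxen_{test_id}.json",
            )
            rows.append(
                _fit_predict_evaluate(
                    common_train, common_test, coxen_panel, metadata, config, out,
                    panel_label="coxen",
                )
            )

    report_path = out / "report.tsv"
    evaluation.write_report_tsv(rows, report_path)
    manifest["stages"]["evaluation"] = {
        "rows": [
            {"dataset": r["dataset"], "panel": r["panel"], "n_genes": r["n_genes"]}
            for r in rows
        ]
    }
    io.write_json(manifest, out / "manifest.json")
    logger.info("pipeline complete: %d report rows -> %s", len(rows), report_path)
    return RunReport(rows=rows, manifest=manifest, output_dir=out, report_path=report_path)


def _fit_predict_evaluate(train, test, panel, metadata, config, out: Path, panel_label: str) -> dict:
    model = _stage("train")(
        predictor.train_predictor, train, metadata, panel,
        config.priors, config.n_components,
    )
    predictor.save_predictor(model, out / f"model_{panel_label}_{test.dataset_id}.json")
    scores = _stage("predict")(predictor.predict_scores, model, test)
    io.write_scores(scores, out / f"scores_{panel_label}_{test.dataset_id}.tsv")
    row = _stage("evaluate")(
        evaluation.evaluation_row, test.dataset_id, panel_label, len(panel),
        scores, metadata,
    )
    return row


def evaluate_saved_scores(scores_path, metadata, dataset_id: str, panel_label: str, n_genes: int) -> dict:
    """Recompute a report row from a saved score artifact (stage artifacts
    are sufficient state to reproduce the evaluation)."""
    scores = io.read_scores(scores_path)
    return evaluation.evaluation_row(dataset_id, panel_label, n_genes, scores, metadata)
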