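"""End-to-end task runner: ontology + KO matrix → consensus report,
association table, pathway enrichment, misclassification audit.

A :class:`PipelineConfig` holds the input paths, the task definitions,
and the protocol constants (prevalence cutoff 0.20, test fraction 0.20,
100 iterations, top-1000 importance rank, 80% consensus fraction).  Every
run writes an immutable JSON manifest (config hash, seeds, versions)
next to its TSV outputs so results are attributable to exact settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import filter_low_prevalence, load_ko_table
from .forest import ConsensusForestClassifier, TuningConfig, misclassification_audit
from .ontology import ANY_PROPERTY, ClassTask, EcologyOntology
from .owl_io import parse_owl
from .stats import (
    association_frame,
    enrichment_frame,
    filter_yeast_pathways,
    ko_association_table,
    pathway_enrichment,
)
from .tsv_io import read_assignments_tsv

logger = logging.getLogger("yeastenv")


def _pkg_version() -> str:
    from importlib.metadata import version

    try:
        return version("yeastenv")
    except Exception:
        return "unknown"

__all__ = ["PipelineConfig", "TaskSpec", "run_task", "run_redefinition", "load_ontology"]


@dataclass
class TaskSpec:
    """Declarative ClassTask block of the config file."""

    name: str
    include_classes: list[str] = field(default_factory=list)
    include_relational: list[str] = field(default_factory=list)
    exclude_classes: list[str] = field(default_factory=list)
    exclude_relational: list[str] = field(default_factory=list)

    @staticmethod
    def _terms(raw: list[str]) -> frozenset[tuple[str, str]]:
        out = []
        for term in raw:
            prop, sep, target = term.partition("->")
            out.append((prop.strip(), target.strip()) if sep else (ANY_PROPERTY, term.strip()))
        return frozenset(out)

    def to_class_task(self) -> ClassTask:
        return ClassTask(
            name=self.name,
            include_class_ids=frozenset(self.include_classes),
            include_relational=self._terms(self.include_relational),
            exclude_class_ids=frozenset(self.exclude_classes),
            exclude_relational=self._terms(self.exclude_relational),
        )


@dataclass
class PipelineConfig:
    """Paths, tasks, thresholds and the master seed of one analysis."""

    ontology_path: str = ""
    matrix_path: str = ""
    pathway_map_path: str | None = None
    output_dir: str = "runs"
    tasks: list[TaskSpec] = field(default_factory=list)
    prevalence_threshold: float = 0.20
    test_fraction: float = 0.20
    n_iterations: int = 100
    n_trees: int = 500
    top_k: int = 1000
    consensus_fraction: float = 0.80
    bh_alpha: float = 0.05
    min_pathway_size: int = 3
    rebalance_per_iteration: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.tasks = [
            t if isinstance(t, TaskSpec) else TaskSpec(**t) for t in self.tasks
        ]
        for name, value in (
            ("prevalence_threshold", self.prevalence_threshold),
            ("test_fraction", self.test_fraction),
            ("consensus_fraction", self.consensus_fraction),
            ("bh_alpha", self.bh_alpha),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_iterations < 1 or self.top_k < 1 or self.n_trees < 1:
            raise ValueError("n_iterations, top_k and n_trees must be positive")

    # config round-trips losslessly through YAML
    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config; scalar fields can be overridden by environment
        variables named ``YEASTENV_<FIELD>`` (e.g. ``YEASTENV_SEED=7``)."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for f in dataclasses.fields(cls):
            if f.name == "tasks":
                continue
            env = os.environ.get(f"YEASTENV_{f.name.upper()}")
            if env is not None:
                raw[f.name] = yaml.safe_load(env)
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def task_by_name(self, name: str) -> TaskSpec:
        for t in self.tasks:
            if t.name == name:
                return t
        raise KeyError(f"no task named {name!r} in config")


def load_ontology(path) -> EcologyOntology:
    """Dispatch on extension: .owl/.rdf/.xml → RDF/XML, .tsv → flat dialect."""
    p = Path(path)
    if p.suffix.lower() in (".owl", ".rdf", ".xml"):
        return parse_owl(p)
    return read_assignments_tsv(p)


def _check_id_consistency(ontology: EcologyOntology, matrix) -> list[str]:
    strain_ids = list(matrix.data.index)
    missing = [s for s in strain_ids if s not in ontology.instances]
    extra = [s for s in ontology.instances if s not in set(strain_ids)]
    offenders = missing + extra
    if offenders:
        raise ValueError(
            "ontology and matrix strain ids disagree; first offenders: "
            f"{offenders[:10]}"
        )
    return strain_ids


def run_task(
    config: PipelineConfig,
    task_name: str,
    ontology: EcologyOntology | None = None,
    matrix=None,
) -> Path:
    """Run one classification task end to end; returns the run directory.

    Outputs: ``manifest.json``, ``iteration_metrics.tsv``,
    ``predictions.tsv``, ``importances.tsv``, ``consensus.tsv``,
    ``associations.tsv``, ``enrichment.tsv``, ``misclassification.tsv``.
    """
    t0 = time.monotonic()
    logging.basicConfig(level=config.log_level)
    task = config.task_by_name(task_name).to_class_task()
    if ontology is None:
        ontology = load_ontology(config.ontology_path)
    if matrix is None:
        matrix = load_ko_table(config.matrix_path, config.pathway_map_path)
    strain_ids = _check_id_consistency(ontology, matrix)
    labels = ontology.build_labels(task, strain_ids)
    logger.info(
        "task %s: %d strains, %d positive", task_name, len(labels), int(labels.sum())
    )

    filtered = filter_low_prevalence(matrix, config.prevalence_threshold)
    logger.info(
        "prevalence filter %.0f%%: %d of %d KOs retained",
        100 * config.prevalence_threshold,
        filtered.shape[1],
        matrix.shape[1],
    )
    model = ConsensusForestClassifier(
        n_iterations=config.n_iterations,
        test_fraction=config.test_fraction,
        n_trees=config.n_trees,
        top_k=config.top_k,
        min_frac=config.consensus_fraction,
        tuning=TuningConfig(n_trees=config.n_trees, test_fraction=config.test_fraction),
        rebalance_per_iteration=config.rebalance_per_iteration,
        random_state=config.seed,
    )
    model.fit(filtered.data, labels)
    logger.info(
        "task %s: mean AUC %.3f, mean TPR %.3f over %d iterations (%.1fs)",
        task_name,
        model.mean_auc_,
        model.mean_tpr_,
        config.n_iterations,
        time.monotonic() - t0,
    )

    consensus = model.consensus_report_
    selected = consensus.consensus_kos
    median_imp = consensus.table["median_importance"]
    associations = ko_association_table(
        filtered, labels, selected, median_importance=median_imp
    )
    labels_map, removed = filter_yeast_pathways(filtered.pathway_labels or {})
    ko_map = {
        k: frozenset(p for p in v if p in labels_map) if labels_map else v
        for k, v in (filtered.ko_to_pathways or {}).items()
    }
    enrichment = []
    if ko_map:
        enrichment = pathway_enrichment(
            selected,
            filtered.ko_ids,
            ko_map,
            labels_map,
            min_pathway_size=config.min_pathway_size,
        )
    audit = misclassification_audit(model.iteration_results_, strain_ids)

    run_dir = Path(config.output_dir) / f"{task_name}_seed{config.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    _write_outputs(
        run_dir, config, task_name, model, associations, enrichment, audit, removed
    )
    logger.info("task %s: outputs in %s", task_name, run_dir)
    return run_dir


def _float_fmt(x) -> str:
    return f"{x:.6g}"


def _write_outputs(
    run_dir: Path, config, task_name, model, associations, enrichment, audit, removed
) -> None:
    results = model.iteration_results_
    pd.DataFrame(
        {
            "iteration": [r.index for r in results],
            "seed": [r.seed for r in results],
            "auc": [r.auc for r in results],
            "tpr": [r.tpr for r in results],
            "mtry": [r.params[0] for r in results],
            "min_n": [r.params[1] for r in results],
        }
    ).to_csv(run_dir / "iteration_metrics.tsv", sep="\t", index=False, float_format=_float_fmt)

    pred_rows = [
        {
            "iteration": r.index,
            "strain_index": idx,
            "y_true": int(r.y_test[pos]),
            "score": r.scores[pos],
            "prediction": int(r.predictions[pos]),
        }
        for r in results
        for pos, idx in enumerate(r.test_indices)
    ]
    pd.DataFrame(pred_rows).to_csv(
        run_dir / "predictions.tsv", sep="\t", index=False, float_format=_float_fmt
    )

    imp = pd.DataFrame(
        np.vstack([r.importances for r in results]).T,
        index=pd.Index(model.feature_names_, name="ko_id"),
        columns=[f"iter{r.index}" for r in results],
    )
    imp.to_csv(run_dir / "importances.tsv", sep="\t", float_format=_float_fmt)

    model.consensus_report_.table.to_csv(
        run_dir / "consensus.tsv", sep="\t", float_format=_float_fmt
    )
    association_frame(associations).to_csv(
        run_dir / "associations.tsv", sep="\t", index=False, float_format=_float_fmt
    )
    enrichment_frame(enrichment).to_csv(
        run_dir / "enrichment.tsv", sep="\t", index=False, float_format=_float_fmt
    )

    per_strain = pd.DataFrame.from_dict(audit["per_strain"], orient="index")
    per_strain.index.name = "strain_id"
    per_strain.to_csv(run_dir / "misclassification.tsv", sep="\t", float_format=_float_fmt)

    manifest = {
        "task": task_name,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": _pkg_version(),
        "tuned_params": {"mtry": model.best_params_[0], "min_n": model.best_params_[1]},
        "mean_auc": model.mean_auc_,
        "mean_tpr": model.mean_tpr_,
        "n_consensus_kos": len(model.consensus_report_.consensus_kos),
        "consistent_false_pos": audit["consistent_false_pos"],
        "consistent_false_neg": audit["consistent_false_neg"],
        "removed_yeast_pathways": removed,
    }
    with open(run_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def run_redefinition(
    config: PipelineConfig,
    base_task: str,
    revised_task: str,
    ontology: EcologyOntology | None = None,
    matrix=None,
) -> dict:
    """Run two task definitions and compare: which strains flipped label
    (and why — relational inclusion vs an exclusion term) and the paired
    change in mean test AUC."""
    if base_task == revised_task:
        logger.warning("base and revised tasks are identical (%r)", base_task)
    if ontology is None:
        ontology = load_ontology(config.ontology_path)
    if matrix is None:
        matrix = load_ko_table(config.matrix_path, config.pathway_map_path)
    strain_ids = _check_id_consistency(ontology, matrix)
    base = config.task_by_name(base_task).to_class_task()
    revised = config.task_by_name(revised_task).to_class_task()
    y_base = ontology.build_labels(base, strain_ids)
    y_rev = ontology.build_labels(revised, strain_ids)

    flips = []
    for sid, b, r in zip(strain_ids, y_base, y_rev):
        if b != r:
            reason = "relational inclusion" if r > b else "exclusion term"
            flips.append({"strain_id": sid, "base": int(b), "revised": int(r), "reason": reason})

    base_dir = run_task(config, base_task, ontology=ontology, matrix=matrix)
    revised_dir = run_task(config, revised_task, ontology=ontology, matrix=matrix)
    with open(base_dir / "manifest.json", encoding="utf-8") as fh:
        auc_base = json.load(fh)["mean_auc"]
    with open(revised_dir / "manifest.json", encoding="utf-8") as fh:
        auc_rev = json.load(fh)["mean_auc"]

    report = {
        "base_task": base_task,
        "revised_task": revised_task,
        "flipped_strains": flips,
        "n_flipped": len(flips),
        "mean_auc_base": auc_base,
        "mean_auc_revised": auc_rev,
        "mean_auc_change": auc_rev - auc_base,
        "base_run_dir": str(base_dir),
        "revised_run_dir": str(revised_dir),
    }
    out = Path(config.output_dir) / f"compare_{base_task}_vs_{revised_task}.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
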