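"""End-to-end orchestration: data -> preprocess -> stats -> ENNA -> report.

The pipeline mirrors the analysis narrative: obtain a feature table
(extracted from PDB files, read from CSV, or simulated), remove tail
outliers, balance the classes, run the exploratory statistics, run the
evolutionary network search, train the final classifier on the selected
variables, and summarize the fold-similarity fixture.  Every stage's seed
is derived from one master seed and logged in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import class_stats, enna_core, preprocess, synthetic_data
from .structure_features import (
    ID_COLUMN,
    LABEL_COLUMN,
    VARIABLE_NAMES,
    extract_features,
    feature_frame,
    parse_structure,
    read_feature_table,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
INPUT_MODES = ("synthetic", "feature-table", "pdb-dir")


@dataclass
class PipelineConfig:
    """Configuration for one full run.

    Exactly one input mode is used.  Synthetic-mode sizes default to the
    study's pre-filter dataset sizes (902 natural chains, 20494 random
    models); the tail quantiles, GA and network settings default to the
    study design.
    """

    mode: str = "synthetic"
    feature_table: str | None = None
    pdb_dir: str | None = None
    pdb_labels: dict[str, str] = field(default_factory=dict)  # filename -> class
    n_natural: int = 902
    n_random: int = 20494
    shape: str = "gaussian"
    lower_q: float = preprocess.DEFAULT_LOWER_Q
    upper_q: float = preprocess.DEFAULT_UPPER_Q
    population_size: int = 30
    generations: int = 10
    mutation_prob: float = 0.01
    folds: int = 10
    epochs: int = 150
    learning_rate: float = 0.3
    momentum: float = 0.2
    holdout_fraction: float = 0.2
    occurrence_threshold: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.mode not in INPUT_MODES:
            raise ValueError(f"invalid field 'mode': {self.mode!r}; choose from {INPUT_MODES}")
        if self.mode == "feature-table" and not self.feature_table:
            raise ValueError("invalid field 'feature_table': required in feature-table mode")
        if self.mode == "pdb-dir" and not self.pdb_dir:
            raise ValueError("invalid field 'pdb_dir': required in pdb-dir mode")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"invalid config field(s): {sorted(unknown)}")
        return cls(**raw)


def _stage_seeds(master: int) -> dict[str, int]:
    names = ("simulate", "balance", "enna", "final")
    spawned = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, spawned)}


def _load_table(config: PipelineConfig, seeds: dict[str, int]) -> pd.DataFrame:
    if config.mode == "synthetic":
        return synthetic_data.simulate_feature_table(
            n_per_class={"natural": config.n_natural, "random": config.n_random},
            shape=config.shape,
            seed=seeds["simulate"],
        )
    if config.mode == "feature-table":
        return read_feature_table(config.feature_table)
    records = []
    for path in sorted(Path(config.pdb_dir).glob("*.pdb")):
        label = config.pdb_labels.get(path.name, "unknown")
        model = parse_structure(path.read_text())
        records.append((path.stem, extract_features(model, label=label)))
    if not records:
        raise ValueError(f"no .pdb files found in {config.pdb_dir!r}")
    return feature_frame(records)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report as a plain JSON-able dict."""
    seeds = _stage_seeds(config.seed)
    table = _load_table(config, seeds)
    if LABEL_COLUMN not in table.columns:
        raise ValueError(f"feature table lacks the {LABEL_COLUMN!r} column")
    sizes_before = table[LABEL_COLUMN].value_counts().to_dict()
    logger.info("input table: %s", sizes_before)

    report_out = preprocess.flag_outliers(table, config.lower_q, config.upper_q)
    filtered = preprocess.remove_outliers(table, report_out)
    sizes_filtered = filtered[LABEL_COLUMN].value_counts().to_dict()
    balanced = preprocess.balance_classes(filtered, seed=seeds["balance"])
    sizes_balanced = balanced[LABEL_COLUMN].value_counts().to_dict()

    summary, corr = class_stats.summarize_by_class(balanced)

    ga = enna_core.GAConfig(
        population_size=config.population_size,
        generations=config.generations,
        mutation_prob=config.mutation_prob,
        folds=config.folds,
        seed=seeds["enna"],
    )
    mlp = enna_core.MLPConfig(
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        epochs=config.epochs,
    )
    enna = enna_core.evolve(balanced, ga, mlp)
    selected = enna.selected_variables(config.occurrence_threshold)
    final_mask = (
        enna_core.Chromosome.from_variables(selected) if selected else enna.best_mask
    )
    final = enna_core.final_classifier(
        balanced, final_mask, mlp, config.holdout_fraction, seed=seeds["final"]
    )

    fold_hits = class_stats.summarize_fold_hits(synthetic_data.table2_fixture())

    return {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(config),
        "seeds": seeds,
        "variables": list(VARIABLE_NAMES),
        "sizes": {
            "input": sizes_before,
            "flagged": report_out.totals,
            "filtered": sizes_filtered,
            "balanced": sizes_balanced,
        },
        "class_summary": summary.to_dict(orient="records"),
        "correlations": {cls: m.values.tolist() for cls, m in corr.items()},
        "enna": {
            "occurrence": dict(zip(VARIABLE_NAMES, map(float, enna.occurrence))),
            "best_mask": list(enna.best_mask.bits),
            "best_cv_misclassification": enna.best_fitness,
            "trace": enna.trace,
            "n_evaluations": enna.n_evaluations,
            "selected_variables": selected,
        },
        "final_classifier": {
            "mask": list(final_mask.bits),
            "variables": final_mask.selected(),
            "holdout_accuracy": final.holdout_accuracy,
            "whole_data_accuracy": final.whole_data_accuracy,
        },
        "fold_hits": fold_hits.reset_index().to_dict(orient="records"),
    }


def _human_summary(report: dict) -> str:
    lines = ["randnat pipeline report", "======================="]
    s = report["sizes"]
    lines.append(f"input sizes:    {s['input']}")
    lines.append(f"flagged:        {s['flagged']}")
    lines.append(f"after filter:   {s['filtered']}")
    lines.append(f"after balance:  {s['balanced']}")
    lines.append("")
    lines.append("ENNA occurrence probabilities:")
    for var, p in report["enna"]["occurrence"].items():
        lines.append(f"  {var:<24s} {p:.3f}")
    lines.append(f"selected variables: {report['enna']['selected_variables']}")
    fc = report["final_classifier"]
    lines.append(f"final classifier on {fc['variables']}:")
    lines.append(f"  holdout accuracy:    {fc['holdout_accuracy']:.4f}")
    lines.append(f"  whole-data accuracy: {fc['whole_data_accuracy']:.4f}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir) -> tuple[Path, Path]:
    """Write report.json (machine) and summary.txt (human); returns paths."""
    if not report:
        raise ValueError("refusing to write an empty report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    txt_path = out / "summary.txt"
    txt_path.write_text(_human_summary(report))
    return json_path, txt_path


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
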