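"""End-to-end orchestration: simulate/read -> fit -> index -> evaluate ->
longitudinal, with per-stage logging and a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, hierarchical, io, longitudinal, synthetic
from .features import BASELINE, FOLLOWUP, ID_COLUMN, TIMEPOINT_COLUMN

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    cohort: dict = field(default_factory=dict)      # CohortSpec overrides
    input_table: str | None = None                  # read instead of simulate
    k_folds: int = 7
    n_ortho_thickness: int | None = None
    n_ortho_volume: int | None = None
    n_ortho_top: int = 0
    block_scores: str = "all"
    threshold: float = 0.5
    seed: int = 0
    out_dir: str = "morphindex_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hier_config(self) -> hierarchical.HierarchicalConfig:
        return hierarchical.HierarchicalConfig(
            n_ortho_thickness=self.n_ortho_thickness,
            n_ortho_volume=self.n_ortho_volume,
            n_ortho_top=self.n_ortho_top,
            block_scores=self.block_scores,
            k_folds=self.k_folds,
            seed=self.seed,
        )


def training_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Baseline AD and CTL rows only; refuses MCI rows in the training set."""
    base = table[table[TIMEPOINT_COLUMN] == BASELINE]
    train = base[base["dx"].isin(["AD", "CTL"])].reset_index(drop=True)
    if len(train) == 0:
        raise ValueError("no baseline AD/CTL rows available for training")
    return train


def ensure_training_classes_only(table: pd.DataFrame) -> None:
    bad = set(table["dx"].unique()) - {"AD", "CTL"}
    if bad:
        raise ValueError(
            f"training set must contain only AD and CTL subjects; found {sorted(bad)}"
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Returns a dict with the in-memory artifacts (cohort table, model,
    indices, reports) in addition to writing them to disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    # --- stage: data --------------------------------------------------------
    if config.input_table:
        logger.info("stage=read input=%s", config.input_table)
        table = io.read_morphometry(config.input_table)
    else:
        spec = synthetic.CohortSpec(**{**config.cohort, "seed": config.seed})
        logger.info("stage=simulate seed=%d", config.seed)
        cohort = synthetic.generate_cohort(spec)
        table = cohort.data
        cohort_path = out / "cohort.tsv"
        io.write_morphometry(table, cohort_path)
        outputs["cohort"] = str(cohort_path)
    for (dx, tp), sub in table.groupby(["dx", TIMEPOINT_COLUMN]):
        logger.info("stage=data dx=%s timepoint=%s n=%d", dx, tp, len(sub))

    # --- stage: fit ---------------------------------------------------------
    train = training_rows(table)
    ensure_training_classes_only(train)
    y = (train["dx"] == "AD").astype(float).to_numpy()
    hier_cfg = config.hier_config()
    logger.info("stage=fit n_train=%d (AD=%d, CTL=%d)", len(train), int(y.sum()), int((1 - y).sum()))
    model = hierarchical.fit_hierarchical(train, y, hier_cfg)
    cv = hierarchical.cross_validate_hierarchical(train, y, hier_cfg)
    model.top_model.q2y = cv.q2y
    model_path = out / "model.json"
    model.save(model_path)
    outputs["model"] = str(model_path)
    logger.info("stage=fit q2y=%.3f significant=%s", cv.q2y, cv.q2y > 0.05)

    # --- stage: index -------------------------------------------------------
    indices = hierarchical.compute_index(model, table)
    index_path = out / "index.tsv"
    indices.to_csv(index_path, sep="\t", index=False)
    outputs["index"] = str(index_path)

    cv_indices = pd.DataFrame(
        {
            ID_COLUMN: train[ID_COLUMN].to_numpy(),
            "index": cv.y_predicted,
            "pattern": hierarchical.pattern_label(cv.y_predicted),
        }
    )
    cv_path = out / "index_cv_training.tsv"
    cv_indices.to_csv(cv_path, sep="\t", index=False)
    outputs["index_cv_training"] = str(cv_path)

    # --- stage: evaluate ----------------------------------------------------
    # The report's longitudinal blocks cover subjects with both timepoints.
    counts = table.groupby(ID_COLUMN)[TIMEPOINT_COLUMN].nunique()
    longitudinal_ids = set(counts[counts == 2].index)
    longi_indices = indices[indices[ID_COLUMN].isin(longitudinal_ids)]
    meta = table[[ID_COLUMN, "dx", "mci_status"]].drop_duplicates(ID_COLUMN)
    report = evaluation.classification_report(longi_indices, meta, cv_indices=cv_indices)
    report_path = out / "classification_report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    outputs["classification_report"] = str(report_path)

    # --- stage: longitudinal ------------------------------------------------
    longit = longitudinal.derive_longitudinal(longi_indices)
    longit_path = out / "longitudinal_index.tsv"
    longit.to_csv(longit_path, sep="\t", index=False)
    outputs["longitudinal_index"] = str(longit_path)

    meta_dx = longit.merge(meta, on=ID_COLUMN, validate="one_to_one")
    comparisons: list[pd.DataFrame] = []
    summaries = longitudinal.summarize_groups(
        pd.concat(
            [
                meta_dx.assign(value=meta_dx["index_baseline"], when="baseline"),
                meta_dx.assign(value=meta_dx["index_m12"], when="m12"),
            ]
        ),
        value="value",
        by=["dx", "when"],
    )
    summaries_path = out / "index_summaries.tsv"
    summaries.to_csv(summaries_path, sep="\t", index=False)
    outputs["index_summaries"] = str(summaries_path)

    pattern_cmp = longitudinal.pattern_comparisons(longit, meta)
    if len(pattern_cmp):
        comparisons.append(pattern_cmp)
    anova = longitudinal.rate_anova(meta_dx)
    paired = {
        dx: longitudinal.paired_change_test(
            sub["index_baseline"].to_numpy(), sub["index_m12"].to_numpy(),
            alternative="greater",
        )
        for dx, sub in meta_dx.groupby("dx")
        if len(sub) >= 2
    }

    mci_rows = table[
        (table["dx"] == "MCI") & (table[ID_COLUMN].isin(longitudinal_ids))
    ].merge(indices[[ID_COLUMN, TIMEPOINT_COLUMN, "index"]], on=[ID_COLUMN, TIMEPOINT_COLUMN])
    apoe = None
    if len(mci_rows) and mci_rows["apoe_e4"].nunique() == 2:
        apoe = longitudinal.apoe_stratification(mci_rows)
        apoe_path = out / "apoe_stratification.tsv"
        apoe.to_csv(apoe_path, sep="\t", index=False)
        outputs["apoe_stratification"] = str(apoe_path)

    stats_path = out / "longitudinal_stats.json"
    stats_blob = {
        "rate_anova": anova,
        "paired_change_by_dx": paired,
        "pattern_comparisons": pattern_cmp.to_dict("records") if len(pattern_cmp) else [],
    }
    stats_path.write_text(json.dumps(stats_blob, indent=1))
    outputs["longitudinal_stats"] = str(stats_path)

    manifest = io.write_manifest(out / "manifest.json", config.to_dict(), outputs)
    logger.info("stage=done outputs=%d", len(outputs))
    return {
        "table": table,
        "model": model,
        "cv": cv,
        "indices": indices,
        "report": report,
        "longitudinal": longit,
        "apoe": apoe,
        "manifest": manifest,
        "outputs": outputs,
    }
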