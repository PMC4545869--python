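"""End-to-end two-stage pipeline orchestration.

Order of operations: QC funnel -> batch alignment on M-values -> cell-type
deconvolution -> stage-1 recursive forest selection on the discovery
subsample (beta scale) -> outlier recoding -> stage-2 pooled logistic
association for both outcomes with Bonferroni control -> optional external
replication.  Every stage's counts, parameters and seeds land in a single
JSON-serializable report so a run can be audited and reproduced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc
from .association import associate_all, bonferroni_alpha, results_frame, significance_filter
from .deconvolution import estimate_proportions_matrix
from .forest import ForestParams
from .replication import replicate, replication_frame
from .selection import recursive_rf
from .simulate import SimulationConfig, generate_dataset
from .types import MethylationDataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Either ``simulation`` (a :class:`~ewasrf.simulate.SimulationConfig`) or
    ``input_dir`` (the TSV/CSV exchange formats) supplies the data.  The
    stage-1 subsample defaults to the phenotype rows with ``stage == 1``.
    Defaults mirror the published analysis choices: detection threshold
    0.01 at fraction 0.10, balanced sampsize (50, 50), mtry rule 0.1p,
    ntree 500, family alpha 0.05, replication alpha 0.05.
    """

    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    output_dir: str | None = None
    detection_p_threshold: float = 0.01
    detection_sample_fraction: float = 0.10
    batch_adjust: bool = True
    deconv_mode: str = "sum_le_one"
    ntree: int = 500
    mtry: str | int = "0.1p"
    sampsize: tuple[int, int] | None = (50, 50)
    stop_policy: str = "global_min"
    max_iterations: int = 15
    focal_class: int = 1
    outlier_fence_k: float = 3.0
    stage2_pool: bool = True
    family_alpha: float = 0.05
    replication_alpha: float = 0.05
    external_results: str | None = None   # CSV: probe_id, odds_ratio, p_value
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            raise ValueError("config needs a simulation block or an input_dir")


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        return generate_dataset(config.simulation)[:4] + (None,)
    from .simulate import read_dataset
    dataset, manifest, phenotype, reference = read_dataset(config.input_dir)
    return dataset, manifest, phenotype, reference, None


def _impute_within_class(beta: pd.DataFrame, outcome: pd.Series) -> pd.DataFrame:
    """Mean-impute missing betas within each outcome class (forest input
    cannot hold NaN)."""
    out = beta.copy()
    for cls, cols in outcome.groupby(outcome).groups.items():
        block = out[cols]
        means = block.mean(axis=1)
        out[cols] = block.T.fillna(means).T
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full two-stage analysis; returns the audit report dict.

    With an ``output_dir`` the filter report, selection trace, association
    and replication tables, and the report JSON are also written to disk.
    Identical config and seeds give identical outputs.
    """
    rng_seed = config.seed
    dataset, manifest, phenotype, reference, _ = _load_inputs(config)

    # ---- QC funnel -------------------------------------------------------
    clean, filter_report = qc.run_qc(
        dataset, manifest, config.detection_p_threshold,
        config.detection_sample_fraction)
    logger.info("QC: %d -> %d probes", filter_report.n_entry,
                filter_report.n_remaining)

    # ---- value prep ------------------------------------------------------
    m = qc.beta_matrix_to_m(clean.beta, eps=1e-6)
    if config.batch_adjust and phenotype["batch"].nunique() > 1:
        m = qc.adjust_batch(m, phenotype.loc[m.columns, "batch"])
        beta_adj = pd.DataFrame(
            1.0 / (1.0 + np.exp2(-m.to_numpy())), index=m.index,
            columns=m.columns)
    else:
        beta_adj = clean.beta

    # ---- cell-type deconvolution ----------------------------------------
    proportions = estimate_proportions_matrix(
        beta_adj, reference.loc[reference.index.intersection(beta_adj.index)],
        mode=config.deconv_mode)

    # ---- stage 1: recursive forest selection on the discovery subsample --
    stage1_ids = phenotype.index[phenotype["stage"] == 1] \
        if "stage" in phenotype.columns else phenotype.index
    y1 = phenotype.loc[stage1_ids, "atopy"]
    X1 = _impute_within_class(beta_adj[stage1_ids], y1).T  # samples x probes
    params = ForestParams(ntree=config.ntree, mtry=config.mtry,
                          sampsize=config.sampsize, seed=rng_seed)
    trace = recursive_rf(X1, y1, params, focal_class=config.focal_class,
                         stop_policy=config.stop_policy,
                         max_iterations=config.max_iterations)
    selected = trace.selected_variables
    logger.info("stage 1 selected %d probes at iteration %d",
                len(selected), trace.selected_iteration)

    # ---- stage 2: outlier recoding + association -------------------------
    # pooled (stage-1 + added samples) by default; disjoint when
    # stage2_pool is off, which removes the stage-1 selection optimism
    if config.stage2_pool or "stage" not in phenotype.columns:
        stage2_ids = phenotype.index
    else:
        stage2_ids = phenotype.index[phenotype["stage"] == 2]
    m_sel = m.loc[selected, stage2_ids]
    m_sel, recoded = qc.recode_outliers(
        m_sel, phenotype.loc[m_sel.columns, "atopy"],
        fence_k=config.outlier_fence_k)
    covariates = proportions.copy()
    covariates["sex_male"] = (phenotype.loc[covariates.index, "sex"] == "M"
                              ).astype(float)
    covariates = covariates.loc[stage2_ids]
    constant = covariates.columns[covariates.std() == 0]
    if len(constant):
        logger.info("dropping constant covariates in stage 2: %s",
                    list(constant))
        covariates = covariates.drop(columns=constant)
    per_test_alpha = bonferroni_alpha(len(selected), config.family_alpha)

    assoc = {}
    skipped = {}
    for outcome_name in ("atopy", "high_ige"):
        y = phenotype.loc[m_sel.columns, outcome_name]
        res, skip = associate_all(m_sel, y, covariates,
                                  outcome_name, config.family_alpha)
        assoc[outcome_name] = res
        skipped[outcome_name] = skip

    sig = {name: significance_filter(res, per_test_alpha)[1]
           for name, res in assoc.items()}

    # ---- optional replication -------------------------------------------
    replication = None
    if config.external_results is not None:
        external = pd.read_csv(config.external_results)
        sig_atopy, _ = significance_filter(assoc["atopy"], per_test_alpha)
        disc = pd.DataFrame({
            "probe_id": [r.probe_id for r in sig_atopy],
            "odds_ratio": [r.adjusted_or for r in sig_atopy],
        })
        records, tested, replicated = replicate(disc, external,
                                                config.replication_alpha)
        replication = {"n_tested": tested, "n_replicated": replicated,
                       "records": records}

    report = {
        "seed": rng_seed,
        "filter_report": filter_report.to_dict(),
        "n_recoded_outlier_cells": len(recoded),
        "stage1": {
            "n_samples": int(len(stage1_ids)),
            "selected_iteration": trace.selected_iteration,
            "n_selected": len(selected),
            "stop_policy": trace.stop_policy,
            "trace": trace.to_frame().to_dict(orient="records"),
        },
        "stage2": {
            "n_samples": int(m_sel.shape[1]),
            "per_test_alpha": per_test_alpha,
            "n_tested": {k: len(v) for k, v in assoc.items()},
            "n_skipped": {k: len(v) for k, v in skipped.items()},
            "n_significant": sig,
        },
        "parameters": {
            "detection_p_threshold": config.detection_p_threshold,
            "detection_sample_fraction": config.detection_sample_fraction,
            "ntree": config.ntree, "mtry": str(config.mtry),
            "sampsize": list(config.sampsize) if config.sampsize else None,
            "stop_policy": config.stop_policy,
            "stage2_pool": config.stage2_pool,
            "family_alpha": config.family_alpha,
        },
    }
    if replication is not None:
        report["replication"] = {"n_tested": replication["n_tested"],
                                 "n_replicated": replication["n_replicated"]}

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "filter_report.json").write_text(
            json.dumps(filter_report.to_dict(), indent=1, sort_keys=True))
        trace.to_frame().to_csv(out / "selection_trace.csv", index=False)
        (out / "selected_probes.json").write_text(
            json.dumps(sorted(selected), indent=1))
        for name, res in assoc.items():
            results_frame(res).to_csv(out / f"association_{name}.csv",
                                      index=False)
        pd.DataFrame(recoded, columns=["probe_id", "sample_id"]).to_csv(
            out / "recoded_cells.csv", index=False)
        if replication is not None:
            replication_frame(replication["records"]).to_csv(
                out / "replication.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))

    # full result objects for programmatic use, not serialized in the report
    report["_objects"] = {
        "trace": trace, "associations": assoc, "proportions": proportions,
        "filter_report": filter_report,
        "replication": replication,
    }
    return report
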