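"""End-to-end orchestration: simulate -> QC -> preprocess -> fit -> summarize.

Runs the stages in a fixed order with per-stage logging, writes intermediate
artifacts as TSV, and aggregates per-trait model fits into cohort-level
summaries (best-model fractions, component means and interquartile ranges,
correlation distributions, per-lineage averages).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import cohort_sim, preprocess, trait_qc, twin_models
from .cohort_sim import SimulationConfig, TraitMatrix, TwinCohort
from .trait_qc import QCReport, QCThresholds
from .twin_models import MODEL_LABELS, TwinData

__all__ = [
    "CohortSummary",
    "PipelineResult",
    "fit_traits",
    "run_pipeline",
    "summarize",
    "write_results",
]

log = logging.getLogger("twinace")

_FLOAT_FMT = "%.10g"
#: Component whose fraction summarises each best-model class.
FOCAL_COMPONENT = {"ACE": "a2", "AE": "a2", "CE": "c2", "E": "e2"}


# ---------------------------------------------------------------------------
# Per-trait fitting


def fit_traits(z_matrix: pd.DataFrame, cohort: TwinCohort,
               trait_meta: pd.DataFrame,
               repro_r: Mapping[str, float] | None = None,
               ci: bool = True, models: Iterable[str] = MODEL_LABELS,
               min_pairs: int = 10) -> pd.DataFrame:
    """Fit the twin models to every trait column of a processed z-matrix.

    Returns one row per trait with pair correlations, Falconer estimates,
    the four model fits (log-likelihood, AIC, convergence), likelihood-ratio
    tests against ACE, the AIC-best model and its standardized fractions,
    and optionally profile-likelihood confidence intervals.
    """
    models = list(models)
    repro_r = repro_r or {}
    rows = []
    for tid in z_matrix.columns:
        values = z_matrix[tid]
        data = TwinData.from_trait(values, cohort)
        row: dict = {"trait_id": tid}
        for colname in ("kind", "lineage_label", "true_a2", "true_c2",
                        "true_e2"):
            if colname in trait_meta.columns:
                row[colname] = trait_meta.at[tid, colname]
        row["n_mz_pairs"] = len(data.mz)
        row["n_dz_pairs"] = len(data.dz)
        row["r_mz"] = twin_models.pair_correlation(values, cohort, "MZ")
        row["r_dz"] = twin_models.pair_correlation(values, cohort, "DZ")
        row["r_longitudinal"] = repro_r.get(tid, math.nan)
        fh = twin_models.falconer_h2(row["r_mz"], row["r_dz"])
        row["falconer_h2"] = fh.h2
        row["falconer_h2_clipped"] = fh.h2_clipped

        try:
            fits = twin_models.fit_all_models(data, min_pairs=min_pairs,
                                              labels=models)
            best_label, record = twin_models.select_best_model(fits)
        except ValueError as err:
            log.warning("trait %s not modelled: %s", tid, err)
            row["best_model"] = "unmodelled"
            rows.append(row)
            continue

        for lab, f in fits.items():
            row[f"loglik_{lab}"] = f.loglik
            row[f"aic_{lab}"] = f.aic
            row[f"converged_{lab}"] = f.converged
        for lab, cmp_ in record["lrt_vs_ACE"].items():
            row[f"lrt_ACE_vs_{lab}"] = cmp_.lrt_stat
            row[f"lrt_p_ACE_vs_{lab}"] = cmp_.p_value

        best = fits[best_label]
        row["best_model"] = best_label
        row["a2"] = best.components.a2
        row["c2"] = best.components.c2
        row["e2"] = best.components.e2
        if ci:
            intervals = twin_models.component_ci(best, data)
            for comp, (lo, hi) in intervals.items():
                row[f"{comp}_ci_low"] = lo
                row[f"{comp}_ci_high"] = hi
        rows.append(row)
    results = pd.DataFrame(rows).set_index("trait_id")
    return results


# ---------------------------------------------------------------------------
# Cohort-level summary


@dataclass
class CohortSummary:
    """Headline aggregates over all modelled traits."""

    n_traits_modelled: int
    fraction_best_model: dict[str, float]
    component_by_best_model: pd.DataFrame  # mean / median / IQR of focal comp
    correlation_summary: pd.DataFrame      # r_mz, r_dz, r_long, falconer h2
    lineage_summary: pd.DataFrame          # mean A/C/E fractions per lineage

    def __post_init__(self) -> None:
        if self.n_traits_modelled:
            total = sum(self.fraction_best_model.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError("best-model fractions must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        """Flat key/value view, with percent alongside fraction units."""
        rows = [("n_traits_modelled", self.n_traits_modelled)]
        for lab, frac in self.fraction_best_model.items():
            rows.append((f"fraction_best_{lab}", frac))
            rows.append((f"percent_best_{lab}", 100.0 * frac))
        for lab, r in self.component_by_best_model.iterrows():
            comp = FOCAL_COMPONENT[lab]
            for stat in ("mean", "iqr_low", "median", "iqr_high"):
                rows.append((f"{lab}_{comp}_{stat}", r[stat]))
                rows.append((f"{lab}_{comp}_{stat}_percent", 100.0 * r[stat]))
        for name, r in self.correlation_summary.iterrows():
            for stat in self.correlation_summary.columns:
                rows.append((f"{name}_{stat}", r[stat]))
        return pd.DataFrame(rows, columns=["quantity", "value"])


def _dist_summary(x: pd.Series) -> dict[str, float]:
    x = x.dropna()
    if x.empty:
        return {k: math.nan for k in ("mean", "iqr_low", "median", "iqr_high")}
    # linear-interpolation quantiles
    q1, q2, q3 = x.quantile([0.25, 0.5, 0.75], interpolation="linear")
    return {"mean": float(x.mean()), "iqr_low": float(q1),
            "median": float(q2), "iqr_high": float(q3)}


def summarize(results: pd.DataFrame) -> CohortSummary:
    """Aggregate a per-trait results table into a CohortSummary."""
    modelled = results[results["best_model"].isin(MODEL_LABELS)]
    n = len(modelled)
    if n == 0:
        raise ValueError("no modelled traits to summarize")
    counts = modelled["best_model"].value_counts()
    fractions = {lab: float(counts.get(lab, 0)) / n for lab in MODEL_LABELS
                 if counts.get(lab, 0) > 0}

    comp_rows = {}
    for lab in MODEL_LABELS:
        sub = modelled[modelled["best_model"] == lab]
        if len(sub) == 0:
            continue
        comp_rows[lab] = _dist_summary(sub[FOCAL_COMPONENT[lab]])
    comp_df = pd.DataFrame.from_dict(comp_rows, orient="index")
    comp_df.index.name = "best_model"

    corr_rows = {}
    for col in ("r_mz", "r_dz", "r_longitudinal", "falconer_h2"):
        if col in modelled.columns:
            corr_rows[col] = _dist_summary(modelled[col])
    corr_df = pd.DataFrame.from_dict(corr_rows, orient="index")

    if "lineage_label" in modelled.columns and {"a2", "c2", "e2"} <= set(
            modelled.columns):
        lineage = (modelled.groupby("lineage_label")[["a2", "c2", "e2"]]
                   .mean().rename(columns={"a2": "mean_a2", "c2": "mean_c2",
                                           "e2": "mean_e2"}))
        lineage["n_traits"] = modelled.groupby("lineage_label").size()
    else:
        lineage = pd.DataFrame()

    return CohortSummary(n, fractions, comp_df, corr_df, lineage)


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class PipelineResult:
    cohort: TwinCohort
    qc_report: QCReport
    results: pd.DataFrame
    summary: CohortSummary
    artifacts: dict[str, str] = field(default_factory=dict)


def run_pipeline(sim_config: SimulationConfig | None = None,
                 thresholds: QCThresholds = QCThresholds(),
                 out_dir=None, seed: int | None = None, ci: bool = True,
                 models: Iterable[str] = MODEL_LABELS, k_sd: float = 4.0,
                 int_offset: float = preprocess.DEFAULT_INT_OFFSET,
                 cohort: TwinCohort | None = None,
                 traits: TraitMatrix | None = None,
                 longitudinal: pd.DataFrame | None = None) -> PipelineResult:
    """Run the full analysis, either on simulated or user-supplied data.

    If ``cohort``/``traits`` are not supplied they are simulated from
    ``sim_config`` (``seed`` overrides its rng_seed).  Stages run in fixed
    order — simulate, QC, preprocess, fit, summarize — and each stage logs
    its input/output counts.  With ``out_dir`` set, every intermediate
    table is written as TSV with a fixed float format, so identical
    configurations and seeds give byte-identical outputs.
    """
    artifacts: dict[str, str] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if traits is None or cohort is None:
        if sim_config is None:
            raise ValueError("need either sim_config or cohort+traits")
        if seed is not None:
            import dataclasses
            sim_config = dataclasses.replace(sim_config, rng_seed=seed)
        log.info("stage=simulate seed=%d n_traits=%d", sim_config.rng_seed,
                 sim_config.n_traits)
        cohort, traits, longitudinal = cohort_sim.simulate_dataset(sim_config)
        if out is not None:
            artifacts.update(cohort_sim.write_dataset(
                cohort, traits, longitudinal, out))

    log.info("stage=qc n_input=%d", traits.n_traits)
    robust, qc_report = trait_qc.run_qc(traits, longitudinal, thresholds)
    log.info("stage=qc n_robust=%d eliminated(window=%d repro=%d lineage=%d)",
             qc_report.n_robust, qc_report.n_eliminated_value_window,
             qc_report.n_eliminated_reproducibility,
             qc_report.n_eliminated_lineage)
    if out is not None:
        p = out / "qc_report.tsv"
        qc_report.trait_status.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
        qc_report.to_frame().to_csv(out / "qc_counts.tsv", sep="\t")
        artifacts["qc_report"] = str(p)
    if qc_report.n_robust == 0:
        raise RuntimeError("stage=qc: no robust traits survive filtering")

    log.info("stage=preprocess n_traits=%d", robust.n_traits)
    z_matrix, pp_log = preprocess.process_traits(robust, cohort, k_sd=k_sd,
                                                 int_offset=int_offset)
    if out is not None:
        z_matrix.to_csv(out / "processed.tsv", sep="\t",
                        float_format=_FLOAT_FMT)
        pp_log.to_csv(out / "preprocess_log.tsv", sep="\t",
                      float_format=_FLOAT_FMT)
        artifacts["processed"] = str(out / "processed.tsv")

    repro = qc_report.trait_status["repro_r"].to_dict()
    log.info("stage=fit n_traits=%d ci=%s", robust.n_traits, ci)
    results = fit_traits(z_matrix, cohort, robust.trait_meta, repro_r=repro,
                         ci=ci, models=models)
    n_unconverged = int((results["best_model"] == "unmodelled").sum())
    if n_unconverged:
        log.warning("stage=fit unmodelled_traits=%d", n_unconverged)
    if out is not None:
        p = out / "results.tsv"
        write_results(results, p)
        artifacts["results"] = str(p)

    summary = summarize(results)
    log.info("stage=summarize n_modelled=%d", summary.n_traits_modelled)
    if out is not None:
        p = out / "summary.tsv"
        summary.to_frame().to_csv(p, sep="\t", index=False,
                                  float_format=_FLOAT_FMT)
        artifacts["summary"] = str(p)
    return PipelineResult(cohort, qc_report, results, summary, artifacts)


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def plot_histograms(results: pd.DataFrame, out_dir) -> list[str]:
    """Optional histogram set for r_MZ, r_DZ and Falconer h2.

    Requires matplotlib; import is deferred so the plotting extra stays
    optional.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for col, label in (("r_mz", "MZ pair correlation"),
                       ("r_dz", "DZ pair correlation"),
                       ("falconer_h2", "Falconer heritability")):
        if col not in results.columns:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(results[col].dropna(), bins=30, color="#4878a8")
        ax.set_xlabel(label)
        ax.set_ylabel("traits")
        fig.tight_layout()
        p = out / f"hist_{col}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(str(p))
    return written
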