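"""Robustness filters applied to trait panels before twin modelling.

Three criteria are applied sequentially, mirroring the accounting structure
of large immunophenotyping studies:

1. value window — a CSF trait's across-subject summary frequency must lie
   strictly between ``csf_min`` and ``csf_max`` percent; a SPEL trait's
   summary median fluorescence intensity must exceed ``spel_min_mfi``;
2. longitudinal reproducibility — the Pearson correlation between the two
   control time points must exceed ``repro_min_r``;
3. lineage — traits from explicitly excluded (poorly characterised)
   lineages are dropped.

A trait eliminated by an earlier criterion is not re-counted by a later
one, so eliminations plus survivors always reconcile with the input count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort_sim import TraitMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "filter_value_window",
    "filter_reproducibility",
    "filter_lineage",
    "run_qc",
]

#: Status labels attributed to the first failing criterion.
PASS = "pass"
FAIL_WINDOW = "fail_value_window"
FAIL_NO_DATA = "fail_no_data"
FAIL_REPRO = "fail_reproducibility"
FAIL_CONTROLS = "fail_insufficient_controls"
FAIL_LINEAGE = "fail_lineage"


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; all comparisons are strict inequalities."""

    csf_min: float = 0.1
    csf_max: float = 99.0
    spel_min_mfi: float = 100.0
    repro_min_r: float = 0.7
    excluded_lineage_labels: frozenset[str] = frozenset(
        {"CD4+CD8+ T", "CD4-CD8- T"})
    summary: str = "median"  # across-subject summary: median, mean or all

    def __post_init__(self) -> None:
        if not 0.0 <= self.csf_min < self.csf_max <= 100.0:
            raise ValueError("need 0 <= csf_min < csf_max <= 100")
        if not -1.0 <= self.repro_min_r <= 1.0:
            raise ValueError("repro_min_r must be in [-1, 1]")
        if self.summary not in ("median", "mean", "all"):
            raise ValueError("summary must be 'median', 'mean' or 'all'")
        object.__setattr__(
            self, "excluded_lineage_labels",
            frozenset(s.casefold() for s in self.excluded_lineage_labels))

    @classmethod
    def from_yaml(cls, path) -> "QCThresholds":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "excluded_lineage_labels" in raw:
            raw["excluded_lineage_labels"] = frozenset(
                raw["excluded_lineage_labels"])
        return cls(**raw)


@dataclass
class QCReport:
    """Per-criterion elimination ledger for one QC run."""

    n_input: int
    n_eliminated_value_window: int
    n_eliminated_reproducibility: int
    n_eliminated_lineage: int
    n_robust: int
    trait_status: pd.DataFrame  # index trait_id; columns status, repro_r

    def __post_init__(self) -> None:
        eliminated = (self.n_eliminated_value_window
                      + self.n_eliminated_reproducibility
                      + self.n_eliminated_lineage)
        if self.n_input - eliminated != self.n_robust:
            raise ValueError("QC accounting identity violated")

    def to_frame(self) -> pd.DataFrame:
        counts = {k: getattr(self, k) for k in (
            "n_input", "n_eliminated_value_window",
            "n_eliminated_reproducibility", "n_eliminated_lineage",
            "n_robust")}
        return pd.DataFrame({"count": counts})


def _summarize(col: pd.Series, how: str) -> float:
    vals = col.dropna()
    if vals.empty:
        return np.nan
    return float(vals.median() if how == "median" else vals.mean())


def filter_value_window(traits: TraitMatrix,
                        thresholds: QCThresholds = QCThresholds()
                        ) -> pd.DataFrame:
    """Per-trait pass/fail against the kind-specific value window.

    With ``summary='all'`` every non-missing subject value must pass;
    otherwise the across-subject median (or mean) is tested.  Traits with
    no non-missing values fail with a "no data" status.
    """
    records = {}
    for tid in traits.values.columns:
        kind = traits.trait_meta.at[tid, "kind"]
        col = traits.values[tid].dropna()
        if col.empty:
            records[tid] = (False, FAIL_NO_DATA)
            continue
        if thresholds.summary == "all":
            if kind == "CSF":
                ok = bool(((col > thresholds.csf_min)
                           & (col < thresholds.csf_max)).all())
            else:
                ok = bool((col > thresholds.spel_min_mfi).all())
        else:
            s = _summarize(col, thresholds.summary)
            if kind == "CSF":
                ok = thresholds.csf_min < s < thresholds.csf_max
            else:
                ok = s > thresholds.spel_min_mfi
        records[tid] = (ok, PASS if ok else FAIL_WINDOW)
    out = pd.DataFrame.from_dict(records, orient="index",
                                 columns=["passed", "status"])
    out.index.name = "trait_id"
    return out


def reproducibility_r(longitudinal: pd.DataFrame, trait_id: str,
                      min_pairs: int = 3) -> float:
    """Pearson test-retest correlation across controls for one trait.

    Uses original (replicate == 0) vials only; replicate vials measure
    run-to-run rather than longitudinal variation.  NaN when fewer than
    ``min_pairs`` controls have both time points.
    """
    orig = longitudinal[longitudinal["replicate"] == 0]
    wide = orig.pivot_table(index="control_id", columns="timepoint",
                            values=trait_id)
    if not {1, 2} <= set(wide.columns):
        return np.nan
    both = wide[[1, 2]].dropna()
    if len(both) < min_pairs:
        return np.nan
    x, y = both[1].to_numpy(), both[2].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def filter_reproducibility(longitudinal: pd.DataFrame,
                           thresholds: QCThresholds = QCThresholds(),
                           trait_ids=None) -> pd.DataFrame:
    """Per-trait pass/fail on longitudinal test-retest correlation."""
    if trait_ids is None:
        trait_ids = [c for c in longitudinal.columns
                     if c not in ("control_id", "timepoint", "replicate")]
    records = {}
    for tid in trait_ids:
        r = reproducibility_r(longitudinal, tid)
        if np.isnan(r):
            records[tid] = (False, FAIL_CONTROLS, r)
        else:
            ok = r > thresholds.repro_min_r
            records[tid] = (ok, PASS if ok else FAIL_REPRO, r)
    out = pd.DataFrame.from_dict(records, orient="index",
                                 columns=["passed", "status", "repro_r"])
    out.index.name = "trait_id"
    return out


def filter_lineage(trait_meta: pd.DataFrame,
                   thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Per-trait pass/fail against the excluded-lineage list.

    Matching is exact on the case-normalized label.
    """
    labels = trait_meta["lineage_label"].astype(str).str.casefold()
    passed = ~labels.isin(thresholds.excluded_lineage_labels)
    out = pd.DataFrame({
        "passed": passed,
        "status": np.where(passed, PASS, FAIL_LINEAGE),
    })
    out.index = trait_meta.index
    out.index.name = "trait_id"
    return out


def run_qc(traits: TraitMatrix, longitudinal: pd.DataFrame | None,
           thresholds: QCThresholds = QCThresholds()
           ) -> tuple[TraitMatrix, QCReport]:
    """Apply the three filters sequentially and reconcile the counts.

    Order: value window, then reproducibility, then lineage; each trait is
    attributed to the first criterion it fails.  ``longitudinal`` may be
    None, in which case the reproducibility filter is skipped entirely.
    """
    trait_ids = list(traits.values.columns)
    if longitudinal is not None:
        long_traits = {c for c in longitudinal.columns
                       if c not in ("control_id", "timepoint", "replicate")}
        missing = set(trait_ids) - long_traits
        if missing:
            raise ValueError(
                f"{len(missing)} trait ids absent from longitudinal table")

    status = pd.Series(PASS, index=pd.Index(trait_ids, name="trait_id"))
    repro = pd.Series(np.nan, index=status.index)

    window = filter_value_window(traits, thresholds)
    status[~window["passed"]] = window.loc[~window["passed"], "status"]

    surviving = status[status == PASS].index
    if longitudinal is not None and len(surviving):
        rep = filter_reproducibility(longitudinal, thresholds,
                                     trait_ids=list(surviving))
        repro[rep.index] = rep["repro_r"]
        failed = rep.index[~rep["passed"]]
        status[failed] = rep.loc[failed, "status"]

    surviving = status[status == PASS].index
    if len(surviving):
        lin = filter_lineage(traits.trait_meta.loc[surviving], thresholds)
        failed = lin.index[~lin["passed"]]
        status[failed] = FAIL_LINEAGE

    robust_ids = list(status[status == PASS].index)
    n_window = int(status.isin([FAIL_WINDOW, FAIL_NO_DATA]).sum())
    n_repro = int(status.isin([FAIL_REPRO, FAIL_CONTROLS]).sum())
    n_lineage = int((status == FAIL_LINEAGE).sum())
    report = QCReport(
        n_input=len(trait_ids),
        n_eliminated_value_window=n_window,
        n_eliminated_reproducibility=n_repro,
        n_eliminated_lineage=n_lineage,
        n_robust=len(robust_ids),
        trait_status=pd.DataFrame({"status": status, "repro_r": repro}),
    )
    return traits.select(robust_ids), report
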