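"""Per-trait transformation to the modelling scale.

The fixed order is: remove gross outliers (beyond ``k_sd`` standard
deviations of the raw values, single pass), regress out age by ordinary
least squares, then map the residuals to normal scores with the rank-based
inverse normal transform (INT).  After INT every trait is approximately
standard normal, so the structured-covariance twin models downstream can
assume normal margins; because INT depends only on ranks, any strictly
monotone distortion of the raw measurement scale is irrelevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_sim import TraitMatrix, TwinCohort

__all__ = [
    "ProcessedTrait",
    "remove_outliers",
    "age_adjust",
    "inverse_normal_transform",
    "process_trait",
    "process_traits",
    "normality_spot_check",
]

#: Blom's rank offset; 0 gives van der Waerden scores, 0.5 Tukey's.
DEFAULT_INT_OFFSET = 3.0 / 8.0


@dataclass
class ProcessedTrait:
    trait_id: str
    z_values: pd.Series  # indexed by retained subject_id
    n_outliers_removed: int
    age_slope: float

    @property
    def subjects_retained(self) -> list:
        return list(self.z_values.index)


def remove_outliers(values: pd.Series, k_sd: float = 4.0
                    ) -> tuple[pd.Series, pd.Index]:
    """Drop values more than ``k_sd`` sample standard deviations from the mean.

    Mean and sd come from a single pass over all non-missing values; the
    cut is not iterated.  Zero-variance input removes nothing.
    """
    vals = values.dropna()
    if len(vals) < 3:
        raise ValueError("need at least 3 non-missing values")
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn(f"zero variance for {values.name}; no outliers removed",
                      stacklevel=2)
        return vals, vals.index[:0]
    out = (vals - vals.mean()).abs() > k_sd * sd
    return vals[~out], vals.index[out]


def age_adjust(values: pd.Series, ages: pd.Series) -> tuple[pd.Series, float]:
    """OLS residuals of value on age (with intercept), plus the fitted slope.

    With constant ages the regression is undefined; mean-centered values
    are returned with slope 0 and a warning.
    """
    if len(values) != len(ages):
        raise ValueError("values and ages must be aligned")
    if len(values) < 3:
        raise ValueError("need at least 3 points for the age regression")
    age = ages.to_numpy(dtype=float)
    y = values.to_numpy(dtype=float)
    if np.ptp(age) == 0:
        warnings.warn("constant ages; returning mean-centered values",
                      stacklevel=2)
        return values - y.mean(), 0.0
    fit = stats.linregress(age, y)
    resid = y - (fit.intercept + fit.slope * age)
    return pd.Series(resid, index=values.index, name=values.name), float(fit.slope)


def inverse_normal_transform(values, offset: float = DEFAULT_INT_OFFSET
                             ) -> np.ndarray:
    """Rank-based inverse normal transform.

    z_i = Phi^-1((r_i - offset) / (n - 2*offset + 1)) with average ranks for
    ties.  The output depends on the input only through its ranks.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d array of values")
    if np.unique(x).size < 2:
        raise ValueError("inverse normal transform undefined for constant input")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size - 2 * offset + 1))


def process_trait(values: pd.Series, ages: pd.Series, k_sd: float = 4.0,
                  int_offset: float = DEFAULT_INT_OFFSET) -> ProcessedTrait:
    """Outlier removal, age adjustment and INT for one trait.

    ``values`` and ``ages`` are indexed by subject_id; missing values are
    dropped per trait, so a subject excluded here may be retained for other
    traits.
    """
    kept, removed = remove_outliers(values, k_sd=k_sd)
    resid, slope = age_adjust(kept, ages.loc[kept.index])
    z = inverse_normal_transform(resid.to_numpy(), offset=int_offset)
    return ProcessedTrait(
        trait_id=str(values.name),
        z_values=pd.Series(z, index=kept.index, name=values.name),
        n_outliers_removed=len(removed),
        age_slope=slope,
    )


def process_traits(traits: TraitMatrix, cohort: TwinCohort, k_sd: float = 4.0,
                   int_offset: float = DEFAULT_INT_OFFSET
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process every trait; returns (z-matrix, per-trait log).

    The z-matrix is subjects x traits with NaN marking subjects removed (or
    missing) for that trait.  The log records outlier counts and fitted age
    slopes.
    """
    ages = cohort.subjects.set_index("subject_id")["age"]
    zcols, log = {}, {}
    for tid in traits.values.columns:
        p = process_trait(traits.values[tid], ages, k_sd=k_sd,
                          int_offset=int_offset)
        zcols[tid] = p.z_values
        log[tid] = (p.n_outliers_removed, p.age_slope,
                    len(p.subjects_retained))
    z = pd.DataFrame(zcols, index=traits.values.index)
    z.index.name = "subject_id"
    log_df = pd.DataFrame.from_dict(
        log, orient="index",
        columns=["n_outliers_removed", "age_slope", "n_retained"])
    log_df.index.name = "trait_id"
    return z, log_df


def normality_spot_check(z_matrix: pd.DataFrame, cohort: TwinCohort,
                         n_sample: int = 100, seed: int = 0,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk spot check on a random sample of processed traits.

    Each sampled trait is tested in the whole cohort and separately in the
    MZ-only and DZ-only subgroups.  Returns per-trait p-values; the
    ``attrs`` dict carries the rejection fraction per group at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    trait_ids = list(z_matrix.columns)
    if len(trait_ids) > n_sample:
        trait_ids = list(rng.choice(trait_ids, size=n_sample, replace=False))
    roster = cohort.subjects.set_index("subject_id")
    groups = {
        "all": z_matrix.index,
        "MZ": roster.index[roster["zygosity"] == "MZ"],
        "DZ": roster.index[roster["zygosity"] == "DZ"],
    }
    rows = {}
    for tid in trait_ids:
        pvals = []
        for name, idx in groups.items():
            vals = z_matrix.loc[z_matrix.index.intersection(idx), tid].dropna()
            pvals.append(stats.shapiro(vals).pvalue if len(vals) >= 3 else np.nan)
        rows[tid] = pvals
    report = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=[f"p_{g}" for g in groups])
    report.index.name = "trait_id"
    report.attrs["rejection_fraction"] = {
        g: float((report[f"p_{g}"] < alpha).mean()) for g in groups}
    return report
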