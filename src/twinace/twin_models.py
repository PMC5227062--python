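"""Variance-component twin models: ACE/AE/CE/E maximum likelihood.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared-environment (C) and unique-environment (E, which also
absorbs measurement error) parts.  Writing path coefficients a, c, e, a twin
pair is bivariate normal with common mean mu and covariance

    MZ:  [[a^2+c^2+e^2, a^2+c^2   ], [a^2+c^2,    a^2+c^2+e^2]]
    DZ:  [[a^2+c^2+e^2, a^2/2+c^2 ], [a^2/2+c^2,  a^2+c^2+e^2]]

because MZ co-twins share all additive genetic variance and DZ co-twins
half of it.  Singletons (and the observed member of a half-missing pair)
contribute univariate normal marginals.  Submodels AE, CE and E fix c, a or
both at zero; nested fits are compared by likelihood-ratio tests against a
chi-square reference, and the best model per trait is the converged fit with
the lowest Akaike information criterion.

Likelihood evaluation is O(1) in the data via per-group sufficient
statistics, which makes the per-trait multi-start optimisation and the
profile-likelihood confidence intervals cheap even across thousands of
traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinData",
    "VarianceComponents",
    "ModelFit",
    "ModelComparison",
    "PairCorrelations",
    "FalconerH2",
    "pair_correlation",
    "falconer_h2",
    "twin_loglik",
    "fit_model",
    "fit_all_models",
    "compare_models",
    "select_best_model",
    "component_ci",
]

_LOG2PI = math.log(2.0 * math.pi)
MODEL_LABELS = ("ACE", "AE", "CE", "E")
#: Tie-break ordering for model selection: simpler labels win.
_LABEL_ORDER = {"E": 0, "CE": 1, "AE": 2, "ACE": 3}
#: Free-parameter counts including the estimated mean.
_N_PARAMS = {"ACE": 4, "AE": 3, "CE": 3, "E": 2}
_NESTED_IN = {"ACE": {"AE", "CE", "E"}, "AE": {"E"}, "CE": {"E"}}
#: Relative floor on the unique-environment path, as a fraction of sample sd.
E_FLOOR_FRACTION = 1e-6


# ---------------------------------------------------------------------------
# Data container and sufficient statistics


def _pair_array(values: pd.Series, cohort, zygosity: str) -> np.ndarray:
    """Complete (both members observed) pair values, shape (n_pairs, 2)."""
    pairs = []
    for members in cohort.families(zygosity):
        if len(members) != 2:
            continue
        v = values.reindex(list(members)).to_numpy(dtype=float)
        if not np.any(np.isnan(v)):
            pairs.append(v)
    return np.asarray(pairs, dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class TwinData:
    """One trait's observations arranged for the twin likelihood."""

    mz: np.ndarray        # (n_mz, 2) complete MZ pairs
    dz: np.ndarray        # (n_dz, 2) complete DZ pairs
    singles: np.ndarray   # (n_s,) singletons + lone members of broken pairs

    @classmethod
    def from_trait(cls, values: pd.Series, cohort) -> "TwinData":
        """Split a per-subject value series by the cohort's pair structure.

        Pairs with one missing member are not dropped: the observed member
        joins the singletons and contributes its univariate marginal.
        """
        mz, dz, singles = [], [], []
        for zyg, bucket in (("MZ", mz), ("DZ", dz)):
            for members in cohort.families(zyg):
                v = values.reindex(list(members)).to_numpy(dtype=float)
                ok = ~np.isnan(v)
                if ok.all() and len(v) == 2:
                    bucket.append(v)
                else:
                    singles.extend(v[ok])
        for members in cohort.families("singleton"):
            v = values.reindex(list(members)).to_numpy(dtype=float)
            singles.extend(v[~np.isnan(v)])
        return cls(np.asarray(mz).reshape(-1, 2),
                   np.asarray(dz).reshape(-1, 2),
                   np.asarray(singles, dtype=float))

    @property
    def n_pairs(self) -> int:
        return len(self.mz) + len(self.dz)

    def all_values(self) -> np.ndarray:
        return np.concatenate([self.mz.ravel(), self.dz.ravel(), self.singles])


class _Suff(NamedTuple):
    """Sufficient statistics for the exchangeable-pair normal likelihood."""

    n_mz: int
    mz_s1: float   # sum(x1 + x2)
    mz_s2: float   # sum(x1^2 + x2^2)
    mz_sp: float   # sum(x1 * x2)
    n_dz: int
    dz_s1: float
    dz_s2: float
    dz_sp: float
    n_sg: int
    sg_s1: float
    sg_s2: float

    @classmethod
    def from_data(cls, data: TwinData) -> "_Suff":
        def pair_stats(p):
            if len(p) == 0:
                return 0, 0.0, 0.0, 0.0
            return (len(p), float(p.sum()), float((p * p).sum()),
                    float((p[:, 0] * p[:, 1]).sum()))

        nm, ms1, ms2, msp = pair_stats(data.mz)
        nd, ds1, ds2, dsp = pair_stats(data.dz)
        s = data.singles
        return cls(nm, ms1, ms2, msp, nd, ds1, ds2, dsp,
                   len(s), float(s.sum()), float((s * s).sum()))


def _pair_group_ll(n, s1, s2, sp, mu, v, s):
    """Log-likelihood of n exchangeable bivariate-normal pairs."""
    if n == 0:
        return 0.0
    det = v * v - s * s
    if det <= 0.0 or v <= 0.0:
        return -math.inf
    q1 = s2 - 2.0 * mu * s1 + 2.0 * n * mu * mu   # sum of squared deviations
    q2 = sp - mu * s1 + n * mu * mu               # sum of cross products
    return (-n * _LOG2PI - 0.5 * n * math.log(det)
            - (v * q1 - 2.0 * s * q2) / (2.0 * det))


def _suff_loglik(suff: _Suff, mu, va, vc, ve):
    """Model log-likelihood from sufficient statistics."""
    v = va + vc + ve
    if v <= 0.0:
        return -math.inf
    ll = _pair_group_ll(suff.n_mz, suff.mz_s1, suff.mz_s2, suff.mz_sp,
                        mu, v, va + vc)
    ll += _pair_group_ll(suff.n_dz, suff.dz_s1, suff.dz_s2, suff.dz_sp,
                         mu, v, 0.5 * va + vc)
    if suff.n_sg:
        q = suff.sg_s2 - 2.0 * mu * suff.sg_s1 + suff.n_sg * mu * mu
        ll += -0.5 * suff.n_sg * (_LOG2PI + math.log(v)) - q / (2.0 * v)
    return ll


def twin_loglik(params: Mapping[str, float], mz_pairs, dz_pairs,
                singletons=()) -> float:
    """Twin-model log-likelihood at the given mean and path coefficients.

    ``params`` maps ``mean``, ``a``, ``c``, ``e`` to floats; paths are
    squared into variance components internally, so their signs are
    irrelevant.  Non-positive-definite covariances yield ``-inf``.
    """
    data = TwinData(np.asarray(mz_pairs, dtype=float).reshape(-1, 2),
                    np.asarray(dz_pairs, dtype=float).reshape(-1, 2),
                    np.asarray(singletons, dtype=float).ravel())
    suff = _Suff.from_data(data)
    a, c, e = params["a"], params["c"], params["e"]
    return _suff_loglik(suff, params["mean"], a * a, c * c, e * e)


# ---------------------------------------------------------------------------
# Descriptive statistics


@dataclass(frozen=True)
class PairCorrelations:
    trait_id: str
    r_mz: float
    r_dz: float
    n_mz_pairs: int
    n_dz_pairs: int
    r_longitudinal: float = math.nan


def _double_entry_r(pairs: np.ndarray) -> float:
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    if np.std(x) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def pair_correlation(values: pd.Series, cohort, zygosity: str,
                     min_pairs: int = 3) -> float:
    """Double-entry Pearson correlation for one zygosity class.

    Each complete pair enters as both (x1, x2) and (x2, x1), making the
    statistic invariant to within-pair ordering (it equals the maximum
    likelihood intraclass correlation up to the pooled mean/variance
    convention).  NaN when fewer than ``min_pairs`` complete pairs exist.
    """
    pairs = _pair_array(values, cohort, zygosity)
    if len(pairs) < min_pairs:
        return math.nan
    return _double_entry_r(pairs)


class FalconerH2(NamedTuple):
    h2: float          # 2 * (r_MZ - r_DZ), unclipped
    h2_clipped: float  # same, clipped into [0, 1]


def falconer_h2(r_mz: float, r_dz: float) -> FalconerH2:
    """Falconer's heritability approximation h2 = 2 (r_MZ - r_DZ)."""
    h2 = 2.0 * (r_mz - r_dz)
    return FalconerH2(h2, float(np.clip(h2, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Model fits


@dataclass(frozen=True)
class VarianceComponents:
    """Standardized fractions and raw path coefficients of one fit."""

    a2: float
    c2: float
    e2: float
    total_variance: float
    a: float
    c: float
    e: float

    def __post_init__(self) -> None:
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-8:
            raise ValueError("standardized fractions must sum to 1")

    @classmethod
    def from_paths(cls, a: float, c: float, e: float) -> "VarianceComponents":
        va, vc, ve = a * a, c * c, e * e
        total = va + vc + ve
        if total <= 0:
            raise ValueError("total variance must be positive")
        return cls(va / total, vc / total, ve / total, total,
                   abs(a), abs(c), abs(e))


@dataclass(frozen=True)
class ModelFit:
    model_label: str
    components: VarianceComponents
    mean: float
    loglik: float
    k: int
    aic: float
    converged: bool
    ci95: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.model_label not in MODEL_LABELS:
            raise ValueError(f"unknown model label {self.model_label!r}")
        if abs(self.aic - (-2.0 * self.loglik + 2.0 * self.k)) > 1e-10:
            raise ValueError("AIC inconsistent with loglik and k")


@dataclass(frozen=True)
class ModelComparison:
    full_label: str
    nested_label: str
    lrt_stat: float
    df: int
    p_value: float


def _sample_stats(data: TwinData) -> tuple[float, float]:
    x = data.all_values()
    if len(x) == 0:
        raise ValueError("no observations")
    mu = float(x.mean())
    v = float(((x - mu) ** 2).mean())
    return mu, v


def _mom_fractions(data: TwinData) -> tuple[float, float] | None:
    """Method-of-moments (a2, c2) start from double-entry correlations."""
    if len(data.mz) < 3 or len(data.dz) < 3:
        return None
    r_mz = _double_entry_r(data.mz)
    r_dz = _double_entry_r(data.dz)
    if math.isnan(r_mz) or math.isnan(r_dz):
        return None
    a2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    a2, c2 = max(a2, 0.0), max(c2, 0.0)
    total = a2 + c2
    if total > 0.95:
        a2, c2 = 0.95 * a2 / total, 0.95 * c2 / total
    return a2, c2


_SIMPLEX_STARTS = {
    "ACE": [(1 / 3, 1 / 3), (0.6, 0.2), (0.2, 0.6), (0.05, 0.05), (0.8, 0.05)],
    "AE": [(0.05, 0.0), (0.3, 0.0), (0.5, 0.0), (0.7, 0.0), (0.9, 0.0)],
    "CE": [(0.0, 0.05), (0.0, 0.3), (0.0, 0.5), (0.0, 0.7), (0.0, 0.9)],
}


def _fit_e_model(suff: _Suff, data: TwinData) -> ModelFit:
    """Closed-form MLE of the E-only model: pooled mean and variance."""
    mu, v = _sample_stats(data)
    ll = _suff_loglik(suff, mu, 0.0, 0.0, v)
    comp = VarianceComponents(0.0, 0.0, 1.0, v, 0.0, 0.0, math.sqrt(v))
    k = _N_PARAMS["E"]
    return ModelFit("E", comp, mu, ll, k, -2.0 * ll + 2.0 * k, True)


def _optimize_paths(suff: _Suff, label: str, starts, e_floor2: float
                    ) -> tuple[np.ndarray, float, bool]:
    """Multi-start Nelder-Mead over (mean, free paths); returns best point."""
    free_a = "A" in label
    free_c = "C" in label

    def unpack(x):
        i = 1
        va = x[i] ** 2 if free_a else 0.0
        i += free_a
        vc = x[i] ** 2 if free_c else 0.0
        i += free_c
        ve = x[i] ** 2 + e_floor2
        return x[0], va, vc, ve

    def nll(x):
        return -_suff_loglik(suff, *unpack(x))

    best, best_val, ok = None, math.inf, False
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 4000, "maxfev": 4000})
        if res.fun < best_val:
            best, best_val, ok = res.x, res.fun, bool(res.success)
    return np.asarray(best), -best_val, ok


def _starts_for(label: str, mu0: float, v0: float, data: TwinData,
                extra_paths: Iterable[tuple[float, float, float]] = ()
                ) -> list[list[float]]:
    fracs = list(_SIMPLEX_STARTS[label])
    mom = _mom_fractions(data)
    if mom is not None:
        fa = mom[0] if "A" in label else 0.0
        fc = mom[1] if "C" in label else 0.0
        if fa + fc > 0.95:
            fa, fc = 0.95 * fa / (fa + fc), 0.95 * fc / (fa + fc)
        fracs.append((fa, fc))
    starts = []
    for fa, fc in fracs:
        fe = max(1.0 - fa - fc, 0.02)
        paths = (math.sqrt(fa * v0), math.sqrt(fc * v0), math.sqrt(fe * v0))
        starts.append(_pack_start(label, mu0, paths))
    for paths in extra_paths:
        starts.append(_pack_start(label, mu0, paths))
    return starts


def _pack_start(label, mu0, paths):
    x = [mu0]
    if "A" in label:
        x.append(paths[0])
    if "C" in label:
        x.append(paths[1])
    x.append(max(paths[2], 1e-6))
    return x


def fit_model(data: TwinData, model_label: str, min_pairs: int = 10,
              extra_starts: Iterable[tuple[float, float, float]] = ()
              ) -> ModelFit:
    """Maximum-likelihood fit of one labelled twin model.

    Free parameters are the mean, E, and whichever of A and C the label
    names; absent paths are fixed at zero.  Optimisation runs Nelder-Mead
    from deterministic starts spanning the (a2, c2) simplex plus a
    method-of-moments start; the E path is floored at a tiny fraction of
    the sample standard deviation so the covariance stays positive
    definite.
    """
    if model_label not in MODEL_LABELS:
        raise ValueError(f"unknown model label {model_label!r}")
    if data.n_pairs < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} complete pairs, have {data.n_pairs}")
    suff = _Suff.from_data(data)
    if model_label == "E":
        return _fit_e_model(suff, data)

    mu0, v0 = _sample_stats(data)
    e_floor2 = (E_FLOOR_FRACTION ** 2) * v0
    starts = _starts_for(model_label, mu0, v0, data, extra_starts)
    x, ll, ok = _optimize_paths(suff, model_label, starts, e_floor2)

    i = 1
    a = abs(x[i]) if "A" in model_label else 0.0
    i += "A" in model_label
    c = abs(x[i]) if "C" in model_label else 0.0
    i += "C" in model_label
    e = math.sqrt(x[i] ** 2 + e_floor2)
    comp = VarianceComponents.from_paths(a, c, e)
    k = _N_PARAMS[model_label]
    converged = ok and math.isfinite(ll)
    return ModelFit(model_label, comp, float(x[0]), ll, k,
                    -2.0 * ll + 2.0 * k, converged)


def fit_all_models(data: TwinData, min_pairs: int = 10,
                   labels: Iterable[str] = MODEL_LABELS
                   ) -> dict[str, ModelFit]:
    """Fit the requested submodels with cascading warm starts.

    The AE and CE optima are handed to the ACE fit as additional starts,
    which enforces the nesting inequality loglik(ACE) >= loglik(AE), ...
    up to optimizer tolerance.
    """
    labels = list(labels)
    fits: dict[str, ModelFit] = {}
    warm: list[tuple[float, float, float]] = []
    for label in ("E", "CE", "AE"):
        if label in labels:
            fits[label] = fit_model(data, label, min_pairs=min_pairs)
            cp = fits[label].components
            warm.append((cp.a, cp.c, cp.e))
    if "ACE" in labels:
        fits["ACE"] = fit_model(data, "ACE", min_pairs=min_pairs,
                                extra_starts=warm)
    return {lab: fits[lab] for lab in labels if lab in fits}


# ---------------------------------------------------------------------------
# Comparison and selection


def compare_models(full: ModelFit, nested: ModelFit) -> ModelComparison:
    """Likelihood-ratio test of a nested against a full model.

    The statistic 2*(loglik_full - loglik_nested), clipped at zero, is
    referred to a chi-square with df equal to the parameter-count
    difference.  When the true parameter sits on the boundary of the
    parameter space (a variance of zero) this reference is conservative;
    it is used regardless, as is conventional in twin analyses.
    """
    if nested.model_label not in _NESTED_IN.get(full.model_label, set()):
        raise ValueError(
            f"{nested.model_label} is not nested in {full.model_label}")
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -1e-6:
        raise ValueError("nested model exceeds full-model likelihood")
    stat = max(stat, 0.0)
    df = full.k - nested.k
    return ModelComparison(full.model_label, nested.model_label, stat, df,
                           float(stats.chi2.sf(stat, df)))


def select_best_model(fits: Mapping[str, ModelFit], tie_tol: float = 1e-9
                      ) -> tuple[str, dict]:
    """Pick the converged fit with the lowest AIC.

    AIC ties (within ``tie_tol``) are broken toward fewer parameters, then
    by the fixed label order E < CE < AE < ACE.  The returned record holds
    per-model AICs and, when an ACE fit is present, the LRTs of each nested
    model against it.
    """
    converged = {lab: f for lab, f in fits.items() if f.converged}
    if not converged:
        raise ValueError("no converged fit to select from")
    min_aic = min(f.aic for f in converged.values())
    tied = [f for f in converged.values() if f.aic <= min_aic + tie_tol]
    tied.sort(key=lambda f: (f.k, _LABEL_ORDER[f.model_label]))
    best = tied[0]
    record = {
        "aic": {lab: f.aic for lab, f in fits.items()},
        "converged": {lab: f.converged for lab, f in fits.items()},
        "lrt_vs_ACE": {},
    }
    if "ACE" in converged:
        for lab, f in converged.items():
            if lab in _NESTED_IN["ACE"]:
                record["lrt_vs_ACE"][lab] = compare_models(converged["ACE"], f)
    return best.model_label, record


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals


def _fraction_loglik(suff: _Suff, mu, total, fa, fc, e_floor2):
    if total <= 0 or fa < 0 or fc < 0 or fa + fc > 1:
        return -math.inf
    va, vc = fa * total, fc * total
    ve = (1.0 - fa - fc) * total + e_floor2
    return _suff_loglik(suff, mu, va, vc, ve)


def _profile_loglik(suff: _Suff, label: str, comp: str, p: float,
                    mu0: float, v0: float, e_floor2: float) -> float:
    """Max log-likelihood with the standardized component fixed at p.

    Nuisance parameters are the mean, the log total variance and, for the
    three-component model, a logit split of the remaining variance mass
    between the two unconstrained components.
    """

    def _sigmoid(u):
        if u >= 0:
            return 1.0 / (1.0 + math.exp(-u))
        z = math.exp(u)
        return z / (1.0 + z)

    def fractions(theta):
        total = math.exp(min(theta[1], 700.0))
        if label == "ACE":
            t = _sigmoid(theta[2])
            rem = 1.0 - p
            if comp == "a2":
                fa, fc = p, t * rem
            elif comp == "c2":
                fa, fc = t * rem, p
            else:  # e2 fixed at p; split the rest between a and c
                fa, fc = t * rem, (1.0 - t) * rem
        elif label == "AE":
            fa, fc = (p, 0.0) if comp == "a2" else (1.0 - p, 0.0)
        elif label == "CE":
            fa, fc = (0.0, p) if comp == "c2" else (0.0, 1.0 - p)
        else:
            raise ValueError(label)
        return theta[0], total, fa, fc

    n_free = 2 + (label == "ACE")

    def nll(theta):
        mu, total, fa, fc = fractions(theta)
        ll = _fraction_loglik(suff, mu, total, fa, fc, e_floor2)
        return -ll if math.isfinite(ll) else 1e12

    x0 = [mu0, math.log(v0)] + ([0.0] if n_free == 3 else [])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9,
                                     "maxiter": 2000, "maxfev": 2000})
    return -res.fun


def component_ci(fit: ModelFit, data: TwinData, level: float = 0.95,
                 components: Iterable[str] = ("a2", "c2", "e2")
                 ) -> dict[str, tuple[float, float]]:
    """Profile-likelihood intervals for the standardized fractions.

    For each free component the interval is the set of fractions whose
    profile log-likelihood lies within chi2_1(level)/2 of the maximum,
    bounded to [0, 1].  Components fixed at zero by the model label get the
    degenerate interval (0, 0); the E-only model's e2 is identically 1.
    ``components`` restricts which intervals are profiled.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    components = list(components)
    label = fit.model_label
    if label == "E":
        return {c: {"a2": (0.0, 0.0), "c2": (0.0, 0.0),
                    "e2": (1.0, 1.0)}[c] for c in components}

    suff = _Suff.from_data(data)
    mu0, v0 = _sample_stats(data)
    e_floor2 = (E_FLOOR_FRACTION ** 2) * v0
    half_crit = 0.5 * stats.chi2.ppf(level, 1)

    free = {"a2", "e2"} if label == "AE" else {"c2", "e2"} if label == "CE" \
        else {"a2", "c2", "e2"}
    est = {"a2": fit.components.a2, "c2": fit.components.c2,
           "e2": fit.components.e2}

    out: dict[str, tuple[float, float]] = {}
    for comp in components:
        if comp not in free:
            out[comp] = (0.0, 0.0)
            continue
        p_hat = min(max(est[comp], 0.0), 1.0)

        def prof(p):
            return _profile_loglik(suff, label, comp, p, fit.mean,
                                   fit.components.total_variance, e_floor2)

        ll_max = max(fit.loglik, prof(p_hat))
        cut = ll_max - half_crit

        def g(p):
            val = prof(p) - cut
            return val if math.isfinite(val) else -1e12

        out[comp] = (_ci_bound(g, p_hat, 0.0), _ci_bound(g, p_hat, 1.0))
    return out


def _ci_bound(g, p_hat: float, boundary: float, xtol: float = 1e-5) -> float:
    """Root of g between p_hat and a [0,1] boundary; boundary if none."""
    if abs(p_hat - boundary) < xtol:
        return boundary
    gb = g(boundary)
    if gb >= 0.0:
        return boundary
    gh = g(p_hat)
    if gh < 0.0:  # profile maximum below cut: degenerate, stay at estimate
        return p_hat
    lo, hi = (boundary, p_hat) if boundary < p_hat else (p_hat, boundary)
    return float(optimize.brentq(g, lo, hi, xtol=xtol))
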