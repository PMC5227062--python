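"""Synthetic twin cohorts with known variance-component structure.

Generates rosters of monozygotic (MZ) and dizygotic (DZ) twin pairs plus
singletons, trait matrices whose latent values follow the classical ACE
decomposition (additive genetic A, shared environment C, unique environment
E), and longitudinal control tables for test-retest reproducibility.  Because
the true per-trait variance fractions are recorded in the trait metadata,
every downstream stage (QC, preprocessing, model fitting) can be validated
against ground truth.

The latent model for one trait in one family is

    z_i = a*A_i + c*C + e*E_i + beta_age * (age_i - age_mid)

where C is shared by co-twins, A is fully shared for MZ co-twins and
correlated 0.5 for DZ co-twins, and E is independent per subject.  With
a^2 + c^2 + e^2 = 1 the latent twin correlations are

    r_MZ = a^2 + c^2        r_DZ = 0.5*a^2 + c^2.

Latent values are mapped to observed scales by strictly monotone transforms:
cell-subset frequency (CSF) traits via a scaled logistic onto (0, 100) percent,
surface-protein expression level (SPEL) traits via an exponential onto
positive fluorescence intensities.  Monotonicity means the rank-based inverse
normal transform applied downstream recovers the latent correlation structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "TwinCohort",
    "TraitMatrix",
    "simulate_cohort",
    "simulate_traits",
    "simulate_longitudinal_controls",
    "simulate_dataset",
    "write_dataset",
    "load_config",
]

#: Immune-cell lineage labels used to tag simulated traits.  The last two are
#: the poorly characterised double-positive / double-negative T-cell lineages
#: that the default QC settings exclude.
DEFAULT_LINEAGES = (
    "CD4 T",
    "CD8 T",
    "Treg",
    "B2",
    "B1",
    "NK",
    "NKT",
    "gd T",
    "mDC",
    "pDC",
    "Monocyte",
    "CD4+CD8+ T",
    "CD4-CD8- T",
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic twin study.

    Defaults reproduce the shape of the cohort the package targets: 75 MZ
    pairs, 170 DZ pairs and 7 singletons (497 all-female subjects aged
    41-77, MZ on average 2 years older than DZ), and 29 longitudinal
    controls sampled twice at least 6 months apart, 14 of them with a
    replicate vial.

    ``a2``, ``c2``, ``e2`` may each be a scalar (applied to every trait) or a
    per-trait sequence.  If all three are ``None`` the generator draws
    per-trait fractions from a three-class mixture (AE-like, CE-like,
    ACE-like traits) emulating the heterogeneous composition of a real
    immunophenotype panel.
    """

    n_mz_pairs: int = 75
    n_dz_pairs: int = 170
    n_singletons: int = 7
    age_range: tuple[float, float] = (41.0, 77.0)
    mz_age_offset: float = 2.0
    n_traits: int = 40
    a2: float | Sequence[float] | None = None
    c2: float | Sequence[float] | None = None
    e2: float | Sequence[float] | None = None
    age_effect_slope: float = 0.01
    trait_kind_mix: float = 0.983  # fraction of traits that are CSF
    csf_logit_location: float = -2.0
    csf_logit_scale: float = 1.0
    spel_log_location: float = 6.0
    spel_log_scale: float = 0.5
    n_controls: int = 29
    n_replicated_controls: int = 14
    measurement_error_sd: float = 1.0 / 3.0
    missing_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_singletons", "n_traits",
                     "n_controls", "n_replicated_controls"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range low must be < high")
        if self.mz_age_offset < 0 or self.mz_age_offset >= hi - lo:
            raise ConfigurationError("mz_age_offset must lie in [0, age span)")
        if self.n_replicated_controls > self.n_controls:
            raise ConfigurationError(
                "n_replicated_controls cannot exceed n_controls")
        if not 0.0 <= self.trait_kind_mix <= 1.0:
            raise ConfigurationError("trait_kind_mix must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.measurement_error_sd < 0:
            raise ConfigurationError("measurement_error_sd must be >= 0")
        given = [f for f in (self.a2, self.c2, self.e2) if f is not None]
        if given and len(given) != 3:
            raise ConfigurationError(
                "a2, c2, e2 must be given together or all left unset")

    def resolve_fractions(self, rng: np.random.Generator) -> np.ndarray:
        """Per-trait (a2, c2, e2) array of shape (n_traits, 3)."""
        if self.a2 is None:
            return _mixture_fractions(self.n_traits, rng)
        fr = np.column_stack([
            np.broadcast_to(np.asarray(f, dtype=float), self.n_traits)
            for f in (self.a2, self.c2, self.e2)
        ])
        if np.any(fr < 0) or np.any(fr > 1):
            raise ConfigurationError("variance fractions must be in [0, 1]")
        if np.any(np.abs(fr.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigurationError("a2 + c2 + e2 must equal 1 per trait")
        return fr


def _mixture_fractions(n_traits: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-trait variance fractions from an AE/CE/ACE class mixture.

    Class weights and component centres follow the composition a large twin
    immunophenotyping panel typically shows: a majority of AE-like traits
    with moderate-to-high heritability, a minority dominated by shared
    environment, and a smaller group with both influences.
    """
    classes = rng.choice(3, size=n_traits, p=(0.54, 0.24, 0.22))
    a2 = np.zeros(n_traits)
    c2 = np.zeros(n_traits)
    is_ae = classes == 0
    is_ce = classes == 1
    is_ace = classes == 2
    a2[is_ae] = np.clip(rng.normal(0.62, 0.12, is_ae.sum()), 0.2, 0.9)
    c2[is_ce] = np.clip(rng.normal(0.43, 0.12, is_ce.sum()), 0.1, 0.8)
    a2[is_ace] = np.clip(rng.normal(0.40, 0.08, is_ace.sum()), 0.1, 0.7)
    c2[is_ace] = np.clip(rng.normal(0.25, 0.08, is_ace.sum()), 0.05, 0.6)
    # keep at least 5% unique-environment variance
    over = a2 + c2 > 0.95
    scale = np.where(over, 0.95 / (a2 + c2 + 1e-300), 1.0)
    a2 *= scale
    c2 *= scale
    e2 = 1.0 - a2 - c2
    return np.column_stack([a2, c2, e2])


@dataclass
class TwinCohort:
    """Subject roster: one row per subject.

    ``subjects`` has columns subject_id, family_id, zygosity (MZ, DZ or
    singleton), age (years) and sex.
    """

    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "family_id", "zygosity", "age", "sex"}
        missing = required - set(self.subjects.columns)
        if missing:
            raise ValueError(f"cohort roster missing columns: {sorted(missing)}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def families(self, zygosity: str) -> list[tuple[str, ...]]:
        """Subject-id tuples per family of the requested zygosity.

        Cached per zygosity; the roster is treated as immutable after
        construction.
        """
        cache = self.__dict__.setdefault("_family_cache", {})
        if zygosity not in cache:
            sub = self.subjects[self.subjects["zygosity"] == zygosity]
            cache[zygosity] = [tuple(g["subject_id"])
                               for _, g in sub.groupby("family_id", sort=True)]
        return cache[zygosity]

    def validate(self) -> None:
        counts = self.subjects.groupby("family_id")["subject_id"].count()
        zyg = self.subjects.groupby("family_id")["zygosity"].nunique()
        if (zyg > 1).any():
            raise ValueError("zygosity must be constant within a family")
        fam_zyg = self.subjects.groupby("family_id")["zygosity"].first()
        bad_twin = counts[(fam_zyg != "singleton") & (counts != 2)]
        bad_single = counts[(fam_zyg == "singleton") & (counts != 1)]
        if len(bad_twin) or len(bad_single):
            raise ValueError("family sizes inconsistent with zygosity")


@dataclass
class TraitMatrix:
    """Subjects x traits observed values with per-trait metadata.

    ``values``: DataFrame indexed by subject_id, one column per trait_id;
    missing measurements are NaN.  ``trait_meta``: DataFrame indexed by
    trait_id with columns kind (CSF or SPEL), lineage_label and, for
    simulated data, the true variance fractions true_a2/true_c2/true_e2.
    """

    values: pd.DataFrame
    trait_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.trait_meta.index):
            raise ValueError("trait_meta index must match value columns")

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def select(self, trait_ids: Sequence[str]) -> "TraitMatrix":
        ids = list(trait_ids)
        return TraitMatrix(self.values[ids], self.trait_meta.loc[ids])


def simulate_cohort(config: SimulationConfig) -> TwinCohort:
    """Build a twin roster matching the configured counts.

    DZ ages are uniform on [low, high - offset] and MZ ages uniform on
    [low + offset, high], so both lie inside ``age_range`` and the MZ-DZ
    mean age difference equals ``mz_age_offset`` in expectation.
    """
    rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.age_range
    rows = []
    for i in range(config.n_mz_pairs):
        fam = f"MZ{i + 1:04d}"
        age = rng.uniform(lo + config.mz_age_offset, hi)
        for j in (1, 2):
            rows.append((f"{fam}.{j}", fam, "MZ", age, "F"))
    for i in range(config.n_dz_pairs):
        fam = f"DZ{i + 1:04d}"
        age = rng.uniform(lo, hi - config.mz_age_offset)
        for j in (1, 2):
            rows.append((f"{fam}.{j}", fam, "DZ", age, "F"))
    for i in range(config.n_singletons):
        fam = f"SG{i + 1:04d}"
        rows.append((f"{fam}.1", fam, "singleton", rng.uniform(lo, hi), "F"))
    roster = pd.DataFrame(
        rows, columns=["subject_id", "family_id", "zygosity", "age", "sex"])
    cohort = TwinCohort(roster)
    cohort.validate()
    return cohort


def _latent_values(cohort: TwinCohort, fractions: np.ndarray,
                   age_slope: float, age_mid: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Latent standardized trait values, subjects x traits.

    A components: MZ co-twins share one draw; DZ co-twins each get
    sqrt(1/2)*family + sqrt(1/2)*individual, giving correlation 0.5 at unit
    variance.  C is shared per family, E independent.  Singletons use the
    same generative path with the co-twin discarded.
    """
    roster = cohort.subjects
    n_sub = len(roster)
    n_traits = fractions.shape[0]
    fam_codes, fam_index = pd.factorize(roster["family_id"], sort=True)
    n_fam = len(fam_index)

    a_fam = rng.standard_normal((n_fam, n_traits))
    c_fam = rng.standard_normal((n_fam, n_traits))
    a_ind = rng.standard_normal((n_sub, n_traits))
    e_ind = rng.standard_normal((n_sub, n_traits))

    is_dz = (roster["zygosity"] == "DZ").to_numpy()[:, None]
    # MZ and singletons take the family A draw wholesale; DZ mix half-half.
    a_part = np.where(is_dz,
                      np.sqrt(0.5) * a_fam[fam_codes] + np.sqrt(0.5) * a_ind,
                      a_fam[fam_codes])
    a, c, e = (np.sqrt(fractions[:, k])[None, :] for k in range(3))
    latent = a * a_part + c * c_fam[fam_codes] + e * e_ind
    latent += age_slope * (roster["age"].to_numpy()[:, None] - age_mid)
    return latent


def _to_observed(latent: np.ndarray, kinds: np.ndarray,
                 config: SimulationConfig) -> np.ndarray:
    """Map latent values through monotone kind-specific transforms."""
    obs = np.empty_like(latent)
    csf = kinds == "CSF"
    z = latent[:, csf]
    pct = 100.0 / (
        1.0 + np.exp(-(config.csf_logit_location + config.csf_logit_scale * z)))
    # float saturation at extreme latents would land exactly on the open
    # (0, 100) bounds; clamp one ulp inside
    obs[:, csf] = np.clip(pct, 1e-300, np.nextafter(100.0, 0.0))
    z = latent[:, ~csf]
    obs[:, ~csf] = np.exp(config.spel_log_location + config.spel_log_scale * z)
    return obs


def simulate_traits(cohort: TwinCohort, config: SimulationConfig) -> TraitMatrix:
    """Simulate the observed trait matrix for an existing cohort.

    The rng stream is derived from ``rng_seed`` but offset so that trait
    draws do not recycle the roster draws.
    """
    if cohort.n_subjects == 0:
        raise ConfigurationError("cohort is empty")
    rng = np.random.default_rng((config.rng_seed, 1))
    fractions = config.resolve_fractions(rng)
    n_csf = int(round(config.trait_kind_mix * config.n_traits))
    kinds = np.array(["CSF"] * n_csf + ["SPEL"] * (config.n_traits - n_csf))
    lineages = rng.choice(DEFAULT_LINEAGES, size=config.n_traits,
                          p=_lineage_weights())
    age_mid = float(np.mean(config.age_range))
    latent = _latent_values(cohort, fractions, config.age_effect_slope,
                            age_mid, rng)
    obs = _to_observed(latent, kinds, config)
    if config.missing_rate > 0:
        obs[rng.random(obs.shape) < config.missing_rate] = np.nan
    trait_ids = [f"T{i + 1:05d}" for i in range(config.n_traits)]
    values = pd.DataFrame(obs, index=pd.Index(cohort.subjects["subject_id"],
                                              name="subject_id"),
                          columns=trait_ids)
    meta = pd.DataFrame(
        {
            "kind": kinds,
            "lineage_label": lineages,
            "true_a2": fractions[:, 0],
            "true_c2": fractions[:, 1],
            "true_e2": fractions[:, 2],
        },
        index=pd.Index(trait_ids, name="trait_id"),
    )
    return TraitMatrix(values, meta)


def _lineage_weights() -> np.ndarray:
    """Lineage sampling weights; the excluded DP/DN lineages stay rare."""
    w = np.ones(len(DEFAULT_LINEAGES))
    w[-2:] = 0.25
    return w / w.sum()


def simulate_longitudinal_controls(config: SimulationConfig,
                                   trait_meta: pd.DataFrame) -> pd.DataFrame:
    """Two-timepoint control table with optional replicate vials.

    Each control's trait value has a stable subject component s ~ N(0, 1);
    the vial analysed at time point t observes s + measurement error, and a
    replicate vial of time point 1 observes the time-point value plus its own
    independent error.  The expected test-retest correlation is therefore
    1 / (1 + measurement_error_sd^2).  Values are mapped through the same
    monotone kind transforms as the twin traits.
    """
    rng = np.random.default_rng((config.rng_seed, 2))
    n_traits = len(trait_meta)
    kinds = trait_meta["kind"].to_numpy()
    sd = config.measurement_error_sd

    stable = rng.standard_normal((config.n_controls, n_traits))
    rows, labels = [], []
    tp_values = {}
    for tp in (1, 2):
        latent = stable + sd * rng.standard_normal(stable.shape)
        tp_values[tp] = latent
        for i in range(config.n_controls):
            labels.append((f"C{i + 1:03d}", tp, 0))
            rows.append(latent[i])
    rep_latent = tp_values[1] + sd * rng.standard_normal(stable.shape)
    for i in range(config.n_replicated_controls):
        labels.append((f"C{i + 1:03d}", 1, 1))
        rows.append(rep_latent[i])

    obs = _to_observed(np.asarray(rows), kinds, config)
    table = pd.DataFrame(obs, columns=trait_meta.index)
    info = pd.DataFrame(labels, columns=["control_id", "timepoint", "replicate"])
    return pd.concat([info, table], axis=1)


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[TwinCohort, TraitMatrix, pd.DataFrame]:
    """Cohort, trait matrix and longitudinal table from a single config."""
    cohort = simulate_cohort(config)
    traits = simulate_traits(cohort, config)
    longitudinal = simulate_longitudinal_controls(config, traits.trait_meta)
    return cohort, traits, longitudinal


# ---------------------------------------------------------------------------
# Serialization

_FLOAT_FMT = "%.10g"


def write_dataset(cohort: TwinCohort, traits: TraitMatrix,
                  longitudinal: pd.DataFrame, out_dir) -> dict[str, str]:
    """Write the four standard TSVs; returns a name -> path map."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.tsv",
        "traits": out / "traits.tsv",
        "trait_meta": out / "trait_meta.tsv",
        "longitudinal": out / "longitudinal.tsv",
    }
    cohort.subjects.to_csv(paths["cohort"], sep="\t", index=False,
                           float_format=_FLOAT_FMT)
    traits.values.to_csv(paths["traits"], sep="\t", float_format=_FLOAT_FMT)
    traits.trait_meta.to_csv(paths["trait_meta"], sep="\t",
                             float_format=_FLOAT_FMT)
    longitudinal.to_csv(paths["longitudinal"], sep="\t", index=False,
                        float_format=_FLOAT_FMT)
    return {k: str(v) for k, v in paths.items()}


def read_cohort(path) -> TwinCohort:
    return TwinCohort(pd.read_csv(path, sep="\t"))


def read_traits(values_path, meta_path) -> TraitMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="subject_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="trait_id")
    return TraitMatrix(values, meta)


def read_longitudinal(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "age_range" in raw:
        raw["age_range"] = tuple(raw["age_range"])
    return SimulationConfig(**raw)
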