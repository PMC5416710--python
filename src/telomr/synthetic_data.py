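"""Synthetic multi-cohort generator for telomere-length MR analyses.

Individual-level data are drawn from a linear-Gaussian structural model with
a single standard-normal confounder U (the classic instrumental-variable
triangle: genotype G -> telomere length TL -> cognitive trait, with U acting
on both TL and trait):

    TL_std  = sum_j beta_j (G_j - 2 p_j) + gamma_U * U
              + age_slope * (age - age_mean) + eps_TL
    tl_raw  = tl_scale_mu + tl_scale_sigma * Z(TL_std)   (floored at 0.01)
    trait_t = theta_t* Z(TL_std) + lambda_U * U + age/sex effects
              + APOE-e4 shift + eps_t

where Z() standardizes within the simulated cohort, G_j are Hardy-Weinberg
genotype dosages, and theta_t* equals theta_t multiplied by an optional
APOE-e4 modifier in e4 carriers. Raw T/S-ratio location and spread are
cohort-specific, emulating lab-to-lab scaling differences; standardization
downstream absorbs them.

All randomness flows from one master seed plus per-cohort integer offsets,
so identical configurations reproduce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .published import TRAITS, cohort_table

__all__ = [
    "SNPDef", "TrueParams", "CohortConfig", "Cohort", "SummaryStatRow",
    "DEFAULT_SNPS", "default_true_params", "default_cohort_configs",
    "simulate_genotypes", "simulate_cohort", "simulate_multi_cohort",
    "simulate_two_sample_summary",
]

APOE_GENOTYPES = ("e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4")
TS_FLOOR = 0.01  # raw T/S is a ratio of positive quantities


@dataclass(frozen=True)
class SNPDef:
    """One telomere-length instrument locus.

    ``effect_allele`` is the counted, telomere-SHORTENING allele, so
    ``beta_tl`` (s.d.-change of TL per allele) is negative.
    """

    rsid: str
    gene_label: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta_tl: float

    def __post_init__(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.rsid}: eaf must be in (0, 1), got {self.eaf}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")


# The seven loci of the unweighted TL risk score. Allele frequencies and
# per-allele effects are generator defaults chosen so that the score mean
# (sum 2*eaf = 8.55) and s.d. (~1.50) and the pooled standardized GRS-TL
# slope (~ -0.05 s.d./allele) match the magnitudes the consortium reports;
# true per-SNP values live in the underlying TL GWAS and are not asserted.
DEFAULT_SNPS: tuple[SNPDef, ...] = (
    SNPDef("rs10936599", "TERC", "T", "C", 0.960, -0.05),
    SNPDef("rs2736100", "TERT", "C", "A", 0.440, -0.05),
    SNPDef("rs7675998", "NAF1", "A", "G", 0.800, -0.05),
    SNPDef("rs9420907", "OBFC1", "A", "C", 0.900, -0.05),
    SNPDef("rs8105767", "ZNF208", "A", "G", 0.680, -0.05),
    SNPDef("rs755017", "RTEL1", "G", "A", 0.280, -0.05),
    SNPDef("rs11125529", "ACYP2", "C", "A", 0.215, -0.05),
)


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth structural parameters shared by all simulated cohorts."""

    theta: Mapping[str, float]
    gamma_u_tl: float = 0.5
    lambda_u_trait: float = 0.5
    age_tl_slope: float = -0.02
    trait_age_effects: Mapping[str, float] = field(default_factory=dict)
    trait_sex_effects: Mapping[str, float] = field(default_factory=dict)
    apoe_freqs: tuple[float, float, float] = (0.08, 0.77, 0.15)
    apoe_trait_shift: Mapping[str, float] = field(default_factory=dict)
    apoe_theta_modifier: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.apoe_freqs) - 1.0) > 1e-12:
            raise ValueError("apoe_freqs must sum to 1")
        if any(f < 0 for f in self.apoe_freqs):
            raise ValueError("apoe_freqs must be non-negative")
        for m, what in ((self.trait_age_effects, "trait_age_effects"),
                        (self.trait_sex_effects, "trait_sex_effects"),
                        (self.apoe_trait_shift, "apoe_trait_shift"),
                        (self.apoe_theta_modifier, "apoe_theta_modifier")):
            missing = set(self.theta) - set(m)
            if missing:
                raise ValueError(f"{what} missing traits: {sorted(missing)}")


def default_true_params(theta: Mapping[str, float] | None = None,
                        **overrides) -> TrueParams:
    """Defaults: a confounded global null (theta = 0 for every trait).

    Age erodes both TL (-0.02 s.d./year) and cognition (-0.02 s.d./year,
    except the adolescent-stable MMSE-style ceiling is ignored); e4 carriers
    score 0.1 s.d. lower on every trait.
    """
    theta = dict.fromkeys(TRAITS, 0.0) if theta is None else dict(theta)
    base = dict(
        theta=theta,
        trait_age_effects=dict.fromkeys(theta, -0.02),
        trait_sex_effects=dict.fromkeys(theta, 0.05),
        apoe_trait_shift=dict.fromkeys(theta, -0.10),
        apoe_theta_modifier=dict.fromkeys(theta, 1.0),
    )
    base.update(overrides)
    return TrueParams(**base)


@dataclass(frozen=True)
class CohortConfig:
    """One study's size, demography, lab TL scale and trait panel."""

    name: str
    n: int
    age_mean: float = 60.0
    age_sd: float = 10.0
    prop_female: float = 0.5
    tl_scale_mu: float = 1.0
    tl_scale_sigma: float = 0.3
    tl_noise_sd: float = 1.0
    trait_noise_sd: Mapping[str, float] = field(default_factory=dict)
    traits_available: tuple[str, ...] = TRAITS
    has_apoe: bool = True
    seed_offset: int = 0
    missing_rate: float = 0.0
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.name}: n must be >= 2")
        if self.tl_scale_sigma <= 0:
            raise ValueError(f"{self.name}: tl_scale_sigma must be > 0")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError(f"{self.name}: prop_female must be in [0, 1]")
        unknown = set(self.traits_available) - set(TRAITS)
        if unknown:
            raise ValueError(f"{self.name}: unknown traits {sorted(unknown)}")

    def noise_sd(self, trait: str) -> float:
        return float(self.trait_noise_sd.get(trait, 1.0))


@dataclass
class Cohort:
    """A named per-individual table (dosages, tl_raw, traits, demography)."""

    name: str
    data: pd.DataFrame
    covariates: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class SummaryStatRow:
    """One SNP's GWAS summary statistics."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: se must be > 0")
        if self.n < 1:
            raise ValueError(f"{self.rsid}: n must be >= 1")


def default_cohort_configs(scale: float = 1.0) -> list[CohortConfig]:
    """Cohort configurations mirroring the published per-study table.

    ``scale`` < 1 shrinks every cohort proportionally (minimum 50 rows)
    for fast replicated simulations.
    """
    configs = []
    for i, row in cohort_table().iterrows():
        configs.append(CohortConfig(
            name=row["cohort"],
            n=max(50, int(round(row["n"] * scale))),
            age_mean=row["age_mean"],
            age_sd=row["age_sd"],
            prop_female=row["pct_women"] / 100.0,
            tl_scale_mu=row["tl_mean"],
            tl_scale_sigma=row["tl_sd"],
            traits_available=tuple(row["traits"]),
            has_apoe=bool(row["has_apoe"]),
            seed_offset=1000 * int(i),
        ))
    return configs


def simulate_genotypes(n: int, snps: Sequence[SNPDef],
                       seed: int) -> np.ndarray:
    """Draw an n x k Hardy-Weinberg dosage matrix (entries in {0, 1, 2})."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not snps:
        raise ValueError("empty SNP list")
    rng = np.random.default_rng(seed)
    return _draw_genotypes(rng, n, snps)


def _draw_genotypes(rng: np.random.Generator, n: int,
                    snps: Sequence[SNPDef]) -> np.ndarray:
    eaf = np.array([s.eaf for s in snps])
    # two independent Bernoulli(eaf) gametes per individual
    return (rng.random((n, len(snps))) < eaf).astype(float) + \
           (rng.random((n, len(snps))) < eaf).astype(float)


def _draw_apoe(rng: np.random.Generator, n: int,
               freqs: Sequence[float]) -> np.ndarray:
    alleles = np.array(["e2", "e3", "e4"])
    a1 = rng.choice(3, size=n, p=freqs)
    a2 = rng.choice(3, size=n, p=freqs)
    lo, hi = np.minimum(a1, a2), np.maximum(a1, a2)
    return np.char.add(np.char.add(alleles[lo], "/"), alleles[hi])


def simulate_cohort(config: CohortConfig, snps: Sequence[SNPDef],
                    truth: TrueParams, seed: int) -> Cohort:
    """Simulate one cohort under the structural model.

    The RNG stream is ``default_rng(seed + config.seed_offset)``; cohorts in
    a multi-cohort run are therefore independent and individually
    reproducible.
    """
    for t in config.traits_available:
        if t not in truth.theta:
            raise ValueError(f"trait {t!r} not covered by truth.theta")
    rng = np.random.default_rng(seed + config.seed_offset)
    n = config.n
    eaf = np.array([s.eaf for s in snps])
    beta = np.array([s.beta_tl for s in snps])

    g = _draw_genotypes(rng, n, snps)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 0.0, None)
    female = rng.random(n) < config.prop_female
    u = rng.normal(0.0, 1.0, n)
    eps_tl = rng.normal(0.0, config.tl_noise_sd, n)

    tl_std = ((g - 2 * eaf) @ beta + truth.gamma_u_tl * u
              + truth.age_tl_slope * (age - config.age_mean) + eps_tl)
    sd = tl_std.std(ddof=1)
    z_tl = (tl_std - tl_std.mean()) / sd if sd > 0 else np.zeros(n)
    # lab scale applied to the standardized latent TL so the raw T/S mean
    # and s.d. reproduce the configured cohort values exactly
    tl_raw = np.maximum(config.tl_scale_mu + config.tl_scale_sigma * z_tl,
                        TS_FLOOR)

    if config.has_apoe:
        apoe = _draw_apoe(rng, n, truth.apoe_freqs)
        carrier = np.isin(apoe, ("e3/e4", "e4/e4")).astype(float)
    else:
        apoe = np.full(n, np.nan, dtype=object)
        carrier = np.zeros(n)

    cols: dict[str, object] = {
        "id": [f"{config.name}_{i:05d}" for i in range(n)],
    }
    for j, s in enumerate(snps):
        cols[s.rsid] = g[:, j]
    cols["tl_raw"] = tl_raw
    cols["age"] = age
    cols["sex"] = np.where(female, "female", "male")
    cols["apoe"] = apoe

    for t in config.traits_available:
        theta_star = truth.theta[t] * np.where(
            carrier > 0, truth.apoe_theta_modifier.get(t, 1.0), 1.0)
        y = (theta_star * z_tl
             + truth.lambda_u_trait * u
             + truth.trait_age_effects.get(t, 0.0) * (age - config.age_mean)
             + truth.trait_sex_effects.get(t, 0.0) * female
             + truth.apoe_trait_shift.get(t, 0.0) * carrier
             + rng.normal(0.0, config.noise_sd(t), n))
        if config.missing_rate > 0:
            y = np.where(rng.random(n) < config.missing_rate, np.nan, y)
        cols[t] = y

    return Cohort(config.name, pd.DataFrame(cols), config.covariates)


def simulate_multi_cohort(configs: Sequence[CohortConfig],
                          snps: Sequence[SNPDef], truth: TrueParams,
                          seed: int) -> list[Cohort]:
    """Simulate every configured cohort from one master seed."""
    if not configs:
        raise ValueError("at least one cohort config required")
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cohort names")
    offsets = [c.seed_offset for c in configs]
    if len(set(offsets)) != len(offsets):
        # distinct streams even if the caller left offsets at 0
        configs = [replace(c, seed_offset=c.seed_offset + 1000 * i)
                   for i, c in enumerate(configs)]
    return [simulate_cohort(c, snps, truth, seed) for c in configs]


def simulate_two_sample_summary(
    snps: Sequence[SNPDef], truth: TrueParams, n_x: int, n_y: int,
    seed: int, trait: str = "GENERAL", exact: bool = False,
) -> tuple[list[SummaryStatRow], list[SummaryStatRow]]:
    """Per-SNP GWAS summary rows for exposure (TL) and outcome (trait).

    The true outcome effect of SNP j is ``theta_trait * beta_tl_j`` (no
    pleiotropy). Sampling SEs follow the GWAS approximation
    ``1 / sqrt(2 p (1-p) n)`` for a standardized phenotype; with
    ``exact=True`` the point estimates equal the population values (the
    infinite-sample limit) while the SEs keep their finite-n scale.
    """
    if n_x < 10 or n_y < 10:
        raise ValueError("n_x and n_y must both be >= 10")
    if trait not in truth.theta:
        raise ValueError(f"trait {trait!r} not covered by truth.theta")
    rng = np.random.default_rng(seed)
    theta = truth.theta[trait]
    exposure, outcome = [], []
    for s in snps:
        het = 2 * s.eaf * (1 - s.eaf)
        if het <= 0:
            raise ValueError(f"{s.rsid}: degenerate allele frequency")
        se_x = 1.0 / np.sqrt(het * n_x)
        se_y = 1.0 / np.sqrt(het * n_y)
        bx = s.beta_tl if exact else rng.normal(s.beta_tl, se_x)
        by = theta * s.beta_tl if exact else rng.normal(theta * s.beta_tl, se_y)
        exposure.append(SummaryStatRow(s.rsid, s.effect_allele, s.other_allele,
                                       s.eaf, float(bx), float(se_x), n_x))
        outcome.append(SummaryStatRow(s.rsid, s.effect_allele, s.other_allele,
                                      s.eaf, float(by), float(se_y), n_y))
    return exposure, outcome
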