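"""Causal (instrumental-variable) estimation for telomere length.

One-sample analysis: the Wald ratio divides the pooled GRS-trait effect by
the pooled GRS-TL effect, giving the causal effect of one s.d. of TL on the
standardized trait; its standard error comes from the first-order delta
method. Instrument strength is summarized by F = (beta/se)^2 of the first
stage. The observed-vs-causal contrast is a Z-test that treats the two
estimates as independent.

Two-sample analysis: per-SNP exposure and outcome GWAS effects are combined
by the inverse-variance-weighted (IVW) ratio estimator
``sum(x y / s_y^2) / sum(x^2 / s_y^2)``, with a Z-score-only mode for
outcome GWAS that publish test statistics but no effect sizes. A per-SNP
ratio scan with a heterogeneity Q serves as a generic pleiotropy
diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grs import align_alleles
from .synthetic_data import SNPDef, SummaryStatRow

__all__ = ["MRResult", "TwoSampleInput", "WeakInstrumentError", "ci_to_se",
           "wald_iv", "f_statistic", "difference_test", "two_sample_ivw",
           "per_snp_ratio_scan", "harmonize_summary_stats"]

Z95 = 1.959963984540054


class WeakInstrumentError(ValueError):
    """Instrument-exposure association too weak for a stable Wald ratio."""


@dataclass(frozen=True)
class MRResult:
    """A causal estimate with instrument and difference-test diagnostics."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    mode: str  # one_sample_wald | two_sample_ivw | two_sample_zscore
    f_stat: float = math.nan
    diff_z: float = math.nan
    diff_p: float = math.nan
    trait: str = ""
    stratum: str = "all"
    n: int = 0

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class TwoSampleInput:
    """Per-SNP harmonized exposure (x) and outcome (y) effects with SEs."""

    x: np.ndarray
    sx: np.ndarray
    y: np.ndarray
    sy: np.ndarray
    rsids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.x, self.sx, self.y, self.sy)]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1 or lengths == {0}:
            raise ValueError("x, sx, y, sy must share a common length >= 1")
        if np.any(arrays[1] <= 0) or np.any(arrays[3] <= 0):
            raise ValueError("all standard errors must be > 0")
        object.__setattr__(self, "x", arrays[0])
        object.__setattr__(self, "sx", arrays[1])
        object.__setattr__(self, "y", arrays[2])
        object.__setattr__(self, "sy", arrays[3])

    def __len__(self) -> int:
        return len(self.x)


def ci_to_se(lower: float, upper: float, level: float = 0.95,
             exact_196: bool = False) -> float:
    """Recover a standard error from a symmetric normal confidence interval.

    ``exact_196=True`` divides the width by 2 x 1.96 instead of the exact
    normal quantile, reproducing the rounding convention of printed tables.
    """
    if upper <= lower:
        raise ValueError("upper must exceed lower")
    mult = 1.96 if exact_196 else stats.norm.ppf(0.5 + level / 2)
    return (upper - lower) / (2 * mult)


def f_statistic(beta: float, se: float) -> float:
    """Single-coefficient first-stage F: the squared Wald Z, (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def wald_iv(grs_trait, grs_tl, weak_z: float = 2.0) -> MRResult:
    """Wald-ratio causal estimate: (GRS-trait) / (GRS-TL).

    Inputs are any objects with ``beta`` and ``se`` attributes (pooled
    estimates or meta-results). The SE is first-order delta method:
    sqrt(se_GY^2/b_GX^2 + b_GY^2 se_GX^2 / b_GX^4). Ratios on instruments
    with first-stage |Z| below ``weak_z`` are refused.
    """
    b_gx, se_gx = float(grs_tl.beta), float(grs_tl.se)
    b_gy, se_gy = float(grs_trait.beta), float(grs_trait.se)
    if se_gx < 0 or se_gy <= 0:
        raise ValueError("standard errors must be positive")
    f = f_statistic(b_gx, se_gx) if se_gx > 0 else math.inf
    if b_gx == 0 or math.sqrt(f) < weak_z:
        raise WeakInstrumentError(
            f"instrument too weak: first-stage F = {f:.2f} "
            f"(|Z| < {weak_z:g})")
    beta = b_gy / b_gx
    se = math.sqrt(se_gy**2 / b_gx**2 + b_gy**2 * se_gx**2 / b_gx**4)
    return MRResult(
        beta=beta, se=se, ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        p=float(2 * stats.norm.sf(abs(beta / se))),
        mode="one_sample_wald", f_stat=f,
        trait=getattr(grs_trait, "trait", ""),
        stratum=getattr(grs_trait, "stratum", "all"),
        n=int(getattr(grs_trait, "n", 0)),
    )


def difference_test(observed, causal) -> tuple[float, float]:
    """Z-test of observational minus causal effect, assuming independence.

    Returns (z, two-sided p). Both arguments need ``beta`` and ``se``
    attributes.
    """
    se_o, se_c = float(observed.se), float(causal.se)
    if se_o <= 0 or se_c <= 0:
        raise ValueError("standard errors must be > 0")
    z = (float(observed.beta) - float(causal.beta)) / math.hypot(se_o, se_c)
    return z, float(2 * stats.norm.sf(abs(z)))


def two_sample_ivw(data: TwoSampleInput, zscore_only: bool = False,
                   trait: str = "", n: int = 0) -> MRResult:
    """Inverse-variance-weighted two-sample causal estimate.

    beta = sum(x_j y_j / s_yj^2) / sum(x_j^2 / s_yj^2), the precision-
    weighted combination of per-SNP Wald ratios; se = denominator^-1/2.
    With ``zscore_only=True`` the outcome betas are taken as being on an
    unknown scale and only the standardized statistic Z = beta/se is
    meaningful; beta and CI are reported as NaN.
    """
    if np.all(data.x == 0):
        raise ValueError("all exposure effects are zero")
    w = 1.0 / data.sy**2
    denom = float(np.sum(data.x**2 * w))
    beta = float(np.sum(data.x * data.y * w)) / denom
    se = 1.0 / math.sqrt(denom)
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    if zscore_only:
        return MRResult(beta=z, se=1.0, ci_low=math.nan, ci_high=math.nan,
                        p=p, mode="two_sample_zscore", trait=trait, n=n)
    return MRResult(beta=beta, se=se, ci_low=beta - Z95 * se,
                    ci_high=beta + Z95 * se, p=p, mode="two_sample_ivw",
                    trait=trait, n=n)


def per_snp_ratio_scan(data: TwoSampleInput) -> pd.DataFrame:
    """Per-SNP Wald ratios with delta-method SEs and a heterogeneity Q.

    A generic pleiotropy diagnostic: under a shared causal effect and no
    direct SNP-outcome paths the per-SNP ratios scatter around the IVW
    estimate with Q ~ chi2(k_used - 1). SNPs with a zero exposure effect
    are flagged and skipped.
    """
    if len(data) < 2:
        raise ValueError("ratio scan requires >= 2 SNPs")
    rsids = data.rsids or tuple(f"snp_{j}" for j in range(len(data)))
    ivw = two_sample_ivw(data)
    rows = []
    for j in range(len(data)):
        x, sx, y, sy = data.x[j], data.sx[j], data.y[j], data.sy[j]
        if x == 0:
            warnings.warn(f"{rsids[j]}: zero exposure effect, skipped")
            rows.append((rsids[j], math.nan, math.nan, math.nan, True))
            continue
        ratio = y / x
        se = math.sqrt(sy**2 / x**2 + y**2 * sx**2 / x**4)
        q_j = ((ratio - ivw.beta) / se) ** 2
        rows.append((rsids[j], ratio, se, q_j, False))
    table = pd.DataFrame(rows, columns=["rsid", "ratio", "se",
                                        "q_contribution", "skipped"])
    used = table[~table["skipped"]]
    q = float(used["q_contribution"].sum())
    df = len(used) - 1
    table.attrs["q"] = q
    table.attrs["q_df"] = df
    table.attrs["q_p"] = float(stats.chi2.sf(q, df)) if df > 0 else math.nan
    table.attrs["ivw_beta"] = ivw.beta
    return table


def harmonize_summary_stats(exposure: Sequence[SummaryStatRow],
                            outcome: Sequence[SummaryStatRow],
                            reference: Sequence[SNPDef]) -> TwoSampleInput:
    """Align two summary-statistic sets to the reference counted alleles.

    A swapped or strand-flipped orientation negates the effect size (a
    beta per effect allele becomes a beta per the other allele). SNPs
    absent from either set are dropped.
    """
    exp = {r.rsid: r for r in exposure}
    out = {r.rsid: r for r in outcome}
    xs, sxs, ys, sys_, rsids = [], [], [], [], []
    for snp in reference:
        if snp.rsid not in exp or snp.rsid not in out:
            continue
        row_pair = []
        for row in (exp[snp.rsid], out[snp.rsid]):
            # orienting the "dosage" 1 tells us whether the beta flips sign
            oriented, action = align_alleles(
                np.array([1.0]), row.effect_allele, row.other_allele,
                snp, eaf=row.eaf)
            row_pair.append(row.beta if action == "as-is" else -row.beta)
        xs.append(row_pair[0]); sxs.append(exp[snp.rsid].se)
        ys.append(row_pair[1]); sys_.append(out[snp.rsid].se)
        rsids.append(snp.rsid)
    if not xs:
        raise ValueError("no SNPs shared between exposure and outcome sets")
    return TwoSampleInput(np.array(xs), np.array(sxs), np.array(ys),
                          np.array(sys_), tuple(rsids))
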