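"""Per-cohort preprocessing and the three association models.

Every cohort contributes three ordinary-least-squares fits on standardized
variables: trait on TL (the observational association), TL on GRS (the
instrument first stage) and trait on GRS (the reduced form). TL and the
trait are Z-transformed within cohort (and within APOE stratum for
stratified runs) so that per-study lab scaling of the raw T/S-ratio cancels;
the GRS enters on its raw allele-count scale. All models adjust for sex, an
age-group factor (0-29 / 30-59 / 60-79 / 80+ years, youngest present group
as reference) and any declared study covariates. Rows with a missing value
in any model variable are dropped listwise, per model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_data import APOE_GENOTYPES, Cohort

__all__ = ["Estimate", "CohortTooSmallError", "z_transform",
           "assign_age_group", "fit_linear", "stratify_apoe",
           "cohort_associations", "MODEL_LABELS"]

log = logging.getLogger(__name__)

MODEL_LABELS = ("TL_trait", "GRS_TL", "GRS_trait")
APOE_CARRIER = ("e3/e4", "e4/e4")
APOE_NONCARRIER = ("e2/e2", "e2/e3", "e3/e3")
_AGE_EDGES = (30.0, 60.0, 80.0)


class CohortTooSmallError(ValueError):
    """Fewer complete cases than the configured minimum."""


@dataclass(frozen=True)
class Estimate:
    """A fitted association: effect, its standard error and sample size."""

    beta: float
    se: float
    n: int
    label: str = ""
    trait: str = ""
    cohort: str = ""
    stratum: str = "all"

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def ci(self, mult: float = 1.959963984540054) -> tuple[float, float]:
        return self.beta - mult * self.se, self.beta + mult * self.se


def z_transform(values, name: str = "variable") -> np.ndarray:
    """Standardize to mean 0, sample s.d. 1 (n-1 denominator); NaN passes
    through untouched."""
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError(f"{name}: need >= 2 non-missing values")
    sd = x[ok].std(ddof=1)
    if sd == 0:
        raise ValueError(f"{name}: zero variance, cannot Z-transform")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - x[ok].mean()) / sd
    return out


def assign_age_group(age) -> np.ndarray:
    """Map age in years to the four-level age-group code 1..4."""
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("negative age")
    return (np.digitize(a, _AGE_EDGES) + 1).astype(int)


def fit_linear(y, X: pd.DataFrame) -> tuple[Estimate, pd.DataFrame]:
    """OLS of y on X (which must contain a 'const' column).

    Returns the estimate for the first non-intercept column plus the full
    coefficient table. Non-intercept columns without variation in the
    complete cases (e.g. a sex indicator in a single-sex cohort, or absent
    age groups) are dropped with a logged warning; genuine rank deficiency
    among the remaining columns is an error.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    keep = y.notna() & X.notna().all(axis=1)
    yc, Xc = y[keep], X.loc[keep].astype(float)

    exog = [c for c in Xc.columns if c != "const"]
    if not exog:
        raise ValueError("design has no non-intercept column")
    target = exog[0]
    degenerate = [c for c in exog if Xc[c].nunique() <= 1]
    if target in degenerate:
        raise ValueError(f"no variation in {target!r} among complete cases")
    if degenerate:
        log.warning("dropping constant design columns: %s", degenerate)
        Xc = Xc.drop(columns=degenerate)

    n, p = Xc.shape
    if n < p + 1:
        raise ValueError(f"too few complete cases ({n}) for {p} parameters")
    if np.linalg.matrix_rank(Xc.to_numpy()) < p:
        raise ValueError("design matrix is rank deficient")

    fit = sm.OLS(yc, Xc).fit()
    table = pd.DataFrame({"beta": fit.params, "se": fit.bse,
                          "t": fit.tvalues, "p": fit.pvalues})
    est = Estimate(float(fit.params[target]), float(fit.bse[target]), int(n))
    return est, table


def stratify_apoe(cohort: Cohort) -> tuple[Cohort, Cohort, int]:
    """Split on APOE e4 carriage.

    Carriers are e3/e4 and e4/e4; non-carriers e2/e2, e2/e3 and e3/e3;
    the ambiguous e2/e4 genotype (one risk, one protective allele) and
    missing genotypes are excluded.
    """
    geno = cohort.data["apoe"]
    known = geno.dropna()
    bad = set(known) - set(APOE_GENOTYPES)
    if bad:
        raise ValueError(f"{cohort.name}: unknown APOE genotypes {sorted(bad)}")
    carrier = cohort.data[geno.isin(APOE_CARRIER)]
    noncarrier = cohort.data[geno.isin(APOE_NONCARRIER)]
    excluded = len(cohort.data) - len(carrier) - len(noncarrier)
    return (Cohort(cohort.name, carrier, cohort.covariates),
            Cohort(cohort.name, noncarrier, cohort.covariates),
            excluded)


def _design(frame: pd.DataFrame, exposure: pd.Series,
            covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame({"exposure": exposure}, index=frame.index)
    X["female"] = (frame["sex"] == "female").astype(float)
    groups = assign_age_group(frame["age"].to_numpy())
    present = np.unique(groups)
    for g in present[1:]:  # youngest present group is the reference
        X[f"age_group_{g}"] = (groups == g).astype(float)
    for c in covariates:
        X[c] = frame[c].astype(float)
    return sm.add_constant(X, has_constant="add")


def cohort_associations(cohort: Cohort, trait: str, stratum: str = "all",
                        min_n: int = 30) -> dict[str, Estimate]:
    """Fit the three association models for one cohort and trait.

    Returns estimates keyed ``TL_trait``, ``GRS_TL``, ``GRS_trait``. The
    cohort table must already carry a ``grs`` column. Stratified runs
    ("e4_carrier" / "e4_noncarrier") require APOE genotypes and restandardize
    TL and trait within the stratum.
    """
    if trait not in cohort.data.columns:
        raise ValueError(f"{cohort.name}: trait {trait!r} not available")
    if "grs" not in cohort.data.columns:
        raise ValueError(f"{cohort.name}: no 'grs' column; build the score first")

    if stratum == "all":
        frame = cohort.data
    elif stratum in ("e4_carrier", "e4_noncarrier"):
        if cohort.data["apoe"].isna().all():
            raise ValueError(f"{cohort.name}: APOE genotype unavailable, "
                             f"cannot stratify")
        carrier, noncarrier, _ = stratify_apoe(cohort)
        frame = (carrier if stratum == "e4_carrier" else noncarrier).data
    else:
        raise ValueError(f"unknown stratum {stratum!r}")

    complete = frame[["tl_raw", trait, "grs", "age", "sex"]].notna().all(axis=1)
    if int(complete.sum()) < min_n:
        raise CohortTooSmallError(
            f"{cohort.name}/{trait}/{stratum}: {int(complete.sum())} complete "
            f"cases < minimum {min_n}")

    z_tl = pd.Series(z_transform(frame["tl_raw"], f"{cohort.name} TL"),
                     index=frame.index)
    z_trait = pd.Series(z_transform(frame[trait], f"{cohort.name} {trait}"),
                        index=frame.index)
    grs = frame["grs"]

    specs = {"TL_trait": (z_trait, z_tl), "GRS_TL": (z_tl, grs),
             "GRS_trait": (z_trait, grs)}
    out = {}
    for label, (y, x) in specs.items():
        est, _ = fit_linear(y, _design(frame, x, cohort.covariates))
        out[label] = Estimate(est.beta, est.se, est.n, label=label,
                              trait=trait, cohort=cohort.name, stratum=stratum)
    return out
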