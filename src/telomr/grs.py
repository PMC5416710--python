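"""Unweighted genetic risk score (GRS) for telomere length.

The score is the per-individual count of telomere-shortening alleles across
the seven instrument loci (range 0-14). Counting the shortening allele makes
the pooled GRS-on-TL regression slope negative, matching the reported
direction of the instrument. Dosages may be fractional (imputed genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import SNPDef

__all__ = ["GRSVector", "AmbiguousStrandError", "AlleleMismatchError",
           "align_alleles", "build_grs", "add_grs_column"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AmbiguousStrandError(ValueError):
    """Palindromic SNP whose strand cannot be resolved from frequency."""


class AlleleMismatchError(ValueError):
    """Observed alleles match neither strand orientation of the reference."""


def _complement(allele: str) -> str:
    try:
        return _COMPLEMENT[allele]
    except KeyError:
        raise ValueError(f"not a single base: {allele!r}") from None


def align_alleles(dosages: np.ndarray, effect_allele: str, other_allele: str,
                  reference: SNPDef, eaf: float | None = None,
                  ) -> tuple[np.ndarray, str]:
    """Orient a dosage column to the reference counted allele.

    Returns ``(oriented dosages, action)`` where action is ``"as-is"`` or
    ``"flipped"`` (``d -> 2 - d``). Strand flips are resolved by
    complementing the observed alleles; palindromic pairs (A/T, C/G) with
    allele frequency in [0.4, 0.6] (or no frequency at all) are refused
    because the strand is ambiguous.
    """
    e, o = effect_allele.upper(), other_allele.upper()
    ref = (reference.effect_allele.upper(), reference.other_allele.upper())
    if len(e) != 1 or len(o) != 1:
        raise ValueError("alleles must be single bases")
    d = np.asarray(dosages, dtype=float)

    if o == _complement(e):  # palindromic: both strands carry the same pair
        freq = reference.eaf if eaf is None else eaf
        if eaf is None or 0.4 <= freq <= 0.6:
            raise AmbiguousStrandError(
                f"{reference.rsid}: ambiguous strand for palindromic "
                f"{e}/{o} SNP (eaf {freq:.2f} in [0.4, 0.6] or unknown)")
        # frequency resolves orientation: the counted allele is the one on
        # the same side of 0.5 as the reference frequency
        same_side = (eaf < 0.5) == (reference.eaf < 0.5)
        matches_effect = e == ref[0] or _complement(e) == ref[0]
        if not (matches_effect or e == ref[1] or _complement(e) == ref[1]):
            raise AlleleMismatchError(
                f"{reference.rsid}: observed {e}/{o} vs reference "
                f"{ref[0]}/{ref[1]}")
        if matches_effect == same_side:
            return d, "as-is"
        return 2.0 - d, "flipped"

    if (e, o) == ref or (_complement(e), _complement(o)) == ref:
        return d, "as-is"
    if (o, e) == ref or (_complement(o), _complement(e)) == ref:
        return 2.0 - d, "flipped"
    raise AlleleMismatchError(
        f"{reference.rsid}: observed {e}/{o} vs reference {ref[0]}/{ref[1]}")


@dataclass
class GRSVector:
    """Per-individual risk-allele counts plus bookkeeping."""

    score: np.ndarray
    n_snps_used: np.ndarray
    orientation_log: dict[str, str]

    def __len__(self) -> int:
        return len(self.score)


def build_grs(dosages: np.ndarray | pd.DataFrame, snps: Sequence[SNPDef],
              missing_policy: str = "mean_impute") -> GRSVector:
    """Sum oriented counted-allele dosages across the instrument SNPs.

    ``mean_impute`` replaces a missing dosage at SNP j by its Hardy-Weinberg
    expectation 2*eaf_j; ``drop`` gives individuals with any missing dosage
    a missing score.
    """
    if missing_policy not in ("mean_impute", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if isinstance(dosages, pd.DataFrame):
        d = dosages.loc[:, [s.rsid for s in snps]].to_numpy(dtype=float)
    else:
        d = np.asarray(dosages, dtype=float)
    if d.ndim != 2 or d.shape[1] != len(snps):
        raise ValueError(f"dosage matrix must be n x {len(snps)}")
    with np.errstate(invalid="ignore"):
        if np.nanmin(d, initial=0.0) < 0 or np.nanmax(d, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")

    missing = np.isnan(d)
    log: dict[str, str] = {}
    for j, s in enumerate(snps):
        if missing[:, j].all():
            raise ValueError(f"{s.rsid}: all dosages missing")
        log[s.rsid] = "mean-imputed" if (missing_policy == "mean_impute"
                                         and missing[:, j].any()) else "as-is"

    n_used = (~missing).sum(axis=1)
    if missing_policy == "mean_impute":
        fill = 2.0 * np.array([s.eaf for s in snps])
        d = np.where(missing, fill, d)
        score = d.sum(axis=1)
    else:
        score = np.where(missing.any(axis=1), np.nan, np.nansum(d, axis=1))
    return GRSVector(score, n_used, log)


def add_grs_column(frame: pd.DataFrame, snps: Sequence[SNPDef],
                   missing_policy: str = "mean_impute",
                   column: str = "grs") -> pd.DataFrame:
    """Return a copy of a cohort table with the risk score appended."""
    out = frame.copy()
    out[column] = build_grs(frame, snps, missing_policy).score
    return out
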