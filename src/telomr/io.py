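"""Delimited-text I/O for cohort tables, summary statistics and estimates.

Everything is tab-separated text with ``NA`` as the missing marker; files
written by a seeded run open with a ``# seed=<int>`` comment line so the
generating stream is always recoverable from the artifact itself.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_models import Estimate
from .synthetic_data import (APOE_GENOTYPES, Cohort, SNPDef, SummaryStatRow,
                             TRAITS)

__all__ = ["write_cohort_table", "read_cohort_table", "write_summary_stats",
           "read_summary_stats", "write_estimates", "read_estimates"]

NA = "NA"
_SUMMARY_COLS = ["rsid", "effect_allele", "other_allele", "eaf", "beta",
                 "se", "n"]
_ESTIMATE_COLS = ["cohort", "trait", "label", "stratum", "beta", "se", "n"]


def _write_tsv(frame: pd.DataFrame, path, seed: int | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        # shortest round-trip float repr keeps read(write(x)) == x exactly
        frame.to_csv(fh, sep="\t", index=False, na_rep=NA,
                     float_format=lambda v: repr(float(v)))


def write_cohort_table(cohort: Cohort, path, seed: int | None = None) -> None:
    _write_tsv(cohort.data, path, seed)


def read_cohort_table(path, snps: Sequence[SNPDef],
                      name: str | None = None,
                      covariates: Sequence[str] = ()) -> Cohort:
    """Read a per-individual cohort table, validating dosages and APOE."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", na_values=[NA], float_precision="round_trip",
                        keep_default_na=False, dtype={"id": str, "sex": str,
                                                      "apoe": str})
    required = ["id", "tl_raw", "age", "sex"] + [s.rsid for s in snps]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    known = set(required) | {"apoe", "grs"} | set(TRAITS) | set(covariates)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        raise ValueError(f"{path.name}: unknown columns {unknown}")

    for s in snps:
        d = pd.to_numeric(frame[s.rsid], errors="coerce")
        bad = frame.index[(~d.isna()) & ((d < 0) | (d > 2))]
        if len(bad):
            raise ValueError(f"{path.name}: dosage outside [0, 2] at row "
                             f"{bad[0] + 2}, column {s.rsid}")
        non_numeric = frame.index[d.isna() & frame[s.rsid].notna()]
        if len(non_numeric):
            raise ValueError(f"{path.name}: non-numeric dosage at row "
                             f"{non_numeric[0] + 2}, column {s.rsid}")
        frame[s.rsid] = d
    if (frame["tl_raw"] <= 0).any():
        row = int(frame.index[frame["tl_raw"] <= 0][0]) + 2
        raise ValueError(f"{path.name}: non-positive tl_raw at row {row}")
    if "apoe" in frame.columns:
        bad = frame["apoe"].dropna()
        bad = bad[~bad.isin(APOE_GENOTYPES)]
        if len(bad):
            raise ValueError(f"{path.name}: malformed APOE genotype "
                             f"{bad.iloc[0]!r} at row {int(bad.index[0]) + 2}")
    else:
        frame["apoe"] = np.nan
    return Cohort(name or path.stem, frame, tuple(covariates))


def write_summary_stats(rows: Sequence[SummaryStatRow], path,
                        seed: int | None = None) -> None:
    frame = pd.DataFrame([(r.rsid, r.effect_allele, r.other_allele, r.eaf,
                           r.beta, r.se, r.n) for r in rows],
                         columns=_SUMMARY_COLS)
    _write_tsv(frame, path, seed)


def read_summary_stats(path) -> list[SummaryStatRow]:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", na_values=[NA], float_precision="round_trip",
                        keep_default_na=False)
    missing = [c for c in _SUMMARY_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    rows = []
    for i, r in frame.iterrows():
        if not r["se"] > 0:
            raise ValueError(f"{path.name}: se must be > 0 at row {i + 2}")
        rows.append(SummaryStatRow(str(r["rsid"]), str(r["effect_allele"]),
                                   str(r["other_allele"]), float(r["eaf"]),
                                   float(r["beta"]), float(r["se"]),
                                   int(r["n"])))
    return rows


def write_estimates(estimates: Sequence[Estimate], path,
                    seed: int | None = None) -> None:
    frame = pd.DataFrame([(e.cohort, e.trait, e.label, e.stratum, e.beta,
                           e.se, e.n) for e in estimates],
                         columns=_ESTIMATE_COLS)
    _write_tsv(frame, path, seed)


def read_estimates(path) -> list[Estimate]:
    frame = pd.read_csv(path, sep="\t", comment="#", na_values=[NA], float_precision="round_trip",
                        keep_default_na=False)
    missing = [c for c in _ESTIMATE_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {missing}")
    return [Estimate(float(r["beta"]), float(r["se"]), int(r["n"]),
                     label=str(r["label"]), trait=str(r["trait"]),
                     cohort=str(r["cohort"]), stratum=str(r["stratum"]))
            for _, r in frame.iterrows()]
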