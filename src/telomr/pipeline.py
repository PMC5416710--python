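"""End-to-end orchestration: simulate/load -> GRS -> models -> meta -> MR.

``run_pipeline`` executes the full analysis and writes three artifacts to
the output directory: a per-cohort descriptive summary (``cohort_summary.tsv``),
a per-trait results table with predicted (IV) and observed effects side by
side plus the difference P (``results.tsv``), and the machine-readable
per-cohort estimates every pooled number is derived from
(``estimates.tsv``), together with a run manifest recording seed and
configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .cohort_models import (Cohort, CohortTooSmallError, Estimate,
                            cohort_associations)
from .grs import add_grs_column
from .meta_analysis import MetaResult, pool
from .mr import MRResult, WeakInstrumentError, difference_test, wald_iv
from .published import TRAITS
from .synthetic_data import (CohortConfig, DEFAULT_SNPS, SNPDef, TrueParams,
                             default_cohort_configs, default_true_params,
                             simulate_multi_cohort)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "analyze_cohorts", "weighted_cohort_summary",
           "sample_size_weighted_mean", "load_run_config"]


def sample_size_weighted_mean(means, ns) -> float:
    """Sum(n_c * m_c) / Sum(n_c) over per-cohort statistics."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.size == 0:
        raise ValueError("no cohorts")
    return float(np.average(means, weights=ns))

log = logging.getLogger(__name__)
STRATA = ("all", "e4_carrier", "e4_noncarrier")


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    seed: int = 0
    out_dir: str | Path = "telomr_out"
    cohort_paths: Mapping[str, str] = field(default_factory=dict)
    simulate: bool = True
    sim_scale: float = 1.0
    cohort_configs: Sequence[CohortConfig] | None = None
    truth: TrueParams | None = None
    snps: Sequence[SNPDef] = DEFAULT_SNPS
    traits: Sequence[str] = TRAITS
    stratify: bool = True
    switch_p: float = 0.05
    weak_z: float = 2.0
    min_n: int = 30
    missing_policy: str = "mean_impute"


@dataclass
class PipelineResult:
    cohorts: list[Cohort]
    estimates: list[Estimate]
    pooled: dict[tuple[str, str, str], MetaResult]  # (trait, label, stratum)
    mr: dict[tuple[str, str], MRResult]             # (trait, stratum)
    diff: dict[tuple[str, str], tuple[float, float]]
    summary: pd.DataFrame


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (simulation block or cohort paths)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for key in ("seed", "out_dir", "simulate", "sim_scale", "switch_p",
                "weak_z", "min_n", "missing_policy", "stratify", "traits"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "cohorts" in raw:
        if isinstance(raw["cohorts"], dict):  # name -> path of prepared tables
            cfg.cohort_paths = dict(raw["cohorts"])
            cfg.simulate = False
        else:  # list of simulation blocks
            cfg.cohort_configs = [CohortConfig(**{**c, "traits_available":
                                                  tuple(c.get("traits_available", TRAITS))})
                                  for c in raw["cohorts"]]
    if "truth" in raw:
        t = dict(raw["truth"])
        theta = t.pop("theta", None)
        cfg.truth = default_true_params(theta=theta, **t)
    return cfg


def weighted_cohort_summary(cohorts: Sequence[Cohort]) -> pd.DataFrame:
    """Per-cohort descriptives plus a sample-size-weighted TOTAL row."""
    if not cohorts:
        raise ValueError("no cohorts")
    rows = []
    for c in cohorts:
        d = c.data
        rows.append({
            "cohort": c.name, "n": len(d),
            "age_mean": d["age"].mean(), "age_sd": d["age"].std(ddof=1),
            "tl_mean": d["tl_raw"].mean(), "tl_sd": d["tl_raw"].std(ddof=1),
            "pct_women": 100.0 * (d["sex"] == "female").mean(),
            "grs_mean": d["grs"].mean() if "grs" in d else np.nan,
            "grs_sd": d["grs"].std(ddof=1) if "grs" in d else np.nan,
            "traits": ",".join(t for t in TRAITS if t in d.columns),
            "has_apoe": bool(d["apoe"].notna().any()),
        })
    table = pd.DataFrame(rows)
    n = table["n"].to_numpy(dtype=float)
    total = {"cohort": "TOTAL", "n": int(n.sum()), "traits": "",
             "has_apoe": bool(table["has_apoe"].any())}
    for col in ("age_mean", "age_sd", "tl_mean", "tl_sd", "pct_women",
                "grs_mean", "grs_sd"):
        total[col] = float(np.average(table[col].to_numpy(dtype=float),
                                      weights=n))
    return pd.concat([table, pd.DataFrame([total])], ignore_index=True)


def analyze_cohorts(cohorts: Sequence[Cohort], traits: Sequence[str],
                    stratify: bool = True, min_n: int = 30,
                    ) -> list[Estimate]:
    """Per-cohort association estimates for every trait (and APOE stratum)."""
    estimates: list[Estimate] = []
    strata = STRATA if stratify else ("all",)
    for cohort in cohorts:
        for trait in traits:
            if trait not in cohort.data.columns:
                continue
            for stratum in strata:
                if stratum != "all" and cohort.data["apoe"].isna().all():
                    continue
                try:
                    ests = cohort_associations(cohort, trait, stratum,
                                               min_n=min_n)
                except CohortTooSmallError as err:
                    log.info("skipping %s", err)
                    continue
                estimates.extend(ests.values())
    return estimates


def pool_estimates(estimates: Sequence[Estimate], switch_p: float = 0.05,
                   ) -> dict[tuple[str, str, str], MetaResult]:
    pooled = {}
    keys = sorted({(e.trait, e.label, e.stratum) for e in estimates})
    for trait, label, stratum in keys:
        group = [e for e in estimates if (e.trait, e.label, e.stratum)
                 == (trait, label, stratum)]
        pooled[(trait, label, stratum)] = pool(group, switch_p=switch_p)
    return pooled


def causal_estimates(pooled: Mapping[tuple[str, str, str], MetaResult],
                     weak_z: float = 2.0,
                     ) -> tuple[dict, dict]:
    """Wald-ratio IV estimate and observed-vs-causal test per trait/stratum."""
    mr_results, diffs = {}, {}
    for (trait, label, stratum), res in pooled.items():
        if label != "GRS_trait":
            continue
        first_stage = pooled.get((trait, "GRS_TL", stratum))
        observed = pooled.get((trait, "TL_trait", stratum))
        if first_stage is None:
            continue
        try:
            iv = wald_iv(res, first_stage, weak_z=weak_z)
        except WeakInstrumentError as err:
            log.warning("%s/%s: %s", trait, stratum, err)
            continue
        mr_results[(trait, stratum)] = iv
        if observed is not None:
            diffs[(trait, stratum)] = difference_test(observed, iv)
    return mr_results, diffs


def _results_table(pooled, mr_results, diffs) -> pd.DataFrame:
    rows = []
    for (trait, stratum), iv in sorted(mr_results.items()):
        obs = pooled.get((trait, "TL_trait", stratum))
        diff = diffs.get((trait, stratum), (np.nan, np.nan))
        rows.append({
            "trait": trait, "stratum": stratum, "n": iv.n,
            "iv_beta": iv.beta, "iv_ci_low": iv.ci_low,
            "iv_ci_high": iv.ci_high, "iv_p": iv.p, "f_stat": iv.f_stat,
            "diff_p": diff[1],
            "obs_beta": obs.beta if obs else np.nan,
            "obs_ci_low": obs.ci_low if obs else np.nan,
            "obs_ci_high": obs.ci_high if obs else np.nan,
            "obs_p": obs.p if obs else np.nan,
            "obs_method": obs.method if obs else "",
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        configs = (list(config.cohort_configs) if config.cohort_configs
                   else default_cohort_configs(config.sim_scale))
        truth = config.truth or default_true_params()
        cohorts = simulate_multi_cohort(configs, config.snps, truth,
                                        config.seed)
    else:
        cohorts = [tio.read_cohort_table(p, config.snps, name=n)
                   for n, p in config.cohort_paths.items()]
        if not cohorts:
            raise ValueError("no cohorts configured")

    cohorts = [Cohort(c.name, add_grs_column(c.data, config.snps,
                                             config.missing_policy),
                      c.covariates) for c in cohorts]

    estimates = analyze_cohorts(cohorts, config.traits,
                                stratify=config.stratify, min_n=config.min_n)
    if not estimates:
        raise ValueError("no estimable cohort/trait combinations")
    pooled = pool_estimates(estimates, switch_p=config.switch_p)
    mr_results, diffs = causal_estimates(pooled, weak_z=config.weak_z)
    summary = weighted_cohort_summary(cohorts)

    tio.write_estimates(estimates, out / "estimates.tsv", seed=config.seed)
    with open(out / "cohort_summary.tsv", "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        summary.to_csv(fh, sep="\t", index=False, na_rep="NA")
    with open(out / "results.tsv", "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        _results_table(pooled, mr_results, diffs).to_csv(
            fh, sep="\t", index=False, na_rep="NA")
    manifest = {"seed": config.seed, "switch_p": config.switch_p,
                "weak_z": config.weak_z, "min_n": config.min_n,
                "stratify": bool(config.stratify),
                "simulate": bool(config.simulate),
                "traits": list(config.traits),
                "cohorts": [c.name for c in cohorts],
                "n_total": int(sum(len(c) for c in cohorts))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return PipelineResult(cohorts, estimates, pooled, mr_results, diffs,
                          summary)
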