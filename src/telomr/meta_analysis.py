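"""Inverse-variance meta-analysis with a heterogeneity switch.

Per-cohort estimates are pooled with fixed-effect inverse-variance weights;
when Cochran's Q is significant at the switch threshold (default P < 0.05)
the pooling is redone under a DerSimonian-Laird random-effects model. This
mirrors the consortium's rule: fixed effects unless heterogeneity is
statistically significant. Confidence intervals and P-values use the normal
approximation throughout (beta +/- 1.96 se).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort_models import Estimate

__all__ = ["MetaResult", "fixed_effect_meta", "cochran_q",
           "random_effects_meta", "pool"]

log = logging.getLogger(__name__)
Z95 = 1.959963984540054


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect with heterogeneity diagnostics."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    k: int
    q: float
    q_df: int
    q_p: float
    i2: float
    tau2: float
    method: str  # "fixed" or "random"
    label: str = ""
    trait: str = ""
    stratum: str = "all"
    n: int = 0

    @property
    def z(self) -> float:
        return self.beta / self.se


def _weights(estimates: Sequence[Estimate]) -> tuple[np.ndarray, np.ndarray]:
    if not estimates:
        raise ValueError("no estimates to pool")
    b = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    return b, 1.0 / se**2


def fixed_effect_meta(estimates: Sequence[Estimate]) -> tuple[float, float]:
    """Inverse-variance weighted mean: beta = sum(w b)/sum(w), se = sum(w)^-1/2."""
    b, w = _weights(estimates)
    return float(np.sum(w * b) / np.sum(w)), float(1.0 / math.sqrt(np.sum(w)))


def cochran_q(estimates: Sequence[Estimate]) -> tuple[float, int, float, float]:
    """Cochran's Q against the fixed-effect mean; returns (q, df, p, i2)."""
    if len(estimates) < 2:
        raise ValueError("heterogeneity requires >= 2 studies")
    b, w = _weights(estimates)
    beta_f, _ = fixed_effect_meta(estimates)
    q = float(np.sum(w * (b - beta_f) ** 2))
    df = len(estimates) - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, p, i2


def random_effects_meta(estimates: Sequence[Estimate],
                        ) -> tuple[float, float, float]:
    """DerSimonian-Laird pooling; returns (beta, se, tau2)."""
    b, w = _weights(estimates)
    q, df, _, _ = cochran_q(estimates)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (np.array([e.se for e in estimates]) ** 2 + tau2)
    beta = float(np.sum(w_star * b) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    return beta, se, tau2


def pool(estimates: Sequence[Estimate], switch_p: float = 0.05) -> MetaResult:
    """Pool estimates, switching to random effects when Q's P < switch_p."""
    beta, se = fixed_effect_meta(estimates)
    k = len(estimates)
    tau2, method = 0.0, "fixed"
    if k >= 2:
        q, q_df, q_p, i2 = cochran_q(estimates)
        if q_p < switch_p:
            beta, se, tau2 = random_effects_meta(estimates)
            method = "random"
    else:
        q, q_df, q_p, i2 = 0.0, 0, 1.0, 0.0
        log.info("single study: heterogeneity undefined, fixed-effect pooling")

    first = estimates[0]
    return MetaResult(
        beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        p=float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0,
        k=k, q=q, q_df=q_df, q_p=q_p, i2=i2, tau2=tau2, method=method,
        label=first.label, trait=first.trait, stratum=first.stratum,
        n=int(sum(e.n for e in estimates)),
    )
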