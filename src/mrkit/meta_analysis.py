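"""Cross-cohort meta-analysis and multiple-testing control.

Discovery and replication estimates for the same exposure-outcome pair are
pooled by inverse-variance meta-analysis: a fixed-effects model when the
cohorts are homogeneous, DerSimonian–Laird random effects when I² exceeds
30%. Family-wise error is controlled by Bonferroni (0.05/91 for the protein
screen, 0.05/20 for the 4-protein × 5-complication screen).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaResult:
    """Pooled cross-cohort estimate with heterogeneity accounting."""

    model: str  # "fixed" | "random"
    beta: float
    se: float
    pval: float
    q_meta: float
    q_df_meta: int
    i2: float
    tau2: float
    inputs: tuple = field(default_factory=tuple)


def _coerce(estimates) -> tuple[np.ndarray, np.ndarray]:
    betas, ses = [], []
    for est in estimates:
        if hasattr(est, "beta"):
            betas.append(float(est.beta))
            ses.append(float(est.se))
        else:
            b, s = est
            betas.append(float(b))
            ses.append(float(s))
    return np.asarray(betas), np.asarray(ses)


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def i_squared(q: float, df: int) -> float:
    """Higgins I²: share of heterogeneity in Q beyond its expectation, floored at 0."""
    if q < 0 or df < 1:
        raise ValueError("require q >= 0 and df >= 1")
    if q == 0:
        return 0.0
    return max(0.0, (q - df) / q)


def choose_model(i2: float, threshold: float = 0.30) -> str:
    """Random effects iff I² strictly exceeds the threshold (default 30%)."""
    if not 0.0 <= i2 <= 1.0:
        raise ValueError("i2 must lie in [0,1]")
    return "random" if i2 > threshold else "fixed"


def bonferroni(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _fixed_core(betas: np.ndarray, ses: np.ndarray):
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (betas - pooled) ** 2))
    return pooled, se, q, w


def meta_fixed(estimates) -> MetaResult:
    """Fixed-effects inverse-variance pooling.

    With fewer than two inputs the single estimate passes through unchanged
    (warned), with Q = 0 and df = 0.
    """
    betas, ses = _coerce(estimates)
    if betas.size < 2:
        logger.warning("meta_fixed: fewer than 2 estimates; passing through")
        b, s = float(betas[0]), float(ses[0])
        return MetaResult("fixed", b, s, _normal_p(b, s), 0.0, 0, 0.0, 0.0, tuple(estimates))
    pooled, se, q, _ = _fixed_core(betas, ses)
    df = betas.size - 1
    return MetaResult(
        "fixed", pooled, se, _normal_p(pooled, se), q, df, i_squared(q, df), 0.0, tuple(estimates)
    )


def meta_random_dl(estimates) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    tau² = max(0, (Q − df)/(Σw − Σw²/Σw)) from the fixed-effects Q, then
    weights are re-formed as 1/(se² + tau²).
    """
    betas, ses = _coerce(estimates)
    if betas.size < 2:
        logger.warning("meta_random_dl: fewer than 2 estimates; passing through")
        b, s = float(betas[0]), float(ses[0])
        return MetaResult("random", b, s, _normal_p(b, s), 0.0, 0, 0.0, 0.0, tuple(estimates))
    _, _, q, w = _fixed_core(betas, ses)
    df = betas.size - 1
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    pooled = float(np.sum(w_star * betas) / np.sum(w_star))
    se = float(math.sqrt(1.0 / np.sum(w_star)))
    return MetaResult(
        "random", pooled, se, _normal_p(pooled, se), q, df, i_squared(q, df), tau2, tuple(estimates)
    )


def meta_pool(estimates, i2_threshold: float = 0.30, model: str | None = None) -> MetaResult:
    """Pool with the model chosen by the I² > threshold rule (or forced via ``model``)."""
    fixed = meta_fixed(estimates)
    chosen = model if model is not None else choose_model(fixed.i2, i2_threshold)
    if chosen == "fixed":
        return fixed
    return meta_random_dl(estimates)


def significance_tier(pval: float, alpha: float = 0.05, m: int = 1) -> str:
    """Classify a p-value: 'bonferroni' (< alpha/m), 'nominal' (< alpha), else 'ns'."""
    if pval < bonferroni(alpha, m):
        return "bonferroni"
    if pval < alpha:
        return "nominal"
    return "ns"
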