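"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~mrkit.gwas_io.HarmonizedSet` of J
instruments and return the causal effect of a 1-SD change in the exposure on
the outcome (log-odds scale for binary outcomes), with an OR-scale 95%
interval. The per-SNP building block is the Wald ratio beta_out/beta_exp;
the primary combiner is inverse-variance weighting with a multiplicative
random-effects scale floored at 1. MR-Egger adds a pleiotropy intercept,
the weighted median tolerates up to 50% invalid instruments, and the
maximum-likelihood estimator models measurement error on both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import EstimationError
from .gwas_io import HarmonizedSet

Z95 = float(stats.norm.ppf(0.975))  # 1.959963985...


@dataclass(frozen=True)
class MrEstimate:
    """One estimator's causal effect for one exposure-outcome pair."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Map a log-odds effect and its SE to an OR with 95% CI."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    return math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and first-order delta-method SEs.

    Returns (ratio, ratio_se, used) where ``used`` masks SNPs with nonzero
    exposure effect; zero-exposure SNPs are excluded (their ratio is
    undefined).
    """
    used = h.beta_exp != 0.0
    ratio = h.beta_out[used] / h.beta_exp[used]
    ratio_se = h.se_out[used] / np.abs(h.beta_exp[used])
    return ratio, ratio_se, used


def ivw_components(h: HarmonizedSet) -> tuple[float, float, float, int]:
    """Fixed-effect IVW estimate, its SE, Cochran's Q, and J.

    Weights w_j = beta_exp_j²/se_out_j² (inverse Wald-ratio variance under
    first-order errors); Q = Σ w_j (ratio_j − beta)². Single source of truth
    for the Q reused by the multiplicative random-effects scale and the
    heterogeneity test.
    """
    ratio, ratio_se, _ = wald_ratios(h)
    J = ratio.size
    if J < 2:
        raise EstimationError(f"insufficient instruments for IVW (J={J})")
    w = 1.0 / ratio_se**2
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (ratio - beta) ** 2))
    return beta, se_fixed, q, J


def ivw(h: HarmonizedSet, model: str = "mre") -> MrEstimate:
    """Inverse-variance-weighted estimate.

    ``model="fixed"`` uses the fixed-effect SE; ``model="mre"`` (the primary
    analysis) inflates it by sqrt(max(1, Q/(J−1))) — the multiplicative
    random-effects scale, which widens intervals under heterogeneity but
    never narrows them. Two-sided p from the normal reference.
    """
    if model not in ("fixed", "mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    beta, se_fixed, q, J = ivw_components(h)
    scale = max(1.0, q / (J - 1)) if model == "mre" else 1.0
    se = se_fixed * math.sqrt(scale)
    return MrEstimate(
        method="ivw_mre" if model == "mre" else "ivw_fe",
        beta=beta,
        se=se,
        pval=_normal_p(beta, se),
        n_snp=J,
        extra={"q": q, "q_df": J - 1, "mre_scale": scale, "se_fixed": se_fixed},
    )


def egger(h: HarmonizedSet) -> MrEstimate:
    """MR-Egger regression: slope = causal effect, intercept = mean pleiotropy.

    Weighted least squares of beta_out on beta_exp with intercept, weights
    1/se_out², after orienting every SNP so its exposure effect is
    nonnegative (required for identifiability of the intercept). Standard
    errors use a multiplicative overdispersion scale floored at 1; p-values
    from t with J−2 df.
    """
    used = h.beta_exp != 0.0
    sign = np.sign(h.beta_exp[used])
    x = h.beta_exp[used] * sign
    y = h.beta_out[used] * sign
    se_out = h.se_out[used]
    J = x.size
    if J < 3:
        raise EstimationError(f"insufficient instruments for Egger (J={J})")
    res = sm.WLS(y, sm.add_constant(x), weights=1.0 / se_out**2).fit()
    # res.bse already carries sqrt(scale) with scale = weighted RSS/(J-2);
    # floor the scale at 1 so homogeneous data keep the analytic SE
    infl = math.sqrt(max(1.0, res.scale) / res.scale) if res.scale > 0 else 1.0
    slope, intercept = float(res.params[1]), float(res.params[0])
    slope_se = float(res.bse[1]) * infl
    int_se = float(res.bse[0]) * infl
    df = J - 2

    def _t_p(est, se):
        if se == 0:
            return 1.0 if est == 0 else 0.0
        return float(2.0 * stats.t.sf(abs(est) / se, df))

    return MrEstimate(
        method="egger",
        beta=slope,
        se=slope_se,
        pval=_t_p(slope, slope_se),
        n_snp=J,
        extra={
            "intercept": intercept,
            "intercept_se": int_se,
            "intercept_pval": _t_p(intercept, int_se),
            "scale": float(res.scale),
        },
    )


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative midpoint.

    Order ratios ascending; with normalized weights w', the j-th order
    statistic sits at s_j = cumsum(w')_j − w'_j/2; the estimate interpolates
    the ratios at s = 0.5.
    """
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    w = weight[order] / np.sum(weight)
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Consistent when instruments carrying at least half the weight are valid.
    Weights are inverse Wald-ratio variances. The SE resamples per-SNP betas
    from their normal sampling errors (both sides), recomputes the weighted
    median, and takes the SD over ``n_boot`` draws; pass ``n_boot=0`` to skip
    the bootstrap (SE returned as NaN — point estimate only).
    """
    ratio, ratio_se, used = wald_ratios(h)
    J = ratio.size
    if J < 3:
        raise EstimationError(f"insufficient instruments for weighted median (J={J})")
    w = 1.0 / ratio_se**2
    est = _weighted_median(ratio, w)

    if n_boot <= 0:
        return MrEstimate("weighted_median", est, float("nan"), float("nan"), J)
    rng = np.random.default_rng(seed)
    bx = h.beta_exp[used] + h.se_exp[used] * rng.standard_normal((n_boot, J))
    by = h.beta_out[used] + h.se_out[used] * rng.standard_normal((n_boot, J))
    draws = np.empty(n_boot)
    for b in range(n_boot):
        ok = bx[b] != 0.0
        r_b = by[b][ok] / bx[b][ok]
        w_b = (bx[b][ok] / h.se_out[used][ok]) ** 2
        draws[b] = _weighted_median(r_b, w_b)
    se = float(np.std(draws, ddof=1))
    return MrEstimate(
        "weighted_median", est, se, _normal_p(est, se), J, extra={"n_boot": n_boot}
    )


def _profile_nll(b: float, bx, by, sx2, sy2) -> float:
    # per-SNP true exposure effects profiled out analytically
    return 0.5 * float(np.sum((by - b * bx) ** 2 / (sy2 + b * b * sx2)))


def max_likelihood(h: HarmonizedSet) -> MrEstimate:
    """Maximum-likelihood estimate under a bivariate normal measurement model.

    Model: beta_exp_j ~ N(γ_j, se_exp_j²), beta_out_j ~ N(b·γ_j, se_out_j²),
    independent across SNPs and between samples (two-sample design). The J
    nuisance effects γ_j are profiled out in closed form; b maximizes the
    profile likelihood and its SE comes from the numerical curvature of the
    profile log-likelihood at the optimum. Unlike IVW, this accounts for
    exposure-side measurement error.
    """
    used = h.beta_exp != 0.0
    bx, by = h.beta_exp[used], h.beta_out[used]
    sx2, sy2 = h.se_exp[used] ** 2, h.se_out[used] ** 2
    J = bx.size
    if J < 2:
        raise EstimationError(f"insufficient instruments for maximum likelihood (J={J})")

    b0, se0, _, _ = ivw_components(h)
    half_width = max(1.0, 50.0 * se0, 2.0 * abs(b0))
    res = optimize.minimize_scalar(
        _profile_nll,
        args=(bx, by, sx2, sy2),
        bounds=(b0 - half_width, b0 + half_width),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise EstimationError(f"maximum-likelihood optimizer failed: {res.message}")
    b_hat = float(res.x)
    if min(b_hat - (b0 - half_width), (b0 + half_width) - b_hat) < 1e-6 * half_width:
        raise EstimationError("maximum-likelihood estimate at search boundary")

    step = 1e-5 * max(1.0, abs(b_hat))
    f0 = _profile_nll(b_hat, bx, by, sx2, sy2)
    fp = _profile_nll(b_hat + step, bx, by, sx2, sy2)
    fm = _profile_nll(b_hat - step, bx, by, sx2, sy2)
    info = (fp - 2.0 * f0 + fm) / step**2
    if info <= 0:
        raise EstimationError("non-positive profile curvature at the ML optimum")
    se = float(1.0 / math.sqrt(info))
    return MrEstimate(
        "max_likelihood", b_hat, se, _normal_p(b_hat, se), J, extra={"nll": f0}
    )
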