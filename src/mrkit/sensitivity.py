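"""Heterogeneity, pleiotropy, and directionality diagnostics.

Three checks qualify an MR result: Cochran's Q across the per-SNP Wald
ratios (heterogeneity; p < 0.05 flags it), the MR-Egger intercept (directional
horizontal pleiotropy; p < 0.05 flags it), and the Steiger directionality
test — valid instruments should explain more variance in the exposure than in
the outcome, so the summed per-SNP R² on each side is compared with a
Fisher-z test on the implied correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, EstimationError
from .estimators import egger, ivw_components
from .gwas_io import HarmonizedSet

LIABILITY_RESIDUAL_VAR = math.pi**2 / 3.0  # logistic residual variance


@dataclass(frozen=True)
class SensitivityReport:
    """Q / Egger-intercept / Steiger outputs for one exposure-outcome pair.

    Egger fields are NaN when J < 3; Steiger fields are None/NaN when the
    exposure EAF or a sample size is unavailable.
    """

    q: float
    q_df: int
    q_pval: float
    egger_intercept: float = float("nan")
    egger_intercept_se: float = float("nan")
    egger_intercept_pval: float = float("nan")
    steiger_correct_direction: bool | None = None
    steiger_pval: float = float("nan")
    r2_exposure_total: float = float("nan")
    r2_outcome_total: float = float("nan")


def cochrans_q(h: HarmonizedSet, beta_ivw: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q over Wald ratios with IVW weights; chi-square(J−1) p-value.

    ``beta_ivw`` defaults to the fixed-effect IVW estimate so that this Q is
    identical to the one driving the multiplicative random-effects scale.
    """
    est, _, q_at_est, J = ivw_components(h)
    if beta_ivw is None or beta_ivw == est:
        q = q_at_est
    else:
        from .estimators import wald_ratios

        ratio, ratio_se, _ = wald_ratios(h)
        q = float(np.sum((ratio - beta_ivw) ** 2 / ratio_se**2))
    df = J - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """Egger regression intercept, its SE, and two-sided t p-value."""
    est = egger(h)
    return est.extra["intercept"], est.extra["intercept_se"], est.extra["intercept_pval"]


def _liability_r2(beta: np.ndarray, eaf: np.ndarray) -> np.ndarray:
    # log-odds betas mapped to an approximate liability-scale variance share
    v = 2.0 * eaf * (1.0 - eaf) * beta**2
    return v / (v + LIABILITY_RESIDUAL_VAR)


def steiger(
    h: HarmonizedSet,
    n_exp: int | None = None,
    n_out: int | None = None,
    cases: int | None = None,
    controls: int | None = None,
) -> tuple[bool, float, float, float]:
    """Directionality test: do the instruments explain more of the exposure?

    Per-SNP R² is 2·EAF·(1−EAF)·beta² on each trait's standardized scale
    (outcome EAF falls back to the exposure EAF when missing). For a binary
    outcome (``cases``/``controls`` given) the log-odds betas are converted
    with the liability approximation R² ≈ v/(v + π²/3) and the effective
    sample size 4/(1/cases + 1/controls). Totals are summed over SNPs;
    ``correct_direction`` is the strict comparison r2_exp > r2_out (a tie is
    conservatively not correct); the p-value is a Fisher-z comparison of the
    implied correlations at the two sample sizes.

    Returns (correct_direction, pval, r2_exp_total, r2_out_total).
    """
    if not np.isfinite(h.eaf_exp).all() or len(h) == 0:
        raise DataError("Steiger requires allele frequencies on the exposure side")
    n_exp = n_exp if n_exp is not None else h.n_exp
    if cases is not None and controls is not None:
        n_out_eff = 4.0 / (1.0 / cases + 1.0 / controls)
    else:
        n_out_eff = n_out if n_out is not None else h.n_out
    if n_exp is None or n_out_eff is None:
        raise DataError("Steiger requires sample sizes for both traits")

    eaf_out = np.where(np.isfinite(h.eaf_out), h.eaf_out, h.eaf_exp)
    r2_exp = 2.0 * h.eaf_exp * (1.0 - h.eaf_exp) * h.beta_exp**2
    if cases is not None and controls is not None:
        r2_out = _liability_r2(h.beta_out, eaf_out)
    else:
        r2_out = 2.0 * eaf_out * (1.0 - eaf_out) * h.beta_out**2
    r2_exp_total = float(np.sum(r2_exp))
    r2_out_total = float(np.sum(r2_out))

    cap = 1.0 - 1e-12
    r_exp = math.sqrt(min(r2_exp_total, cap))
    r_out = math.sqrt(min(r2_out_total, cap))
    z = (math.atanh(r_exp) - math.atanh(r_out)) / math.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out_eff - 3)
    )
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return r2_exp_total > r2_out_total, pval, r2_exp_total, r2_out_total


def sensitivity_report(
    h: HarmonizedSet,
    n_exp: int | None = None,
    n_out: int | None = None,
    cases: int | None = None,
    controls: int | None = None,
) -> SensitivityReport:
    """Run every applicable diagnostic for one pair; missing inputs degrade gracefully."""
    q, df, q_p = cochrans_q(h)
    kwargs: dict = {"q": q, "q_df": df, "q_pval": q_p}
    try:
        ic, ic_se, ic_p = egger_intercept_test(h)
        kwargs.update(
            egger_intercept=ic, egger_intercept_se=ic_se, egger_intercept_pval=ic_p
        )
    except EstimationError:
        pass
    try:
        direction, s_p, r2x, r2y = steiger(h, n_exp=n_exp, n_out=n_out, cases=cases, controls=controls)
        kwargs.update(
            steiger_correct_direction=direction,
            steiger_pval=s_p,
            r2_exposure_total=r2x,
            r2_outcome_total=r2y,
        )
    except DataError:
        pass
    return SensitivityReport(**kwargs)
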