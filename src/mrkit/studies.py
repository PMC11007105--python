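"""Replicated simulation studies over the scenario bank.

Each study generates many independent pairs from :mod:`mrkit.synthetic`,
pushes them through harmonization and the estimators, and summarizes a
calibration or recovery property: bias of the IVW estimate under a known
causal effect, type-I error under the null, the chi-square behaviour of
Cochran's Q, robustness of the weighted median to invalid instruments,
Egger-intercept recovery of directional pleiotropy, and Steiger
directionality accuracy. These functions back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import estimators as est
from .gwas_io import harmonize
from .sensitivity import cochrans_q, steiger
from .synthetic import SimConfig, scenario, simulate_pair


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def _harmonized(cfg: SimConfig):
    exp, out, truth = simulate_pair(cfg)
    return harmonize(exp, out, n_exp=cfg.n_exp, n_out=cfg.n_out), truth


def ivw_recovery_study(n_rep: int = 1000, seed: int = 0, scenario_name: str = "causal") -> dict:
    """Mean IVW-MRE estimate across replicates of a causal scenario.

    Returns the replicate mean/SD, the Monte-Carlo standard error of the
    mean, and the true effect.
    """
    seeds = _child_seeds(seed, n_rep)
    estimates = np.empty(n_rep)
    true_beta = None
    for i, s in enumerate(seeds):
        cfg = scenario(scenario_name, int(s))
        h, truth = _harmonized(cfg)
        true_beta = truth.causal_beta
        estimates[i] = est.ivw(h, model="mre").beta
    sd = float(np.std(estimates, ddof=1))
    return {
        "true_beta": float(true_beta),
        "mean": float(np.mean(estimates)),
        "sd": sd,
        "mcse": sd / np.sqrt(n_rep),
        "n_rep": n_rep,
    }


def null_calibration_study(n_rep: int = 2000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of IVW-MRE and the distribution of Q under the null.

    Under a homogeneous null (no causal effect, no pleiotropy) Q is exactly
    chi-square(J−1); the study reports the empirical rejection rate at
    ``alpha`` and the Kolmogorov–Smirnov p-value of Q against chi2(J−1).
    """
    seeds = _child_seeds(seed, n_rep)
    pvals = np.empty(n_rep)
    qs = np.empty(n_rep)
    df = None
    for i, s in enumerate(seeds):
        cfg = scenario("null", int(s))
        h, _ = _harmonized(cfg)
        pvals[i] = est.ivw(h, model="mre").pval
        q, df, _ = cochrans_q(h)
        qs[i] = q
    ks = stats.kstest(qs, stats.chi2(df).cdf)
    return {
        "type1_error": float(np.mean(pvals < alpha)),
        "q_ks_pval": float(ks.pvalue),
        "q_df": int(df),
        "n_rep": n_rep,
    }


def robustness_study(n_rep: int = 300, seed: int = 0) -> dict:
    """Invalid-instrument robustness and pleiotropy-intercept recovery.

    Scenario ``forty_invalid`` (40% of SNPs carry directional pleiotropy):
    compares the absolute bias of the weighted median against IVW.
    Scenario ``directional_pleiotropy`` (all SNPs pleiotropic, InSIDE holds):
    fraction of replicates whose Egger intercept lies within 2 SE of the
    true mean pleiotropic effect.
    """
    seeds = _child_seeds(seed, 2 * n_rep)
    ivw_est = np.empty(n_rep)
    wm_est = np.empty(n_rep)
    true_beta = None
    for i in range(n_rep):
        cfg = scenario("forty_invalid", int(seeds[i]))
        h, truth = _harmonized(cfg)
        true_beta = truth.causal_beta
        ivw_est[i] = est.ivw(h, model="mre").beta
        wm_est[i] = est.weighted_median(h, n_boot=0).beta

    covered = np.empty(n_rep, dtype=bool)
    for i in range(n_rep):
        cfg = scenario("directional_pleiotropy", int(seeds[n_rep + i]))
        h, _ = _harmonized(cfg)
        e = est.egger(h)
        covered[i] = (
            abs(e.extra["intercept"] - cfg.pleiotropy_mean) <= 2.0 * e.extra["intercept_se"]
        )
    return {
        "true_beta": float(true_beta),
        "ivw_bias": float(np.mean(ivw_est) - true_beta),
        "weighted_median_bias": float(np.mean(wm_est) - true_beta),
        "egger_intercept_coverage": float(np.mean(covered)),
        "pleiotropy_mean": 0.05,
        "n_rep": n_rep,
    }


def steiger_study(n_rep: int = 300, seed: int = 0) -> dict:
    """Directionality accuracy: forward-causal pairs should be flagged
    exposure→outcome, reverse-causal pairs should not."""
    seeds = _child_seeds(seed, 2 * n_rep)
    forward = np.empty(n_rep, dtype=bool)
    reverse = np.empty(n_rep, dtype=bool)
    for i in range(n_rep):
        h, _ = _harmonized(scenario("causal", int(seeds[i])))
        forward[i], _, _, _ = steiger(h)
        h, _ = _harmonized(scenario("reverse_causal", int(seeds[n_rep + i])))
        reverse[i], _, _, _ = steiger(h)
    return {
        "forward_correct_rate": float(np.mean(forward)),
        "reverse_flagged_rate": float(np.mean(~reverse)),
        "n_rep": n_rep,
    }
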