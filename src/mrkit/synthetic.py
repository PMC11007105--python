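"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a protein-exposure / disease-outcome
pair: J independent variants with MAF-dependent standard errors
(se = 1/sqrt(2·N·MAF·(1−MAF)) on the standardized trait scale), true per-SNP
exposure effects sized to a target per-SNP variance explained, an optional
pleiotropic direct effect on the outcome for an invalid subset of SNPs
(drawn independently of instrument strength, so the InSIDE condition holds
by construction), palindromic allele pairs at a configurable rate, and
block-diagonal LD. The true effect allele is defined as the
exposure-increasing allele, so true exposure effects are positive — a
labelling convention without loss of generality.

Binary outcomes are emulated directly on the log-odds scale (no
individual-level liability simulation); sample sizes default to the shape of
a large protein GWAS (N = 14,824) against a large case-control meta-analysis
(N = 898,130).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .errors import DataError
from .gwas_io import GwasRecord
from .instruments import LdTable

_NON_PALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


class SimConfig(BaseModel):
    """Ground-truth scenario for one exposure/outcome pair."""

    n_snps: int = Field(default=100, gt=0)
    n_exp: int = Field(default=14824, gt=2)
    n_out: int = Field(default=898130, gt=2)
    causal_beta: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_r2_per_snp: float = Field(default=0.005, gt=0.0, lt=1.0)
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = Field(default=0.0, ge=0.0)
    prop_invalid: float = Field(default=0.0, ge=0.0, le=1.0)
    prop_palindromic: float = Field(default=0.0, ge=0.0, le=1.0)
    ld_blocks: list[tuple[int, float]] = Field(default_factory=list)
    reverse_causal: bool = False
    seed: int

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < low <= high < 1")
        for size, r2 in self.ld_blocks:
            if size < 1 or not (0.0 <= r2 <= 1.0):
                raise ValueError("ld_blocks entries must be (size >= 1, r2 in [0,1])")
        return self


#: Scenario bank: the study conditions exercised by the property tests.
SCENARIOS: dict[str, dict] = {
    "null": {"causal_beta": 0.0},
    "causal": {"causal_beta": 0.15},
    "directional_pleiotropy": {
        "causal_beta": 0.15,
        "prop_invalid": 1.0,
        "pleiotropy_mean": 0.05,
        "pleiotropy_sd": 0.02,
    },
    "balanced_pleiotropy": {
        "causal_beta": 0.15,
        "prop_invalid": 1.0,
        "pleiotropy_mean": 0.0,
        "pleiotropy_sd": 0.05,
    },
    "forty_invalid": {
        "causal_beta": 0.15,
        "prop_invalid": 0.4,
        "pleiotropy_mean": 0.05,
        "pleiotropy_sd": 0.01,
    },
    "reverse_causal": {"causal_beta": 0.15, "reverse_causal": True},
}


def scenario(name: str, seed: int, **overrides) -> SimConfig:
    """Build a scenario-bank config; ``overrides`` adjust any SimConfig field."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    params = dict(SCENARIOS[name])
    params.update(overrides)
    return SimConfig(seed=seed, **params)


@dataclass
class SimTruth:
    """Latent values behind one simulated pair."""

    causal_beta: float
    reverse_causal: bool
    maf: list[float]
    gamma: list[float]  # true per-SNP effects on the exposure
    big_gamma: list[float]  # true per-SNP effects on the outcome
    alpha: list[float]  # pleiotropic direct effects
    invalid: list[bool]
    palindromic: list[bool]
    snp_ids: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def simulate_pair(cfg: SimConfig) -> tuple[list[GwasRecord], list[GwasRecord], SimTruth]:
    """Draw one exposure/outcome summary-statistic pair.

    True exposure effects γ_j = sqrt(r²/(2·MAF(1−MAF))) (positive by the
    effect-allele convention); outcome effects Γ_j = b·γ_j + α_j with α_j
    pleiotropy for the invalid subset. With ``reverse_causal`` the roles
    swap: variants act directly on the outcome and the exposure inherits
    b·Γ_j + α_j. Observed betas add N(0, se²) noise with the MAF-and-N
    driven se of each trait; p-values are two-sided normal.
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snps
    if cfg.exposure_r2_per_snp * J >= 1.0:
        raise DataError(
            f"total exposure variance explained {cfg.exposure_r2_per_snp * J:.3f} >= 1"
        )
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], J)
    het = 2.0 * maf * (1.0 - maf)
    direct = np.sqrt(cfg.exposure_r2_per_snp / het)
    invalid = rng.random(J) < cfg.prop_invalid
    alpha = np.where(invalid, rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, J), 0.0)
    if cfg.reverse_causal:
        big_gamma = direct
        gamma = cfg.causal_beta * big_gamma + alpha
    else:
        gamma = direct
        big_gamma = cfg.causal_beta * gamma + alpha

    se_exp = 1.0 / np.sqrt(het * cfg.n_exp)
    se_out = 1.0 / np.sqrt(het * cfg.n_out)
    beta_exp = gamma + se_exp * rng.standard_normal(J)
    beta_out = big_gamma + se_out * rng.standard_normal(J)
    p_exp = 2.0 * stats.norm.sf(np.abs(beta_exp) / se_exp)
    p_out = 2.0 * stats.norm.sf(np.abs(beta_out) / se_out)

    palindromic = rng.random(J) < cfg.prop_palindromic
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), J)
    non_pal_choice = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), J)
    snp_ids = [f"rs{i + 1:06d}" for i in range(J)]

    def _records(beta, se, pval, n):
        recs = []
        for j in range(J):
            ea, oa = (
                _PALINDROMIC_PAIRS[pal_choice[j]]
                if palindromic[j]
                else _NON_PALINDROMIC_PAIRS[non_pal_choice[j]]
            )
            recs.append(
                GwasRecord(
                    snp_id=snp_ids[j],
                    effect_allele=ea,
                    other_allele=oa,
                    beta=float(beta[j]),
                    se=float(se[j]),
                    pval=float(max(pval[j], 1e-320)),
                    eaf=float(maf[j]),
                    n=n,
                )
            )
        return recs

    truth = SimTruth(
        causal_beta=cfg.causal_beta,
        reverse_causal=cfg.reverse_causal,
        maf=maf.tolist(),
        gamma=gamma.tolist(),
        big_gamma=big_gamma.tolist(),
        alpha=alpha.tolist(),
        invalid=invalid.tolist(),
        palindromic=palindromic.tolist(),
        snp_ids=snp_ids,
    )
    return (
        _records(beta_exp, se_exp, p_exp, cfg.n_exp),
        _records(beta_out, se_out, p_out, cfg.n_out),
        truth,
    )


def simulate_ld_table(cfg: SimConfig) -> LdTable:
    """Block-diagonal LD for the simulated SNPs: within-block r² as configured,
    zero across blocks. Positions place blocks 20 Mb apart (well beyond the
    10,000 kb clumping window) with 10 kb spacing inside a block."""
    snp_ids = [f"rs{i + 1:06d}" for i in range(cfg.n_snps)]
    table = LdTable(positions={})
    idx = 0
    block_id = 0
    blocks = list(cfg.ld_blocks)
    while idx < cfg.n_snps:
        size, r2 = blocks.pop(0) if blocks else (1, 0.0)
        members = snp_ids[idx : idx + size]
        for i, a in enumerate(members):
            table.positions[a] = ("1", int(2e7 * block_id + 1e4 * i + 1))
            for b in members[i + 1 :]:
                table.set_r2(a, b, r2)
        idx += size
        block_id += 1
    return table


def write_summary_stats(records: list[GwasRecord], path) -> None:
    """Write records in the canonical TSV layout gwas_io reads back by default."""
    import pandas as pd

    pd.DataFrame(
        {
            "snp": [r.snp_id for r in records],
            "ea": [r.effect_allele for r in records],
            "oa": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "p": [r.pval for r in records],
            "n": [r.n for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
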