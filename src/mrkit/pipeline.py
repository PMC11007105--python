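"""End-to-end orchestration: QC chain, estimators, diagnostics, meta stage.

One pair runs p-threshold selection → LD clumping → exclusion list →
harmonization → F filtering → all five estimators (IVW with multiplicative
random effects flagged primary) → sensitivity diagnostics. A screen runs
every exposure × outcome pair, attaches Bonferroni significance tiers with
an explicit family size, and pools named cohort groups by meta-analysis.
All randomness (the weighted-median bootstrap) derives deterministically
from the config seed and the pair's names, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import estimators as est
from .errors import ConfigurationError, EstimationError
from .gwas_io import GwasRecord, HarmonizedSet, harmonize, read_summary_stats
from .instruments import (
    LdTable,
    apply_exclusion_list,
    clump,
    filter_weak,
    instrument_strength,
    read_exclusion_list,
    select_genome_wide,
)
from .meta_analysis import MetaResult, meta_pool, significance_tier
from .sensitivity import SensitivityReport, sensitivity_report

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "exposure", "outcome", "direction", "status", "method", "n_snp",
    "beta", "se", "pval", "or", "ci_low", "ci_high",
    "egger_intercept", "egger_intercept_se", "egger_intercept_p",
    "q", "q_df", "q_pval", "steiger_dir", "steiger_pval",
    "r2_exposure", "r2_outcome", "significance_tier",
]


class TraitSpec(BaseModel):
    """One trait's summary-statistics source."""

    name: str
    path: str
    n: Optional[int] = None
    cases: Optional[int] = None
    controls: Optional[int] = None
    column_map: Optional[dict[str, str]] = None

    @property
    def total_n(self) -> Optional[int]:
        if self.n is not None:
            return self.n
        if self.cases is not None and self.controls is not None:
            return self.cases + self.controls
        return None


class Thresholds(BaseModel):
    """Analysis thresholds; defaults follow the instrument-QC conventions."""

    p_instrument: float = Field(default=5e-8, gt=0, le=1)
    clump_r2: float = Field(default=0.001, ge=0, le=1)
    clump_window_kb: float = Field(default=10000, gt=0)
    f_min: float = Field(default=10.0, ge=0)
    i2_threshold: float = Field(default=0.30, ge=0, le=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    bonferroni_m: Optional[int] = Field(default=None, ge=1)
    palindrome_policy: Literal["strict_remove", "maf_infer"] = "strict_remove"
    maf_threshold: float = Field(default=0.42, gt=0, lt=0.5)
    n_boot: int = Field(default=1000, ge=0)


class AnalysisConfig(BaseModel):
    """Full configuration of a bidirectional multi-cohort screen."""

    exposures: list[TraitSpec]
    outcomes: list[TraitSpec]
    ld_table: Optional[str] = None
    positions: Optional[str] = None
    exclusion_list: Optional[str] = None
    thresholds: Thresholds = Field(default_factory=Thresholds)
    seed: int
    directions: Literal["forward", "reverse", "both"] = "forward"
    #: meta-analysis groups: group name -> outcome names pooled per exposure
    meta_groups: dict[str, list[str]] = Field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.model_validate(raw)


@dataclass
class PairResult:
    """Everything computed for one exposure-outcome pair in one direction."""

    exposure: str
    outcome: str
    direction: str
    status: str  # "ok" | "not_estimable"
    estimates: dict[str, est.MrEstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    qc_counts: dict[str, int] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)
    harmonized: HarmonizedSet | None = None


def _pair_seed(global_seed: int, exposure: str, outcome: str, direction: str) -> int:
    tag = zlib.crc32(f"{exposure}|{outcome}|{direction}".encode())
    return int(np.random.SeedSequence([global_seed, tag]).generate_state(1)[0] & 0x7FFFFFFF)


def run_pair_records(
    exposure_records: list[GwasRecord],
    outcome_records: list[GwasRecord],
    config: AnalysisConfig,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    direction: str = "forward",
    ld: LdTable | None = None,
    excluded_ids: set[str] | None = None,
    n_exp: int | None = None,
    n_out: int | None = None,
    cases: int | None = None,
    controls: int | None = None,
) -> PairResult:
    """Run the QC chain and all estimators on already-loaded records."""
    t = config.thresholds
    result = PairResult(exposure=exposure_name, outcome=outcome_name, direction=direction, status="ok")
    qc = result.qc_counts
    qc["input"] = len(exposure_records)

    selected = select_genome_wide(exposure_records, t.p_instrument)
    qc["genome_wide"] = len(selected)
    if not selected:
        result.status = "not_estimable"
        result.messages.append("no genome-wide significant SNPs")
        return result

    clumped = clump(selected, ld, t.clump_r2, t.clump_window_kb)
    qc["clumped"] = len(clumped)

    if excluded_ids:
        clumped, dropped = apply_exclusion_list(clumped, excluded_ids)
        result.messages.extend(f"excluded {s}: {r}" for s, r in dropped)
    qc["after_exclusion"] = len(clumped)
    if not clumped:
        result.status = "not_estimable"
        result.messages.append("all instruments on exclusion list")
        return result

    h = harmonize(
        clumped,
        outcome_records,
        palindrome_policy=t.palindrome_policy,
        maf_threshold=t.maf_threshold,
        n_exp=n_exp,
        n_out=n_out,
    )
    qc["harmonized"] = len(h)
    if len(h) == 0:
        result.status = "not_estimable"
        result.messages.append("no SNPs survive harmonization")
        return result

    inst = filter_weak(instrument_strength(h, n_exp=n_exp), t.f_min)
    h = inst.harmonized
    qc["strong"] = len(h)
    result.harmonized = h
    if len(h) < 2:
        result.status = "not_estimable"
        result.messages.append(f"fewer than 2 instruments after QC (J={len(h)})")
        return result

    result.estimates["ivw_mre"] = est.ivw(h, model="mre")
    result.estimates["ivw_fe"] = est.ivw(h, model="fixed")
    try:
        result.estimates["max_likelihood"] = est.max_likelihood(h)
    except EstimationError as exc:
        result.messages.append(f"max_likelihood skipped: {exc}")
    if len(h) >= 3:
        result.estimates["egger"] = est.egger(h)
        wm_seed = _pair_seed(config.seed, exposure_name, outcome_name, direction)
        result.estimates["weighted_median"] = est.weighted_median(h, n_boot=t.n_boot, seed=wm_seed)
    else:
        result.messages.append("egger and weighted_median omitted (J < 3)")

    result.sensitivity = sensitivity_report(h, n_exp=n_exp, n_out=n_out, cases=cases, controls=controls)
    return result


def _load_trait(spec: TraitSpec) -> list[GwasRecord]:
    records, _ = read_summary_stats(spec.path, column_map=spec.column_map, study_n=spec.total_n)
    return records


def run_pair(exposure: TraitSpec, outcome: TraitSpec, config: AnalysisConfig) -> PairResult:
    """Load both traits and run one forward pair."""
    ld = _load_ld(config)
    excluded = read_exclusion_list(config.exclusion_list) if config.exclusion_list else None
    return run_pair_records(
        _load_trait(exposure),
        _load_trait(outcome),
        config,
        exposure_name=exposure.name,
        outcome_name=outcome.name,
        ld=ld,
        excluded_ids=excluded,
        n_exp=exposure.total_n,
        n_out=outcome.total_n,
        cases=outcome.cases,
        controls=outcome.controls,
    )


def run_bidirectional(
    exposure: TraitSpec, outcome: TraitSpec, config: AnalysisConfig
) -> tuple[PairResult, PairResult]:
    """Run a pair in both directions; the reverse re-derives instruments from
    the outcome GWAS under the same thresholds."""
    ld = _load_ld(config)
    excluded = read_exclusion_list(config.exclusion_list) if config.exclusion_list else None
    exp_records = _load_trait(exposure)
    out_records = _load_trait(outcome)
    forward = run_pair_records(
        exp_records, out_records, config,
        exposure_name=exposure.name, outcome_name=outcome.name, direction="forward",
        ld=ld, excluded_ids=excluded,
        n_exp=exposure.total_n, n_out=outcome.total_n,
        cases=outcome.cases, controls=outcome.controls,
    )
    reverse = run_pair_records(
        out_records, exp_records, config,
        exposure_name=outcome.name, outcome_name=exposure.name, direction="reverse",
        ld=ld, excluded_ids=excluded,
        n_exp=outcome.total_n, n_out=exposure.total_n,
        cases=exposure.cases, controls=exposure.controls,
    )
    return forward, reverse


def _load_ld(config: AnalysisConfig) -> LdTable | None:
    if config.ld_table is None:
        return None
    return LdTable.read(config.ld_table, positions_path=config.positions)


def pair_rows(result: PairResult, alpha: float, m: int | None) -> list[dict]:
    """Flatten one PairResult into result-table rows (one per method)."""
    s = result.sensitivity
    base = {
        "exposure": result.exposure,
        "outcome": result.outcome,
        "direction": result.direction,
        "status": result.status,
        "q": s.q if s else float("nan"),
        "q_df": s.q_df if s else 0,
        "q_pval": s.q_pval if s else float("nan"),
        "egger_intercept": s.egger_intercept if s else float("nan"),
        "egger_intercept_se": s.egger_intercept_se if s else float("nan"),
        "egger_intercept_p": s.egger_intercept_pval if s else float("nan"),
        "steiger_dir": "" if s is None or s.steiger_correct_direction is None
        else str(bool(s.steiger_correct_direction)),
        "steiger_pval": s.steiger_pval if s else float("nan"),
        "r2_exposure": s.r2_exposure_total if s else float("nan"),
        "r2_outcome": s.r2_outcome_total if s else float("nan"),
    }
    if not result.estimates:
        row = dict.fromkeys(RESULT_COLUMNS)
        row.update(base)
        row.update(method="none", n_snp=0, significance_tier="")
        return [row]
    rows = []
    for method in ("ivw_mre", "ivw_fe", "egger", "weighted_median", "max_likelihood"):
        e = result.estimates.get(method)
        if e is None:
            continue
        row = dict(base)
        row.update(
            method=method,
            n_snp=e.n_snp,
            beta=e.beta,
            se=e.se,
            pval=e.pval,
            **{"or": e.or_},
            ci_low=e.ci_low,
            ci_high=e.ci_high,
            significance_tier=(
                significance_tier(e.pval, alpha, m)
                if m is not None and method == "ivw_mre" and np.isfinite(e.pval)
                else ""
            ),
        )
        rows.append(row)
    return rows


def run_screen(config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """All exposure × outcome pairs (both directions if configured), plus the
    meta stage pooling named cohort groups. Returns (results, meta, manifest)."""
    t = config.thresholds
    if config.meta_groups or len(config.outcomes) * len(config.exposures) > 1:
        if t.bonferroni_m is None:
            raise ConfigurationError(
                "thresholds.bonferroni_m must be set explicitly for a screen"
            )
    ld = _load_ld(config)
    excluded = read_exclusion_list(config.exclusion_list) if config.exclusion_list else None
    trait_cache = {spec.name: _load_trait(spec) for spec in config.exposures + config.outcomes}

    rows: list[dict] = []
    manifest: dict = {"seed": config.seed, "pairs": {}}
    results_by_pair: dict[tuple[str, str], PairResult] = {}
    for exp in config.exposures:
        for out in config.outcomes:
            directions = (
                ["forward", "reverse"] if config.directions == "both" else [config.directions]
            )
            for direction in directions:
                e_spec, o_spec = (exp, out) if direction == "forward" else (out, exp)
                res = run_pair_records(
                    trait_cache[e_spec.name],
                    trait_cache[o_spec.name],
                    config,
                    exposure_name=e_spec.name,
                    outcome_name=o_spec.name,
                    direction=direction,
                    ld=ld,
                    excluded_ids=excluded,
                    n_exp=e_spec.total_n,
                    n_out=o_spec.total_n,
                    cases=o_spec.cases,
                    controls=o_spec.controls,
                )
                rows.extend(pair_rows(res, t.alpha, t.bonferroni_m))
                if direction == "forward":
                    results_by_pair[(exp.name, out.name)] = res
                manifest["pairs"][f"{e_spec.name}->{o_spec.name}"] = {
                    "direction": direction,
                    "status": res.status,
                    "qc_counts": res.qc_counts,
                    "messages": res.messages,
                }
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)

    meta_rows: list[dict] = []
    for group_name, outcome_names in sorted(config.meta_groups.items()):
        for exp in config.exposures:
            inputs = []
            for name in outcome_names:
                res = results_by_pair.get((exp.name, name))
                if res is not None and "ivw_mre" in res.estimates:
                    inputs.append(res.estimates["ivw_mre"])
            if len(inputs) < 2:
                continue
            pooled: MetaResult = meta_pool(inputs, i2_threshold=t.i2_threshold)
            or_, lo, hi = est.to_odds_ratio(pooled.beta, pooled.se)
            meta_rows.append(
                {
                    "exposure": exp.name,
                    "outcome_group": group_name,
                    "model": pooled.model,
                    "n_cohorts": len(inputs),
                    "beta": pooled.beta,
                    "se": pooled.se,
                    "pval": pooled.pval,
                    "or": or_,
                    "ci_low": lo,
                    "ci_high": hi,
                    "q_meta": pooled.q_meta,
                    "i2": pooled.i2,
                    "tau2": pooled.tau2,
                    "significance_tier": significance_tier(pooled.pval, t.alpha, t.bonferroni_m)
                    if t.bonferroni_m
                    else "",
                }
            )
    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "exposure", "outcome_group", "model", "n_cohorts", "beta", "se", "pval",
            "or", "ci_low", "ci_high", "q_meta", "i2", "tau2", "significance_tier",
        ],
    )
    return results, meta, manifest


def write_screen_outputs(
    results: pd.DataFrame, meta: pd.DataFrame, manifest: dict, out_dir
) -> None:
    """Write results.tsv, meta.tsv and manifest.json with stable formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.10g")
    meta.to_csv(out / "meta.tsv", sep="\t", index=False, float_format="%.10g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
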