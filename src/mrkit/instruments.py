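"""Instrumental-variable selection and quality control.

Candidate instruments for an exposure are its genome-wide significant SNPs
(p < 5e-8), pruned to approximate linkage equilibrium by greedy p-value-ranked
clumping (r² < 0.001 within a 10,000 kb window, PLINK-style), cross-checked
against an offline exclusion list of confounder-associated variants, and
finally screened for instrument strength: per-SNP variance explained
R² = 2·EAF·(1−EAF)·beta² and F = R²·(N−2)/(1−R²), with F < 10 excluded as weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .gwas_io import GwasRecord, HarmonizedSet

logger = logging.getLogger(__name__)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class LdTable:
    """Pairwise LD r² lookup with optional physical positions.

    Pairs not present are treated as r² = 0 (unlinked) and counted so a
    summary warning can be emitted. ``positions`` maps snp_id to
    (chromosome, 1-based bp position); when absent the clumping window test
    is skipped and r² alone decides.
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] | None = None
    _missing: int = field(default=0, repr=False)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise DataError(f"r2({a},{b})={r2} outside [0,1]")
        self.pairs[_pair_key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        val = self.pairs.get(_pair_key(a, b))
        if val is None:
            self._missing += 1
            return 0.0
        return val

    @classmethod
    def read(cls, path, positions_path=None) -> "LdTable":
        """Read a 3-column TSV (snp_a, snp_b, r2), optionally positions (snp, chrom, pos)."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        table = cls()
        for a, b, r2 in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2].astype(float)):
            table.set_r2(str(a), str(b), r2)
        if positions_path is not None:
            pos = pd.read_csv(positions_path, sep="\t", dtype=str)
            table.positions = {
                str(s): (str(c), int(p))
                for s, c, p in zip(pos.iloc[:, 0], pos.iloc[:, 1], pos.iloc[:, 2])
            }
        return table

    def write(self, path) -> None:
        rows = sorted((a, b, r2) for (a, b), r2 in self.pairs.items())
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def select_genome_wide(records: list[GwasRecord], p_threshold: float = 5e-8) -> list[GwasRecord]:
    """Keep SNPs reaching genome-wide significance (pval < threshold), order preserved."""
    return [r for r in records if r.pval < p_threshold]


def clump(
    records: list[GwasRecord],
    ld: LdTable | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10000,
) -> list[GwasRecord]:
    """Greedy p-value-ranked LD clumping.

    Sort SNPs by ascending p-value (ties broken by snp_id so the result is
    independent of input order); repeatedly keep the best remaining SNP and
    discard every other remaining SNP with r² >= ``r2_threshold`` against it
    that also lies within ``window_kb`` of it — the distance test applies only
    when both SNPs have known positions on the same chromosome; otherwise r²
    alone decides. Returns kept SNPs in p-value order.
    """
    if ld is None:
        ld = LdTable()
    pos = ld.positions

    def _within_window(a: str, b: str) -> bool:
        if pos is None:
            return True
        pa, pb = pos.get(a), pos.get(b)
        if pa is None or pb is None:
            return True
        if pa[0] != pb[0]:
            return False
        return abs(pa[1] - pb[1]) <= window_kb * 1000

    remaining = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept: list[GwasRecord] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            r
            for r in remaining
            if not (
                ld.r2(best.snp_id, r.snp_id) >= r2_threshold
                and _within_window(best.snp_id, r.snp_id)
            )
        ]
    if ld._missing:
        logger.debug("clump: %d LD pairs missing from table, treated as r2=0", ld._missing)
    return kept


def apply_exclusion_list(
    records: list[GwasRecord], excluded_ids: set[str]
) -> tuple[list[GwasRecord], list[tuple[str, str]]]:
    """Remove SNPs on an offline exclusion list (confounder-associated variants)."""
    kept = [r for r in records if r.snp_id not in excluded_ids]
    dropped = [(r.snp_id, "confounder-associated") for r in records if r.snp_id in excluded_ids]
    return kept, dropped


def read_exclusion_list(path) -> set[str]:
    """One snp_id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return {
            line.strip() for line in fh if line.strip() and not line.lstrip().startswith("#")
        }


def compute_f_statistic(eaf, beta, n):
    """Per-SNP variance explained and F statistic.

    R² = 2·EAF·(1−EAF)·beta² (beta on the standardized trait scale) and
    F = R²·(N−2)/(1−R²). Vectorized over numpy arrays.
    """
    eaf = np.asarray(eaf, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise DataError("F statistic requires n > 2")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    if np.any(r2 >= 1.0):
        raise DataError("per-SNP R^2 >= 1: beta is not on a standardized scale")
    f = r2 * (n - 2.0) / (1.0 - r2)
    return r2, f


@dataclass
class InstrumentSet:
    """A harmonized set annotated with per-SNP instrument strength.

    ``f_fallback`` flags SNPs whose F came from the (beta/se)² approximation
    because the exposure EAF was unavailable (their r2_exp is NaN).
    """

    harmonized: HarmonizedSet
    r2_exp: np.ndarray
    f_stat: np.ndarray
    f_fallback: np.ndarray

    @property
    def n_snp(self) -> int:
        return len(self.harmonized)


def instrument_strength(h: HarmonizedSet, n_exp: int | None = None) -> InstrumentSet:
    """Compute per-SNP exposure R² and F for a harmonized set.

    Uses the EAF-based formula where the exposure EAF is known and the
    squared-Wald fallback F = (beta/se)² elsewhere.
    """
    n = n_exp if n_exp is not None else h.n_exp
    J = len(h)
    r2 = np.full(J, np.nan)
    f = np.empty(J)
    have_eaf = np.isfinite(h.eaf_exp)
    if have_eaf.any():
        if n is None:
            raise DataError("exposure sample size required for F statistics")
        r2[have_eaf], f[have_eaf] = compute_f_statistic(
            h.eaf_exp[have_eaf], h.beta_exp[have_eaf], n
        )
    fallback = ~have_eaf
    f[fallback] = (h.beta_exp[fallback] / h.se_exp[fallback]) ** 2
    if fallback.any():
        logger.debug("instrument_strength: (beta/se)^2 fallback for %d SNPs", fallback.sum())
    return InstrumentSet(harmonized=h, r2_exp=r2, f_stat=f, f_fallback=fallback)


def filter_weak(inst: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Drop weak instruments (F below ``f_min``); F equal to the bound is kept."""
    keep = inst.f_stat >= f_min
    if keep.all():
        return inst
    return InstrumentSet(
        harmonized=inst.harmonized.subset(keep, "weak instrument"),
        r2_exp=inst.r2_exp[keep],
        f_stat=inst.f_stat[keep],
        f_fallback=inst.f_fallback[keep],
    )
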