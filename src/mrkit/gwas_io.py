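"""Read, validate, and harmonize GWAS summary statistics.

A two-sample MR analysis joins two sets of per-SNP association summaries —
one for the exposure (here: a circulating protein measured in SD units of
the inverse-rank-normalized level) and one for the outcome (log-odds for a
binary disease endpoint) — on variant ID, and aligns both effect sizes to a
shared effect allele. Palindromic variants (A/T or C/G), whose strand cannot
be resolved from allele labels alone, are removed by default; variants whose
allele sets disagree even after considering an effect/other swap are removed
as non-concordant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: canonical short keys for column mapping in config files
COLUMN_KEYS = ("snp", "ea", "oa", "eaf", "beta", "se", "p", "n")
REQUIRED_KEYS = ("snp", "ea", "oa", "beta", "se", "p")

#: identity mapping for files written by :mod:`mrkit.synthetic`
DEFAULT_COLUMN_MAP = {k: k for k in COLUMN_KEYS}


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's summary association for one trait.

    ``beta`` is the per-effect-allele effect: SD units for quantitative
    traits, log-odds for binary ones. ``eaf`` and ``n`` are optional; ``n``
    falls back to a study-level sample size when absent.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def invariant_violation(self) -> str | None:
        """Return a human-readable reason this record is invalid, or None."""
        if self.effect_allele not in NUCLEOTIDES or self.other_allele not in NUCLEOTIDES:
            return "invalid allele"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not np.isfinite(self.beta):
            return "nonfinite beta"
        if not np.isfinite(self.se) or self.se <= 0:
            return "nonpositive se"
        if not (0.0 < self.pval <= 1.0):
            return "pval out of range"
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            return "eaf out of range"
        if self.n is not None and self.n <= 0:
            return "nonpositive n"
        return None


@dataclass
class LoadReport:
    """Accounting of what a summary-statistics read kept and dropped."""

    path: str
    n_read: int = 0
    n_valid: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    pair = {effect_allele, other_allele}
    return pair == {"A", "T"} or pair == {"C", "G"}


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    study_n: int | None = None,
    delimiter: str | None = None,
) -> tuple[list[GwasRecord], LoadReport]:
    """Read a delimited summary-statistics file into validated records.

    Parameters
    ----------
    path : str or path-like
        Tab- or comma-delimited text file with a header row.
    column_map : dict
        Maps canonical keys (snp, ea, oa, eaf, beta, se, p, n) to the file's
        column names. ``eaf`` and ``n`` entries are optional.
    study_n : int, optional
        Study-level sample size used when the file has no per-SNP N column.
    delimiter : str, optional
        Field separator; sniffed from the header when omitted.

    Records violating invariants (non-positive SE, out-of-range EAF or p,
    bad alleles) are dropped and itemized in the returned :class:`LoadReport`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    missing_keys = [k for k in REQUIRED_KEYS if k not in cmap]
    if missing_keys:
        raise ConfigurationError(f"column_map lacks required keys: {missing_keys}")

    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str)

    for key in REQUIRED_KEYS:
        if cmap[key] not in df.columns:
            raise ConfigurationError(
                f"mapped column {cmap[key]!r} (for {key!r}) not in {list(df.columns)}"
            )
    has_eaf = "eaf" in cmap and cmap["eaf"] in df.columns
    has_n = "n" in cmap and cmap["n"] in df.columns

    report = LoadReport(path=str(path), n_read=len(df))
    records: list[GwasRecord] = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        snp = str(row[cmap["snp"]]).strip()
        try:
            rec = GwasRecord(
                snp_id=snp,
                effect_allele=str(row[cmap["ea"]]).strip().upper(),
                other_allele=str(row[cmap["oa"]]).strip().upper(),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pval=float(row[cmap["p"]]),
                eaf=float(row[cmap["eaf"]]) if has_eaf and pd.notna(row[cmap["eaf"]]) else None,
                n=int(float(row[cmap["n"]])) if has_n and pd.notna(row[cmap["n"]]) else study_n,
            )
        except (TypeError, ValueError):
            report.dropped.append((snp, "unparseable numeric field"))
            continue
        reason = rec.invariant_violation()
        if reason is not None:
            report.dropped.append((snp, reason))
            continue
        records.append(rec)

    report.n_valid = len(records)
    if report.n_valid == 0:
        raise DataError(f"no valid records in {path}")
    if report.dropped:
        logger.info("read %s: dropped %d/%d records", path, len(report.dropped), report.n_read)
    return records, report


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a shared effect allele.

    All per-SNP arrays share length J. ``flipped`` marks SNPs whose outcome
    effect sign was inverted to match the exposure's effect allele.
    ``dropped`` lists (snp_id, reason) pairs removed along the way — by
    harmonization itself and, later, by instrument filters that subset the
    same object.
    """

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    eaf_exp: np.ndarray  # NaN where unavailable
    pval_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_out: np.ndarray  # NaN where unavailable
    pval_out: np.ndarray
    flipped: np.ndarray
    n_exp: int | None = None
    n_out: int | None = None
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask: np.ndarray, reason: str) -> "HarmonizedSet":
        """Keep SNPs where ``mask`` is True; log the rest under ``reason``."""
        mask = np.asarray(mask, dtype=bool)
        dropped = list(self.dropped)
        dropped.extend((s, reason) for s, keep in zip(self.snp_ids, mask) if not keep)
        return HarmonizedSet(
            snp_ids=[s for s, keep in zip(self.snp_ids, mask) if keep],
            beta_exp=self.beta_exp[mask],
            se_exp=self.se_exp[mask],
            eaf_exp=self.eaf_exp[mask],
            pval_exp=self.pval_exp[mask],
            beta_out=self.beta_out[mask],
            se_out=self.se_out[mask],
            eaf_out=self.eaf_out[mask],
            pval_out=self.pval_out[mask],
            flipped=self.flipped[mask],
            n_exp=self.n_exp,
            n_out=self.n_out,
            dropped=dropped,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta_exp": self.beta_exp,
                "se_exp": self.se_exp,
                "eaf_exp": self.eaf_exp,
                "pval_exp": self.pval_exp,
                "beta_out": self.beta_out,
                "se_out": self.se_out,
                "eaf_out": self.eaf_out,
                "pval_out": self.pval_out,
                "flipped": self.flipped,
            }
        )

    def report_frame(self) -> pd.DataFrame:
        """Per-SNP action report: retained SNPs plus every drop with reason."""
        rows = [
            {"snp_id": s, "action": "retained_flipped" if f else "retained", "reason": ""}
            for s, f in zip(self.snp_ids, self.flipped)
        ]
        rows.extend({"snp_id": s, "action": "dropped", "reason": r} for s, r in self.dropped)
        return pd.DataFrame(rows, columns=["snp_id", "action", "reason"])


def _index_by_snp(records: list[GwasRecord], label: str) -> dict[str, GwasRecord]:
    index: dict[str, GwasRecord] = {}
    for rec in records:
        if rec.snp_id in index:
            raise DataError(f"duplicate snp_id {rec.snp_id!r} in {label} records")
        index[rec.snp_id] = rec
    return index


def harmonize(
    exposure: list[GwasRecord],
    outcome: list[GwasRecord],
    palindrome_policy: str = "strict_remove",
    maf_threshold: float = 0.42,
    n_exp: int | None = None,
    n_out: int | None = None,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    For each SNP present in both traits: if the outcome's alleles are swapped
    relative to the exposure (effect and other exchanged), the outcome beta is
    negated and its EAF complemented; if the allele sets differ, the SNP is
    dropped as non-concordant. Palindromic SNPs are dropped under
    ``strict_remove`` (default). Under ``maf_infer`` they are retained only
    when both traits report an EAF, both are on the same side of 0.5, and both
    lie outside [maf_threshold, 1 - maf_threshold]; frequency agreement then
    orients the SNP without a sign flip. No strand complementation is ever
    attempted — ambiguity is resolved by removal, not inference.
    """
    if palindrome_policy not in ("strict_remove", "maf_infer"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    exp_index = _index_by_snp(exposure, "exposure")
    out_index = _index_by_snp(outcome, "outcome")
    shared = sorted(set(exp_index) & set(out_index))
    if not shared:
        raise DataError("exposure and outcome share no snp_ids")

    kept: list[tuple[GwasRecord, GwasRecord, bool]] = []
    dropped: list[tuple[str, str]] = []
    for snp in shared:
        e, o = exp_index[snp], out_index[snp]
        if {o.effect_allele, o.other_allele} != {e.effect_allele, e.other_allele}:
            dropped.append((snp, "non-concordant alleles"))
            continue
        if is_palindromic(e.effect_allele, e.other_allele):
            if palindrome_policy == "strict_remove":
                dropped.append((snp, "palindromic"))
                continue
            if e.eaf is None or o.eaf is None:
                dropped.append((snp, "palindromic (no eaf to infer strand)"))
                continue
            same_side = (e.eaf - 0.5) * (o.eaf - 0.5) > 0
            both_informative = (
                min(e.eaf, 1 - e.eaf) < maf_threshold and min(o.eaf, 1 - o.eaf) < maf_threshold
            )
            if not (same_side and both_informative):
                dropped.append((snp, "palindromic (ambiguous frequency)"))
                continue
            # frequencies agree on which allele is which: already aligned
            kept.append((e, o, False))
            continue
        if o.effect_allele == e.effect_allele:
            kept.append((e, o, False))
        else:  # swapped: allele sets identical and not palindromic
            kept.append((e, o, True))

    def _n(records, explicit):
        if explicit is not None:
            return explicit
        ns = [r.n for r in records if r.n is not None]
        return max(ns) if ns else None

    J = len(kept)
    h = HarmonizedSet(
        snp_ids=[e.snp_id for e, _, _ in kept],
        beta_exp=np.array([e.beta for e, _, _ in kept], dtype=float),
        se_exp=np.array([e.se for e, _, _ in kept], dtype=float),
        eaf_exp=np.array([np.nan if e.eaf is None else e.eaf for e, _, _ in kept], dtype=float),
        pval_exp=np.array([e.pval for e, _, _ in kept], dtype=float),
        beta_out=np.array([-o.beta if f else o.beta for _, o, f in kept], dtype=float),
        se_out=np.array([o.se for _, o, _ in kept], dtype=float),
        eaf_out=np.array(
            [np.nan if o.eaf is None else (1 - o.eaf if f else o.eaf) for _, o, f in kept],
            dtype=float,
        ),
        pval_out=np.array([o.pval for _, o, _ in kept], dtype=float),
        flipped=np.array([f for _, _, f in kept], dtype=bool),
        n_exp=_n(exposure, n_exp),
        n_out=_n(outcome, n_out),
        dropped=dropped,
    )
    assert len(shared) == J + len(dropped)
    return h


def records_from_harmonized(h: HarmonizedSet, side: str) -> list[GwasRecord]:
    """Reconstruct per-trait records from an aligned set (aligned A/G alleles).

    Convenience for round-trip checks; allele labels are synthesized since an
    aligned set no longer stores them per trait.
    """
    if side not in ("exposure", "outcome"):
        raise ValueError(side)
    beta = h.beta_exp if side == "exposure" else h.beta_out
    se = h.se_exp if side == "exposure" else h.se_out
    eaf = h.eaf_exp if side == "exposure" else h.eaf_out
    pval = h.pval_exp if side == "exposure" else h.pval_out
    n = h.n_exp if side == "exposure" else h.n_out
    return [
        GwasRecord(
            snp_id=s,
            effect_allele="A",
            other_allele="G",
            beta=float(b),
            se=float(e),
            pval=float(p),
            eaf=None if np.isnan(f) else float(f),
            n=n,
        )
        for s, b, e, p, f in zip(h.snp_ids, beta, se, pval, eaf)
    ]


def write_harmonized(h: HarmonizedSet, path) -> None:
    h.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_harmonization_report(h: HarmonizedSet, path) -> None:
    h.report_frame().to_csv(path, sep="\t", index=False)
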