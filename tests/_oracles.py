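"""Independent brute-force reference implementations.

Deliberately written with plain loops and textbook formulas, sharing no code
with the package, so agreement is evidence of correctness rather than of a
shared mistake.
"""

from __future__ import annotations

import math


def oracle_f_statistic(eaf: float, beta: float, n: int) -> tuple[float, float]:
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    return r2, r2 * (n - 2.0) / (1.0 - r2)


def oracle_ivw(beta_exp, beta_out, se_out):
    """Fixed-effect IVW via explicit ratio/weight loops; returns (beta, se, q)."""
    ratios, weights = [], []
    for bx, by, so in zip(beta_exp, beta_out, se_out):
        ratios.append(by / bx)
        weights.append((bx / so) ** 2)
    sw = sum(weights)
    beta = sum(w * r for w, r in zip(weights, ratios)) / sw
    se = math.sqrt(1.0 / sw)
    q = sum(w * (r - beta) ** 2 for w, r in zip(weights, ratios))
    return beta, se, q


def oracle_egger(beta_exp, beta_out, se_out):
    """Weighted least squares with intercept by the normal equations;
    returns (intercept, slope)."""
    xs, ys, ws = [], [], []
    for bx, by, so in zip(beta_exp, beta_out, se_out):
        s = -1.0 if bx < 0 else 1.0
        xs.append(s * bx)
        ys.append(s * by)
        ws.append(1.0 / so**2)
    sw = sum(ws)
    sx = sum(w * x for w, x in zip(ws, xs))
    sy = sum(w * y for w, y in zip(ws, ys))
    sxx = sum(w * x * x for w, x in zip(ws, xs))
    sxy = sum(w * x * y for w, x, y in zip(ws, xs, ys))
    det = sw * sxx - sx * sx
    intercept = (sxx * sy - sx * sxy) / det
    slope = (sw * sxy - sx * sy) / det
    return intercept, slope


def oracle_weighted_median(ratios, weights):
    """Cumulative-midpoint weighted median with explicit interpolation."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    positions = []
    for _, w in pairs:
        positions.append((cum + w / 2.0) / total)
        cum += w
    if 0.5 <= positions[0]:
        return pairs[0][0]
    for k in range(1, len(pairs)):
        if positions[k] >= 0.5:
            lo_p, hi_p = positions[k - 1], positions[k]
            lo_r, hi_r = pairs[k - 1][0], pairs[k][0]
            return lo_r + (0.5 - lo_p) / (hi_p - lo_p) * (hi_r - lo_r)
    return pairs[-1][0]


def oracle_meta_fixed(betas, ses):
    """Returns (pooled, se, q)."""
    ws = [1.0 / s**2 for s in ses]
    sw = sum(ws)
    pooled = sum(w * b for w, b in zip(ws, betas)) / sw
    se = math.sqrt(1.0 / sw)
    q = sum(w * (b - pooled) ** 2 for w, b in zip(ws, betas))
    return pooled, se, q


def oracle_meta_dl(betas, ses):
    """DerSimonian-Laird; returns (pooled, se, tau2)."""
    pooled_f, _, q = oracle_meta_fixed(betas, ses)
    ws = [1.0 / s**2 for s in ses]
    sw = sum(ws)
    denom = sw - sum(w * w for w in ws) / sw
    tau2 = max(0.0, (q - (len(betas) - 1)) / denom) if denom > 0 else 0.0
    w_star = [1.0 / (s**2 + tau2) for s in ses]
    sws = sum(w_star)
    pooled = sum(w * b for w, b in zip(w_star, betas)) / sws
    return pooled, math.sqrt(1.0 / sws), tau2


def oracle_i_squared(q, df):
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q)


def oracle_clump(snps, r2_lookup, r2_threshold, positions=None, window_kb=10000):
    """Greedy p-ranked clumping, re-derived from the rule statement.

    ``snps`` is a list of (snp_id, pval); ``r2_lookup`` maps frozensets to r².
    Returns the kept snp_ids in selection order.
    """
    pool = sorted(snps, key=lambda t: (t[1], t[0]))
    kept = []
    while pool:
        lead = pool[0]
        kept.append(lead[0])
        survivors = []
        for other in pool[1:]:
            r2 = r2_lookup.get(frozenset((lead[0], other[0])), 0.0)
            in_window = True
            if positions is not None:
                pa, pb = positions.get(lead[0]), positions.get(other[0])
                if pa is not None and pb is not None:
                    in_window = pa[0] == pb[0] and abs(pa[1] - pb[1]) <= window_kb * 1000
            if not (r2 >= r2_threshold and in_window):
                survivors.append(other)
        pool = survivors
    return kept
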