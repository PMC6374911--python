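"""Per-CpG differential methylation testing with permutation-calibrated FDR.

For every CpG covered at least ``min_cov`` times in both samples a 2x2
contingency table (condition x methylated/unmethylated read counts) is
tested with a two-sided Fisher exact test.  The number of true null
hypotheses m0 is estimated with a histogram method and p-values are
adjusted with an m0-adaptive step-up (Benjamini-Hochberg-style) procedure;
sites with adjusted p <= alpha are differentially methylated sites (DMSs).
A sequential Monte-Carlo permutation p-value (hypergeometric redraws with
fixed margins, early stopping after ``h`` exceedances, cap ``max_perm``)
is available as an alternative calibration of the exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

# relative tolerance when comparing hypergeometric point probabilities;
# tables whose probability ties the observed one (within this factor)
# count toward the two-sided p
REL_TOL = 1e-7


@lru_cache(maxsize=1_000_000)
def _hypergeom_pmf(total: int, n_meth: int, n_row_a: int):
    """pmf of a ~ Hypergeom(total, n_meth, n_row_a) over its support.

    Returns (kmin, pmf) where pmf[k - kmin] = P(a = k).
    """
    kmin = max(0, n_row_a - (total - n_meth))
    kmax = min(n_row_a, n_meth)
    k = np.arange(kmin, kmax + 1)
    return kmin, stats.hypergeom.pmf(k, total, n_meth, n_row_a)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int):
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    Rows are the two conditions, columns methylated/unmethylated read
    counts.  The two-sided p sums the hypergeometric probabilities of all
    tables (fixed margins) at most as probable as the observed one.

    Returns ``(p, odds_ratio)`` with ``odds_ratio = a*d / (b*c)``
    (``inf`` when only ``b*c`` is 0, ``nan`` when both products are 0).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    total = a + b + c + d
    if total == 0:
        raise ValueError("all-zero contingency table")
    kmin, pmf = _hypergeom_pmf(total, a + c, a + b)
    p_obs = pmf[a - kmin]
    # normalise by the pmf total so a full-support sum is exactly 1
    p = float(pmf[pmf <= p_obs * (1 + REL_TOL)].sum() / pmf.sum())
    p = min(p, 1.0)
    ad, bc = a * d, b * c
    if bc == 0:
        odds = np.nan if ad == 0 else np.inf
    else:
        odds = ad / bc
    return p, odds


def fisher_exact_vector(a, b, c, d) -> np.ndarray:
    """Vectorised two-sided Fisher p over parallel arrays of counts.

    Reuses cached hypergeometric pmfs; identical margins across sites are
    computed once.
    """
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    out = np.empty(len(a), dtype=float)
    for i in range(len(a)):
        out[i] = fisher_exact_two_sided(int(a[i]), int(b[i]),
                                        int(c[i]), int(d[i]))[0]
    return out


def sequential_permutation_pvalue(table, max_perm: int = 1000, h: int = 10,
                                  rng=None):
    """Sequential Monte-Carlo permutation p-value for a 2x2 table.

    Each permutation redraws the table from the hypergeometric null with
    fixed margins (equivalent to permuting read labels across conditions);
    the test statistic is the exact two-sided p.  Sampling stops once ``h``
    permuted statistics are at most the observed one (exceedances) or after
    ``max_perm`` draws.  The estimate is ``h / n_used`` on early stop, else
    ``(exceed + 1) / (max_perm + 1)``; the result is always in (0, 1].

    Returns ``(p_perm, n_used)``.
    """
    if h > max_perm:
        raise ValueError(f"h={h} exceeds max_perm={max_perm}")
    rng = np.random.default_rng(rng)
    a, b, c, d = (int(x) for x in table)
    total = a + b + c + d
    if total == 0:
        raise ValueError("all-zero contingency table")
    n_meth, n_row_a = a + c, a + b
    kmin, pmf = _hypergeom_pmf(total, n_meth, n_row_a)
    # per-support-point two-sided p, so each redraw is a table lookup
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order]) / pmf.sum()
    p_by_k = np.empty_like(pmf)
    # handle probability ties: every k whose pmf ties gets the same p
    sorted_pmf = pmf[order]
    idx = np.searchsorted(sorted_pmf, sorted_pmf * (1 + REL_TOL),
                          side="right") - 1
    p_by_k[order] = np.minimum(csum[idx], 1.0)
    p_obs = p_by_k[a - kmin]

    exceed, n_used = 0, 0
    block = 128
    while n_used < max_perm:
        take = min(block, max_perm - n_used)
        draws = rng.hypergeometric(n_meth, total - n_meth, n_row_a, size=take)
        p_draws = p_by_k[draws - kmin]
        hits = p_draws <= p_obs * (1 + REL_TOL)
        cum = np.cumsum(hits)
        if exceed + cum[-1] >= h:
            stop_at = int(np.searchsorted(cum, h - exceed)) + 1
            n_used += stop_at
            return h / n_used, n_used
        exceed += int(cum[-1])
        n_used += take
    return (exceed + 1) / (max_perm + 1), n_used


def estimate_m0_histogram(pvals, n_bins: int = 20) -> float:
    """Histogram estimate of the number of true null hypotheses m0.

    With ``n_bins`` equal-width bins over [0, 1], find the smallest bin i
    whose count does not exceed the mean count of bins i..B (the point
    where the p-value histogram flattens into its uniform tail), then
    extrapolate the tail: ``m0 = (B / (B - i + 1)) * count(bins i..B)``.
    Uniform p-values give m0 ~ m.
    """
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        raise ValueError("empty p-value vector")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = len(pvals)
    if m < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} p-values, got {m}")
    counts, _ = np.histogram(pvals, bins=n_bins, range=(0.0, 1.0))
    for i in range(n_bins):
        tail = counts[i:]
        if counts[i] <= tail.mean():
            m0 = (n_bins / (n_bins - i)) * tail.sum()
            return float(min(max(m0, 0.0), m))
    return float(m)


def adjust_adaptive_bh(pvals, m0: float) -> np.ndarray:
    """m0-adaptive step-up adjustment.

    ``p_adj(i) = min over j with p(j) >= p(i) of min(1, m0 * p(j) / rank(j))``.
    With ``m0 = m`` this is exactly the textbook Benjamini-Hochberg
    adjustment; smaller m0 scales every adjusted p down linearly.
    """
    pvals = np.asarray(pvals, dtype=float)
    m = len(pvals)
    if not 0 <= m0 <= m:
        raise ValueError(f"m0={m0} outside [0, {m}]")
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * m0 / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def classify_level(level):
    """Classify methylation level(s): hyper (>= 0.8), hypo (<= 0.2),
    else intermediate."""
    arr = np.asarray(level, dtype=float)
    out = np.where(arr >= 0.8, "hyper",
                   np.where(arr <= 0.2, "hypo", "intermediate"))
    if np.isscalar(level) or arr.ndim == 0:
        return str(out)
    return out


@dataclass
class FdrEstimate:
    """Summary of the FDR calibration of one DMS run."""

    m: int                 # number of tested sites
    m0: float              # estimated true nulls
    bins: np.ndarray       # p-value histogram counts
    alpha: float
    n_dms: int = 0

    def __post_init__(self):
        if not 0 <= self.m0 <= self.m:
            raise ValueError("m0 outside [0, m]")


def call_dms(meth_a, meth_b, min_cov: int = 10, alpha: float = 0.05,
             fdr_mode: str = "adaptive", max_perm: int = 1000, h: int = 10,
             seed=None):
    """Call differentially methylated CpG sites between two methylomes.

    Only sites covered >= ``min_cov`` in *both* samples are tested.
    ``fdr_mode``:

    * ``"adaptive"`` (default) - exact Fisher p, histogram m0, adaptive BH;
    * ``"bh"``       - exact Fisher p, textbook BH (m0 = m);
    * ``"permutation"`` - sequential permutation p per site, then the
      adaptive adjustment on the permutation p-values.

    Returns ``(table, FdrEstimate)``; the table has one row per tested site
    with columns chrom, pos, level_a, level_b, delta (= level_b - level_a),
    p, p_adj, cov_a, cov_b, is_dms.
    """
    if fdr_mode not in ("adaptive", "bh", "permutation"):
        raise ValueError(f"unknown fdr_mode {fdr_mode!r}")
    if meth_a.genome_id and meth_b.genome_id and \
            meth_a.genome_id != meth_b.genome_id:
        raise ValueError("methylomes come from different genomes")

    a = meth_a.df.rename(columns={"meth": "meth_a", "unmeth": "unmeth_a"})
    b = meth_b.df.rename(columns={"meth": "meth_b", "unmeth": "unmeth_b"})
    merged = a.merge(b[["chrom", "pos", "meth_b", "unmeth_b"]],
                     on=["chrom", "pos"], how="inner")
    merged["cov_a"] = merged["meth_a"] + merged["unmeth_a"]
    merged["cov_b"] = merged["meth_b"] + merged["unmeth_b"]
    merged = merged[(merged["cov_a"] >= min_cov) &
                    (merged["cov_b"] >= min_cov)].reset_index(drop=True)
    if len(merged) == 0:
        warnings.warn("no common sites pass the coverage filter",
                      stacklevel=2)
        empty = pd.DataFrame(columns=["chrom", "pos", "level_a", "level_b",
                                      "delta", "p", "p_adj", "cov_a", "cov_b",
                                      "is_dms"])
        return empty, FdrEstimate(0, 0.0, np.zeros(20, dtype=int), alpha)

    merged["level_a"] = merged["meth_a"] / merged["cov_a"]
    merged["level_b"] = merged["meth_b"] / merged["cov_b"]
    merged["delta"] = merged["level_b"] - merged["level_a"]

    p_exact = fisher_exact_vector(merged["meth_a"], merged["unmeth_a"],
                                  merged["meth_b"], merged["unmeth_b"])
    if fdr_mode == "permutation":
        rng = np.random.default_rng(seed)
        p = np.empty(len(merged), dtype=float)
        tables = merged[["meth_a", "unmeth_a", "meth_b",
                         "unmeth_b"]].to_numpy()
        for i, row in enumerate(tables):
            p[i], _ = sequential_permutation_pvalue(row, max_perm=max_perm,
                                                    h=h, rng=rng)
    else:
        p = p_exact

    m = len(p)
    if fdr_mode == "bh":
        m0 = float(m)
    else:
        m0 = estimate_m0_histogram(p) if m >= 20 else float(m)
    p_adj = adjust_adaptive_bh(p, m0)

    table = merged[["chrom", "pos", "level_a", "level_b", "delta",
                    "cov_a", "cov_b"]].copy()
    table["p"] = p
    table["p_adj"] = p_adj
    table["is_dms"] = p_adj <= alpha
    table = table[["chrom", "pos", "level_a", "level_b", "delta", "p",
                   "p_adj", "cov_a", "cov_b", "is_dms"]]
    bins, _ = np.histogram(p, bins=20, range=(0.0, 1.0))
    est = FdrEstimate(m, m0, bins, alpha, n_dms=int(table["is_dms"].sum()))
    return table, est
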