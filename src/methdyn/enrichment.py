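"""Enrichment statistics for DMSs and DMRs.

Covers Fisher odds-ratio enrichment of foreground sites over genomic
compartments, the pairwise-comparison rule for cell-type-specific
methylated sites, DMR enrichment on cell-type-specific sites (control =
the entire pool of such sites), and the binomial TF-binding-site overlap
test against a non-differential control set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import IntervalSet
from .dms import adjust_adaptive_bh, call_dms


@dataclass
class EnrichmentResult:
    label: str
    n_hit_fg: int
    n_fg: int
    n_hit_bg: int
    n_bg: int
    odds_ratio: float
    p: float
    q: float = np.nan          # BH across labels within one report
    fold: float = np.nan       # (fg hit rate) / (bg hit rate)

    def __post_init__(self):
        if self.n_hit_fg > self.n_fg or self.n_hit_bg > self.n_bg:
            raise ValueError("hits exceed totals")

    @property
    def defined(self) -> bool:
        return self.n_fg > 0 and self.n_bg > 0


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    ad, bc = a * d, b * c
    if bc == 0:
        return np.nan if ad == 0 else np.inf
    return ad / bc


def _attach_q(results) -> None:
    defined = [r for r in results if np.isfinite(r.p)]
    if not defined:
        return
    q = adjust_adaptive_bh([r.p for r in defined], m0=len(defined))
    for r, qv in zip(defined, q):
        r.q = float(qv)


def compartment_enrichment(fg_sites: pd.DataFrame, compartments: IntervalSet,
                           bg_sites: pd.DataFrame) -> list:
    """Fisher enrichment of foreground sites per labelled compartment.

    ``fg_sites``/``bg_sites`` are DataFrames with ``chrom`` and ``pos``
    (1-based); the background should be the tested-site universe minus the
    foreground.  A site overlapping several labelled compartments counts
    in each.  Returns one :class:`EnrichmentResult` per label, with BH q
    across labels.
    """
    if len(fg_sites) == 0:
        raise ValueError("empty foreground site set")
    results = []
    for label in sorted(compartments.df["label"].unique()):
        comp = compartments.subset_by_label(label)
        fg_in = int(comp.contains_sites(fg_sites["chrom"].to_numpy(),
                                        fg_sites["pos"].to_numpy()).sum())
        bg_in = int(comp.contains_sites(bg_sites["chrom"].to_numpy(),
                                        bg_sites["pos"].to_numpy()).sum())
        n_fg, n_bg = len(fg_sites), len(bg_sites)
        table = [[fg_in, n_fg - fg_in], [bg_in, n_bg - bg_in]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        fold = np.nan
        if n_bg > 0 and bg_in > 0:
            fold = (fg_in / n_fg) / (bg_in / n_bg)
        results.append(EnrichmentResult(
            label=label, n_hit_fg=fg_in, n_fg=n_fg, n_hit_bg=bg_in,
            n_bg=n_bg, odds_ratio=_odds_ratio(fg_in, n_fg - fg_in, bg_in,
                                              n_bg - bg_in),
            p=float(p), fold=fold))
    _attach_q(results)
    return results


@dataclass
class CellTypeSiteSet:
    """Hyper- and hypo-specific CpG sites for one cell type (1-based
    positions, keyed by chromosome via ``(chrom, pos)`` tuples)."""

    cell_type: str
    hyper_sites: set
    hypo_sites: set

    def __post_init__(self):
        if self.hyper_sites & self.hypo_sites:
            raise ValueError(f"{self.cell_type}: hyper/hypo sets overlap")


def celltype_specific_sites(methylomes: dict, min_cov: int = 10,
                            alpha: float = 0.05, min_frac: float = 0.75,
                            fdr_mode: str = "adaptive") -> dict:
    """Cell-type-specific methylated sites from all pairwise DMS runs.

    All C(k, 2) pairwise comparisons reuse the full DMS machinery.  A site
    is hyper-specific for type T iff it is a DMS with T-higher methylation
    in at least ``min_frac`` of the comparisons involving T in which the
    site was testable (k = 5: 3 of 4); analogous for hypo.  Requires
    k >= 3 methylomes.
    """
    names = list(methylomes)
    if len(names) < 3:
        raise ValueError("need at least 3 methylomes")
    pair_tables = {}
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            table, _ = call_dms(methylomes[na], methylomes[nb],
                                min_cov=min_cov, alpha=alpha,
                                fdr_mode=fdr_mode)
            pair_tables[(na, nb)] = table

    out = {}
    for t in names:
        tested = {}  # (chrom, pos) -> [n_tested, n_hyper, n_hypo]
        for (na, nb), table in pair_tables.items():
            if t not in (na, nb):
                continue
            # delta = level_b - level_a; orient so positive means T higher
            sign = -1.0 if t == na else 1.0
            for chrom, pos, delta, is_dms in zip(
                    table["chrom"], table["pos"], table["delta"],
                    table["is_dms"]):
                rec = tested.setdefault((chrom, pos), [0, 0, 0])
                rec[0] += 1
                if is_dms:
                    if sign * delta > 0:
                        rec[1] += 1
                    elif sign * delta < 0:
                        rec[2] += 1
        hyper = {key for key, (n, nh, _) in tested.items()
                 if n > 0 and nh / n >= min_frac}
        hypo = {key for key, (n, _, nl) in tested.items()
                if n > 0 and nl / n >= min_frac}
        out[t] = CellTypeSiteSet(t, hyper_sites=hyper - hypo,
                                 hypo_sites=hypo - hyper)
    return out


def dmr_enrichment_on_celltype_sites(dmrs, site_sets: dict,
                                     control: str = "pool") -> list:
    """Enrichment of DMRs on each (cell type, direction) site set.

    Foreground = one set's sites; a hit is a site inside >= 1 DMR.  The
    control is the entire pool (union) of cell-type-specific sites; the
    Fisher table contrasts the foreground against the rest of the pool,
    while ``fold`` is the hit-rate ratio against the full pool as plotted.
    Empty sets yield an undefined (NaN) result rather than zero.
    """
    if control != "pool":
        raise ValueError("only the pooled control is supported")
    from .dmr import dmrs_to_intervals
    dmr_iv = dmrs_to_intervals(dmrs)
    pool = set()
    for s in site_sets.values():
        pool |= s.hyper_sites | s.hypo_sites
    pool = sorted(pool)
    if not pool:
        raise ValueError("empty pool of cell-type-specific sites")
    pool_chroms = np.array([c for c, _ in pool])
    pool_pos = np.array([p for _, p in pool])
    pool_hit = dmr_iv.contains_sites(pool_chroms, pool_pos)
    hit_by_site = dict(zip(pool, pool_hit))
    n_pool, n_pool_hit = len(pool), int(pool_hit.sum())

    results = []
    for t in sorted(site_sets):
        for direction in ("hyper", "hypo"):
            sites = (site_sets[t].hyper_sites if direction == "hyper"
                     else site_sets[t].hypo_sites)
            label = f"{t}:{direction}"
            n_fg = len(sites)
            if n_fg == 0:
                results.append(EnrichmentResult(
                    label=label, n_hit_fg=0, n_fg=0, n_hit_bg=n_pool_hit,
                    n_bg=n_pool, odds_ratio=np.nan, p=np.nan))
                continue
            n_hit_fg = sum(bool(hit_by_site[s]) for s in sites)
            rest, rest_hit = n_pool - n_fg, n_pool_hit - n_hit_fg
            if rest > 0:
                _, p = stats.fisher_exact(
                    [[n_hit_fg, n_fg - n_hit_fg],
                     [rest_hit, rest - rest_hit]])
                odds = _odds_ratio(n_hit_fg, n_fg - n_hit_fg, rest_hit,
                                   rest - rest_hit)
            else:
                p, odds = np.nan, np.nan
            fold = np.nan
            if n_pool_hit > 0:
                fold = (n_hit_fg / n_fg) / (n_pool_hit / n_pool)
            results.append(EnrichmentResult(
                label=label, n_hit_fg=n_hit_fg, n_fg=n_fg,
                n_hit_bg=n_pool_hit, n_bg=n_pool, odds_ratio=odds,
                p=float(p) if np.isfinite(p) else p, fold=fold))
    _attach_q(results)
    return results


def tf_overlap_binomial(dms_positions: pd.DataFrame, tf_sites: IntervalSet,
                        control_sites: pd.DataFrame,
                        label: str = "TF") -> EnrichmentResult:
    """Binomial test of DMS overlap with TF binding sites.

    The null hit probability p0 is the fraction of control sites (covered
    but not differentially methylated CpGs) overlapping ``tf_sites``; the
    p-value is the upper binomial tail at the observed DMS overlap count.
    A degenerate p0 = 0 with observed hits is floored at
    ``1 / (2 * n_control)``.
    """
    n_control = len(control_sites)
    if n_control == 0:
        raise ValueError("empty control site set")
    p0 = float(tf_sites.contains_sites(
        control_sites["chrom"].to_numpy(),
        control_sites["pos"].to_numpy()).mean())
    n = len(dms_positions)
    k = int(tf_sites.contains_sites(dms_positions["chrom"].to_numpy(),
                                    dms_positions["pos"].to_numpy()).sum()) \
        if n else 0
    if p0 == 0.0 and k > 0:
        p0 = 1.0 / (2 * n_control)
    p = float(stats.binom.sf(k - 1, n, p0)) if k > 0 else 1.0
    n_hit_bg = int(round(p0 * n_control))
    fold = (k / n) / p0 if (n > 0 and p0 > 0) else np.nan
    return EnrichmentResult(label=label, n_hit_fg=k, n_fg=n,
                            n_hit_bg=min(n_hit_bg, n_control),
                            n_bg=n_control,
                            odds_ratio=np.nan, p=p, fold=fold)
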