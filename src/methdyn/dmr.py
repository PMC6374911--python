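"""Merge differentially methylated sites (DMSs) into regions (DMRs).

Two-step rule set: (1) chain adjacent DMSs at most ``max_gap`` bp apart
into candidate clusters; (2) keep clusters that contain at least
``min_dms`` DMSs, whose DMSs agree in direction for at least ``min_frac``
of members, and in which at least ``min_frac`` of *all* covered CpGs show
a methylation change of at least ``min_delta`` in the majority direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import IntervalSet


@dataclass
class DMRRecord:
    """A differentially methylated region.

    ``start``/``end`` are the 0-based half-open hull of the member DMS
    positions.  ``direction`` is the sign of the majority DMS delta
    (hyper: level_b > level_a).  Consistency fractions refer to criteria
    (2) (member DMSs) and (3) (all covered CpGs in the hull).
    """

    chrom: str
    start: int
    end: int
    n_dms: int
    direction: str
    frac_dms_consistent: float
    frac_cpg_consistent: float
    mean_delta: float
    member_positions: list = field(default_factory=list)

    def __post_init__(self):
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid DMR hull")
        if self.n_dms < 1:
            raise ValueError("DMR without member DMSs")
        if not (0 <= self.frac_dms_consistent <= 1 and
                0 <= self.frac_cpg_consistent <= 1):
            raise ValueError("consistency fraction outside [0, 1]")

    @property
    def width(self) -> int:
        return self.end - self.start


def cluster_dms(dms_table: pd.DataFrame, max_gap: int = 500) -> pd.DataFrame:
    """Chain DMSs into candidate clusters (single linkage on position).

    Consecutive DMSs on the same chromosome whose positions differ by at
    most ``max_gap`` bp join the same cluster; clusters never span
    chromosomes.  Returns the DMS rows (``is_dms`` only, sorted) with an
    added integer ``cluster`` column.
    """
    dms = dms_table[dms_table["is_dms"]] if "is_dms" in dms_table else dms_table
    dms = dms.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if len(dms) == 0:
        dms = dms.copy()
        dms["cluster"] = pd.Series(dtype=np.int64)
        return dms
    new_chrom = dms["chrom"].ne(dms["chrom"].shift())
    gap = dms["pos"].diff()
    breaks = new_chrom | (gap > max_gap)
    dms = dms.copy()
    dms["cluster"] = breaks.cumsum().astype(np.int64) - 1
    return dms


def filter_clusters_to_dmrs(clustered_dms: pd.DataFrame,
                            all_cpg_levels: pd.DataFrame,
                            min_dms: int = 5, min_frac: float = 0.8,
                            min_delta: float = 0.1) -> list:
    """Apply the DMR criteria to candidate clusters.

    ``all_cpg_levels`` must provide ``chrom``, ``pos`` and ``delta`` for
    every covered CpG (DMS or not) so criterion (3) can be evaluated over
    the full hull; the tested-site table from :func:`methdyn.dms.call_dms`
    has this shape.  CpGs missing in either sample are absent from that
    table and hence excluded from the criterion-(3) denominator.

    A cluster becomes a DMR iff (1) it has >= ``min_dms`` member DMSs,
    (2) >= ``min_frac`` of member DMSs change in the majority direction and
    (3) >= ``min_frac`` of all covered CpGs in the hull change by at least
    ``min_delta`` in the majority direction.  An exact 50/50 direction
    split cannot reach ``min_frac`` and is rejected.
    """
    dmrs = []
    if len(clustered_dms) == 0:
        return dmrs
    all_sorted = all_cpg_levels.sort_values(["chrom", "pos"],
                                            kind="mergesort")
    by_chrom = {c: sub for c, sub in all_sorted.groupby("chrom", sort=False)}
    for _, cluster in clustered_dms.groupby("cluster", sort=True):
        n_dms = len(cluster)
        if n_dms < min_dms:
            continue
        deltas = cluster["delta"].to_numpy()
        n_hyper = int((deltas > 0).sum())
        n_hypo = int((deltas < 0).sum())
        if n_hyper == n_hypo:
            continue  # tie: majority cannot reach min_frac
        direction = "hyper" if n_hyper > n_hypo else "hypo"
        sign = 1.0 if direction == "hyper" else -1.0
        frac_dms = max(n_hyper, n_hypo) / n_dms
        if frac_dms < min_frac:
            continue
        chrom = cluster["chrom"].iloc[0]
        lo, hi = int(cluster["pos"].min()), int(cluster["pos"].max())
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        i0 = np.searchsorted(pos, lo, side="left")
        i1 = np.searchsorted(pos, hi, side="right")
        hull = sub.iloc[i0:i1]
        hull_delta = hull["delta"].to_numpy()
        n_cpg = len(hull_delta)
        if n_cpg == 0:
            continue
        consistent = (sign * hull_delta) >= min_delta
        frac_cpg = consistent.sum() / n_cpg
        if frac_cpg < min_frac:
            continue
        dmrs.append(DMRRecord(
            chrom=chrom, start=lo - 1, end=hi, n_dms=n_dms,
            direction=direction, frac_dms_consistent=float(frac_dms),
            frac_cpg_consistent=float(frac_cpg),
            mean_delta=float(deltas.mean()),
            member_positions=[int(p) for p in cluster["pos"]]))
    return dmrs


def call_dmrs(dms_table: pd.DataFrame, max_gap: int = 500, min_dms: int = 5,
              min_frac: float = 0.8, min_delta: float = 0.1) -> list:
    """Convenience wrapper: cluster + filter, straight from a DMS table."""
    clustered = cluster_dms(dms_table, max_gap=max_gap)
    return filter_clusters_to_dmrs(clustered, dms_table, min_dms=min_dms,
                                   min_frac=min_frac, min_delta=min_delta)


def dmrs_to_intervals(dmrs) -> IntervalSet:
    rows = [(r.chrom, r.start, r.end, ".", r.direction) for r in dmrs]
    return IntervalSet(pd.DataFrame(rows, columns=IntervalSet._COLUMNS),
                       name="DMRs")


def associate_dmrs_with_genes(dmrs, genes, upstream: int = 10000) -> dict:
    """Map genes to DMRs overlapping the gene body or the strand-aware
    ``upstream`` bp window before the TSS.

    Returns ``{gene_id: [DMRRecord, ...]}`` for genes with >= 1 DMR.
    """
    out = {}
    for gene in genes:
        window = gene.body_with_upstream(upstream)
        hits = [r for r in dmrs
                if r.chrom == window.chrom
                and r.start < window.end and r.end > window.start]
        if hits:
            out[gene.gene_id] = hits
    return out


def promoter_dmr_genes(dmrs, genes, direction=None,
                       promoter_width: int = 2000) -> list:
    """Genes whose promoter ((TSS - width .. TSS], strand-aware) intersects
    at least one DMR, optionally restricted to one direction."""
    if direction is not None:
        dmrs = [r for r in dmrs if r.direction == direction]
    out = []
    for gene in genes:
        prom = gene.promoter(promoter_width)
        if any(r.chrom == prom.chrom and r.start < prom.end
               and r.end > prom.start for r in dmrs):
            out.append(gene.gene_id)
    return out
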