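"""Anchored and scaled methylation metaprofiles.

Three curve families: (i) enhancer/anchor-centred mean +/- SEM methylation
profiles (site-level averaging, so the SEM band is over sites); (ii) DMS
frequency around anchors normalised to the genome-average DMS rate; (iii)
TSS..TES-scaled gene-body profiles with absolute-bp flanks, read-count
weighted, stratified by expression group (not expressed + terciles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IntervalSet, Methylome


@dataclass
class ProfileCurve:
    anchor_mode: str              # "center" or "tss_tes_scaled"
    bin_edges: np.ndarray
    mean: np.ndarray              # NaN for empty bins
    sem: np.ndarray
    n_sites: np.ndarray
    segments: dict = None         # for scaled profiles: bin-range per segment

    def __post_init__(self):
        ok = ~np.isnan(self.mean)
        if np.any((self.mean[ok] < 0) | (self.mean[ok] > 1)):
            raise ValueError("mean level outside [0, 1]")
        if np.any(self.sem[~np.isnan(self.sem)] < 0):
            raise ValueError("negative SEM")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start": self.bin_edges[:-1],
                             "bin_end": self.bin_edges[1:],
                             "mean": self.mean, "sem": self.sem,
                             "n_sites": self.n_sites})


@dataclass
class FrequencyCurve:
    bin_edges: np.ndarray
    fraction: np.ndarray          # DMS / tested per bin (NaN when no sites)
    genome_average: float
    normalized: np.ndarray        # fraction / genome_average

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start": self.bin_edges[:-1],
                             "bin_end": self.bin_edges[1:],
                             "fraction": self.fraction,
                             "normalized": self.normalized})


def _anchor_offsets(positions: pd.DataFrame, anchors: IntervalSet,
                    flank: int):
    """Signed offsets of 1-based site positions from each anchor center.

    A site near several anchors contributes once per anchor.  Minus-strand
    anchors flip the offset sign; '.' anchors are unoriented.
    """
    offsets, row_idx = [], []
    pos_by_chrom = {}
    for c, sub in positions.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        pos_by_chrom[c] = (sub.index.to_numpy(), sub["pos"].to_numpy())
    for anchor in anchors.df.itertuples(index=False):
        if anchor.chrom not in pos_by_chrom:
            continue
        idx, pos = pos_by_chrom[anchor.chrom]
        center = (anchor.start + anchor.end) // 2
        pos0 = pos - 1
        lo = np.searchsorted(pos0, center - flank, side="left")
        hi = np.searchsorted(pos0, center + flank, side="right")
        off = pos0[lo:hi] - center
        if anchor.strand == "-":
            off = -off
        offsets.append(off)
        row_idx.append(idx[lo:hi])
    if not offsets:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    return np.concatenate(offsets), np.concatenate(row_idx)


def anchored_methylation_profile(methylome: Methylome, anchors: IntervalSet,
                                 flank: int = 5000, n_bins: int = 50,
                                 min_cov: int = 5) -> ProfileCurve:
    """Mean +/- SEM methylation level in signed-offset bins around anchor
    centers.  Empty bins carry NaN mean and n_sites 0."""
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    df = methylome.df.copy().reset_index(drop=True)
    cov = methylome.coverage
    lev = methylome.levels
    keep = cov >= max(min_cov, 1)
    sites = df[keep].reset_index(drop=True)
    levels = lev[keep]
    offsets, rows = _anchor_offsets(sites[["chrom", "pos"]], anchors, flank)
    edges = np.linspace(-flank, flank, n_bins + 1)
    which = np.clip(np.digitize(offsets, edges) - 1, 0, n_bins - 1)
    vals = levels[rows]
    n = np.bincount(which, minlength=n_bins).astype(np.int64)
    s1 = np.bincount(which, weights=vals, minlength=n_bins)
    s2 = np.bincount(which, weights=vals ** 2, minlength=n_bins)
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    nz = n > 0
    mean[nz] = s1[nz] / n[nz]
    two = n > 1
    var = np.zeros(n_bins)
    var[two] = np.maximum(s2[two] - n[two] * mean[two] ** 2, 0.0) / (n[two] - 1)
    sem[two] = np.sqrt(var[two] / n[two])
    sem[n == 1] = 0.0
    return ProfileCurve("center", edges, mean, sem, n)


def dms_frequency_profile(dms_positions: pd.DataFrame,
                          all_tested_sites: pd.DataFrame,
                          anchors: IntervalSet, flank: int = 5000,
                          n_bins: int = 50) -> FrequencyCurve:
    """Per-bin DMS fraction around anchors, normalised to the genome
    average (|DMS| / |tested| over all tested sites)."""
    if len(dms_positions) == 0:
        raise ValueError("no DMSs: normalisation undefined")
    genome_average = len(dms_positions) / len(all_tested_sites)
    edges = np.linspace(-flank, flank, n_bins + 1)

    def _bin(positions):
        off, _ = _anchor_offsets(positions.reset_index(drop=True), anchors,
                                 flank)
        which = np.clip(np.digitize(off, edges) - 1, 0, n_bins - 1)
        return np.bincount(which, minlength=n_bins).astype(float)

    n_tested = _bin(all_tested_sites[["chrom", "pos"]])
    n_dms = _bin(dms_positions[["chrom", "pos"]])
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = n_dms / n_tested
    fraction[n_tested == 0] = np.nan
    return FrequencyCurve(edges, fraction, genome_average,
                          fraction / genome_average)


def scaled_gene_profile(methylome: Methylome, genes, context="CpG",
                        flank: int = 100_000, body_bins: int = 60,
                        flank_bins: int = 50, min_cov: int = 1) -> ProfileCurve:
    """TSS..TES-scaled metagene methylation profile.

    The gene body is linearly rescaled to ``body_bins`` bins between TSS
    and TES (strand-aware, TSS always on the left); flanks are binned in
    absolute bp.  Per-bin level is read-count weighted:
    sum(meth) / sum(meth + unmeth) over the sites in the bin.  ``context``
    may be "CpG" or "CH" (= CHG + CHH, both strands combined relative to
    gene orientation).
    """
    contexts = {"CpG"} if context == "CpG" else {"CHG", "CHH"}
    df = methylome.df[methylome.df["context"].isin(contexts)]
    cov = (df["meth"] + df["unmeth"]).to_numpy()
    df = df[cov >= max(min_cov, 1)]
    n_bins = 2 * flank_bins + body_bins
    sum_meth = np.zeros(n_bins)
    sum_cov = np.zeros(n_bins)
    n_sites = np.zeros(n_bins, dtype=np.int64)
    lev_s1 = np.zeros(n_bins)
    lev_s2 = np.zeros(n_bins)
    flank_bp = flank / flank_bins
    by_chrom = {c: sub.reset_index(drop=True)
                for c, sub in df.groupby("chrom", sort=False)}
    for gene in genes:
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = min(gene.tss, gene.tes) - flank
        hi = max(gene.tss, gene.tes) + flank
        i0 = np.searchsorted(pos, lo, side="left")
        i1 = np.searchsorted(pos, hi, side="right")
        if i0 == i1:
            continue
        p = pos[i0:i1].astype(float)
        # signed coordinate along transcription direction
        if gene.strand == "+":
            t = p - gene.tss
            body_len = gene.tes - gene.tss + 1
        else:
            t = gene.tss - p
            body_len = gene.tss - gene.tes + 1
        which = np.empty(len(t), dtype=np.int64)
        up = t < 0
        down = t >= body_len
        body = ~up & ~down
        which[up] = np.clip(flank_bins + np.floor(t[up] / flank_bp),
                            0, flank_bins - 1).astype(np.int64)
        which[body] = flank_bins + np.minimum(
            (t[body] / body_len * body_bins).astype(np.int64), body_bins - 1)
        which[down] = flank_bins + body_bins + np.clip(
            np.floor((t[down] - body_len) / flank_bp), 0,
            flank_bins - 1).astype(np.int64)
        meth = sub["meth"].to_numpy()[i0:i1].astype(float)
        unmeth = sub["unmeth"].to_numpy()[i0:i1].astype(float)
        lv = meth / (meth + unmeth)
        np.add.at(sum_meth, which, meth)
        np.add.at(sum_cov, which, meth + unmeth)
        np.add.at(n_sites, which, 1)
        np.add.at(lev_s1, which, lv)
        np.add.at(lev_s2, which, lv ** 2)
    mean = np.full(n_bins, np.nan)
    nz = sum_cov > 0
    mean[nz] = sum_meth[nz] / sum_cov[nz]
    sem = np.full(n_bins, np.nan)
    two = n_sites > 1
    site_mean = np.where(n_sites > 0, lev_s1 / np.maximum(n_sites, 1), np.nan)
    var = np.zeros(n_bins)
    var[two] = np.maximum(lev_s2[two] - n_sites[two] * site_mean[two] ** 2,
                          0.0) / (n_sites[two] - 1)
    sem[two] = np.sqrt(var[two] / n_sites[two])
    sem[n_sites == 1] = 0.0
    edges = np.arange(n_bins + 1, dtype=float)
    segments = {"upstream": (0, flank_bins),
                "body": (flank_bins, flank_bins + body_bins),
                "downstream": (flank_bins + body_bins, n_bins)}
    return ProfileCurve("tss_tes_scaled", edges, mean, sem, n_sites,
                        segments=segments)


def expression_groups(expr, genes=None,
                      not_expressed_below: float = 1.0) -> pd.Series:
    """Partition genes into {none, low, mid, high} by expression.

    ``expr`` is a Series (gene -> TPM) or a gene x sample DataFrame (row
    means are used).  Genes below ``not_expressed_below`` are "none"; the
    rest are ranked (ties broken by gene id, stable) and split into three
    terciles, the lowest tercile absorbing the remainder first
    (301 expressed -> 101 low / 100 mid / 100 high).
    """
    if isinstance(expr, pd.DataFrame):
        expr = expr.mean(axis=1)
    if genes is not None:
        ids = [g.gene_id if hasattr(g, "gene_id") else g for g in genes]
        expr = expr.reindex(ids).fillna(0.0)
    labels = pd.Series("none", index=expr.index, dtype=object)
    expressed = expr[expr >= not_expressed_below]
    order = expressed.to_frame("tpm").reset_index()
    order = order.sort_values(["tpm", order.columns[0]],
                              kind="mergesort")
    ranked_ids = order.iloc[:, 0].to_numpy()
    parts = np.array_split(ranked_ids, 3)
    for ids_part, name in zip(parts, ("low", "mid", "high")):
        labels.loc[ids_part] = name
    return labels


def fold_change_filter(expr_a: pd.Series, expr_b: pd.Series,
                       min_fc: float = 1.5,
                       pseudocount: float = 0.0) -> list:
    """Genes whose expression changes by a factor >= ``min_fc``.

    The boundary is inclusive (fc exactly ``min_fc`` passes).  With the
    default pseudocount 0, a gene silent in both samples is excluded
    (undefined ratio) and a gene expressed in exactly one sample is
    included (infinite fold change).
    """
    a = expr_a.astype(float) + pseudocount
    b = expr_b.reindex(expr_a.index).astype(float) + pseudocount
    out = []
    log_min = np.log(min_fc) - 1e-12
    for gene in expr_a.index:
        va, vb = a[gene], b[gene]
        if va == 0 and vb == 0:
            continue
        if va == 0 or vb == 0:
            out.append(gene)
            continue
        if abs(np.log(vb / va)) >= log_min:
            out.append(gene)
    return out
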