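"""Co-methylation module discovery across a methylome panel.

A transparent re-implementation of the weighted correlation-network
workflow: signed-free (unsigned) correlation adjacency raised to a soft
threshold, topological overlap similarity, average-linkage hierarchical
clustering with a static cut, eigen-profile (first principal component)
summaries, and merging of modules with highly correlated eigen-profiles.
An optional blockwise mode pre-partitions large inputs with k-means and
merges modules across blocks.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import MethylomePanel


@dataclass
class DmsMatrix:
    """Preprocessed DMS-locus x methylome level matrix (no missing values).

    Row index encodes the merged locus as ``chrom:start-end`` (0-based
    half-open hull).  ``provenance`` records how many loci each
    preprocessing step removed.
    """

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("DmsMatrix must not contain missing values")
        if len(self.values) < 2 or self.values.shape[1] < 3:
            raise ValueError("need >= 2 loci and >= 3 methylomes")


def locus_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def parse_locus_id(locus: str):
    m = re.match(r"^(.+):(\d+)-(\d+)$", locus)
    if not m:
        raise ValueError(f"malformed locus id {locus!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


def preprocess_dms_matrix(dms_positions: pd.DataFrame, genes,
                          panel: MethylomePanel, merge_gap: int = 200,
                          upstream: int = 10000) -> DmsMatrix:
    """DMS preprocessing ahead of network clustering.

    Steps: (1) keep DMSs within the strand-aware window TSS - ``upstream``
    .. TES of at least one gene; (2) chain-merge loci at most ``merge_gap``
    bp apart, the merged level being the coverage-weighted mean of member
    sites per methylome; (3) drop loci with missing data in any methylome.
    """
    prov = {"n_input": len(dms_positions)}
    if len(dms_positions) == 0:
        raise ValueError("empty DMS set")
    windows = [g.body_with_upstream(upstream) for g in genes]
    chroms = dms_positions["chrom"].to_numpy()
    pos = dms_positions["pos"].to_numpy()
    keep = np.zeros(len(pos), dtype=bool)
    for w in windows:
        keep |= (chroms == w.chrom) & (pos - 1 >= w.start) & (pos - 1 < w.end)
    prov["n_in_gene_window"] = int(keep.sum())
    if not keep.any():
        raise ValueError("no DMS within TSS-10kb..TES of any gene")
    sel = (dms_positions[keep].sort_values(["chrom", "pos"])
           .reset_index(drop=True))

    # chain-merge within merge_gap
    brk = sel["chrom"].ne(sel["chrom"].shift()) | \
        (sel["pos"].diff() > merge_gap)
    sel["locus"] = brk.cumsum() - 1
    rows, index = [], []
    for _, grp in sel.groupby("locus"):
        chrom = grp["chrom"].iloc[0]
        lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
        key = [(chrom, p) for p in grp["pos"]]
        lev = panel.levels.reindex(key)
        cov = panel.coverage.reindex(key).fillna(0)
        weighted = (lev * cov).sum(axis=0, skipna=True)
        wsum = cov.where(lev.notna(), 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            merged = weighted / wsum
        merged[wsum == 0] = np.nan
        rows.append(merged)
        index.append(locus_id(chrom, lo - 1, hi))
    values = pd.DataFrame(rows, index=index)
    prov["n_merged_loci"] = len(values)
    values = values.dropna(axis=0, how="any")
    prov["n_complete_loci"] = len(values)
    if len(values) == 0:
        raise ValueError("all loci removed by the missing-data filter")
    return DmsMatrix(values=values, provenance=prov)


def correlation_adjacency(matrix, power: int = 6) -> np.ndarray:
    """Unsigned soft-threshold adjacency ``|corr|^power`` between loci."""
    x = matrix.values if isinstance(matrix, DmsMatrix) else matrix
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant row {bad}: correlation undefined")
    corr = np.corrcoef(x)
    adj = np.abs(np.clip(corr, -1.0, 1.0)) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity.

    ``TOM(i,j) = (sum_u a(i,u) a(u,j) + a(i,j))
    / (min(k_i, k_j) + 1 - a(i,j))`` with ``k`` the connectivity (row sum
    excluding the diagonal); ``TOM(i,i) = 1``.
    """
    a = np.asarray(adjacency, dtype=float)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    shared = a0 @ a0
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    tom = (shared + a0) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


@dataclass
class ModuleAssignment:
    """Locus -> module labels (0 = unassigned) with eigen-profiles.

    ``eigenprofiles[module]`` is the unit-norm first principal component of
    the module's row-standardised submatrix across methylomes, oriented to
    correlate positively with the module mean profile.
    """

    index: list
    labels: np.ndarray
    eigenprofiles: dict = field(default_factory=dict)

    @property
    def sizes(self) -> dict:
        labels, counts = np.unique(self.labels[self.labels > 0],
                                   return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def loci_of(self, module: int) -> list:
        return [l for l, m in zip(self.index, self.labels) if m == module]


def _standardise(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


def _eigenprofile(x: np.ndarray) -> np.ndarray:
    z = _standardise(x)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    return e / np.linalg.norm(e)


def detect_modules(tom: np.ndarray, matrix, min_module_size: int = 30,
                   cut_height: float = 0.75) -> ModuleAssignment:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters smaller than ``min_module_size`` stay unassigned (label 0);
    surviving modules are labelled 1..K by decreasing size and receive
    eigen-profiles.
    """
    x = matrix.values if isinstance(matrix, DmsMatrix) else matrix
    index = list(x.index) if isinstance(x, pd.DataFrame) else \
        list(range(len(x)))
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < min_module_size:
        warnings.warn("fewer loci than min_module_size: nothing assignable",
                      stacklevel=2)
        return ModuleAssignment(index, np.zeros(n, dtype=int))
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    order = sorted(((raw == c).sum(), c) for c in np.unique(raw))[::-1]
    next_label = 1
    for size, c in order:
        if size >= min_module_size:
            labels[raw == c] = next_label
            next_label += 1
    eigen = {m: _eigenprofile(x[labels == m])
             for m in range(1, next_label)}
    return ModuleAssignment(index, labels, eigen)


def merge_close_modules(assignment: ModuleAssignment, matrix,
                        merge_corr: float = 0.75) -> ModuleAssignment:
    """Iteratively merge module pairs whose eigen-profiles correlate at
    least ``merge_corr``, largest correlation first (ties: smaller module
    id), recomputing eigen-profiles after each merge."""
    x = matrix.values if isinstance(matrix, DmsMatrix) else matrix
    x = np.asarray(x, dtype=float)
    labels = assignment.labels.copy()
    eigen = dict(assignment.eigenprofiles)
    while True:
        mods = sorted(eigen)
        best = None
        for i, ma in enumerate(mods):
            for mb in mods[i + 1:]:
                c = float(np.corrcoef(eigen[ma], eigen[mb])[0, 1])
                if c >= merge_corr and (best is None or c > best[0]):
                    best = (c, ma, mb)
        if best is None:
            break
        _, ma, mb = best
        labels[labels == mb] = ma
        eigen.pop(mb)
        eigen[ma] = _eigenprofile(x[labels == ma])
    # relabel 1..K by decreasing size
    out = np.zeros_like(labels)
    new_eigen = {}
    order = sorted(((labels == m).sum(), -m) for m in eigen)[::-1]
    for new, (_, neg_m) in enumerate(order, start=1):
        m = -neg_m
        out[labels == m] = new
        new_eigen[new] = eigen[m]
    return ModuleAssignment(assignment.index, out, new_eigen)


def module_profile_summary(assignment: ModuleAssignment,
                           matrix) -> pd.DataFrame:
    """Tidy per-module methylation summary: mean and sd of member-locus
    levels for each methylome."""
    x = matrix.values if isinstance(matrix, DmsMatrix) else matrix
    if not isinstance(x, pd.DataFrame):
        x = pd.DataFrame(np.asarray(x, dtype=float))
    rows = []
    for m in sorted(assignment.sizes):
        sub = x.iloc[assignment.labels == m]
        for col in x.columns:
            rows.append({"module": m, "methylome": col,
                         "mean": float(sub[col].mean()),
                         "sd": float(sub[col].std(ddof=0)),
                         "n_loci": len(sub)})
    return pd.DataFrame(rows)


def detect_modules_blockwise(matrix, max_block: int = 2000,
                             min_module_size: int = 30,
                             cut_height: float = 0.75, power: int = 6,
                             merge_corr: float = 0.75) -> ModuleAssignment:
    """Two-level clustering for large inputs.

    Loci are pre-partitioned into blocks of at most ~``max_block`` rows by
    k-means on their level profiles; modules are detected per block and
    then merged across blocks by eigen-profile correlation.  Deterministic
    (fixed k-means seeding).  Single-block inputs skip the pre-clustering.
    """
    x = matrix.values if isinstance(matrix, DmsMatrix) else matrix
    index = list(x.index) if isinstance(x, pd.DataFrame) else \
        list(range(len(x)))
    arr = np.asarray(x, dtype=float)
    n = len(arr)
    if n <= max_block:
        adjacency = correlation_adjacency(arr, power=power)
        assignment = detect_modules(topological_overlap(adjacency), arr,
                                    min_module_size=min_module_size,
                                    cut_height=cut_height)
        merged = merge_close_modules(assignment, arr, merge_corr=merge_corr)
        return ModuleAssignment(index, merged.labels, merged.eigenprofiles)
    from scipy.cluster.vq import kmeans2
    n_blocks = int(np.ceil(n / max_block))
    _, block_of = kmeans2(_standardise(arr), n_blocks, seed=0,
                          minit="++")
    labels = np.zeros(n, dtype=int)
    eigen = {}
    next_label = 1
    for b in range(n_blocks):
        sel = np.flatnonzero(block_of == b)
        if len(sel) < min_module_size:
            continue
        sub = arr[sel]
        try:
            adjacency = correlation_adjacency(sub, power=power)
        except ValueError:
            continue
        asg = detect_modules(topological_overlap(adjacency), sub,
                             min_module_size=min_module_size,
                             cut_height=cut_height)
        for m in sorted(asg.sizes):
            labels[sel[asg.labels == m]] = next_label
            eigen[next_label] = asg.eigenprofiles[m]
            next_label += 1
    combined = ModuleAssignment(index, labels, eigen)
    return merge_close_modules(combined, arr, merge_corr=merge_corr)
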