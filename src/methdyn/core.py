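"""Core genomic data types and coordinate conventions.

Conventions used throughout the package:

* Cytosine positions are **1-based** plus-strand reference coordinates
  (the Bismark cytosine-report dialect).
* All intervals (BED and in-memory) are **0-based half-open** ``[start, end)``.
* Conversion between the two happens only through :func:`to_zero_based` /
  :func:`to_one_based`.  A 1-based cytosine at position ``p`` lies inside a
  BED interval ``[s, e)`` iff ``s < p <= e``.
* CpG methylation is symmetric across the dyad; CpG analyses operate on
  dyad-merged plus-strand records (:func:`merge_symmetric_cpg`).  CH
  methylation is asymmetric and keeps strands separate.
* A site with coverage 0 (or absent from a sample) is *missing*; this is
  distinct from a methylation level of 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("CpG", "CHG", "CHH")
CH_CONTEXTS = ("CHG", "CHH")

_METHYLOME_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]


def to_zero_based(pos):
    """1-based cytosine position(s) -> 0-based coordinate(s)."""
    return np.asarray(pos) - 1


def to_one_based(pos0):
    """0-based coordinate(s) -> 1-based cytosine position(s)."""
    return np.asarray(pos0) + 1


@dataclass(frozen=True)
class CytosineSite:
    """A single cytosine with bisulfite read counts.

    ``meth``/``unmeth`` are read counts supporting the methylated and
    unmethylated state.  The methylation level ``meth / (meth + unmeth)``
    is defined only for covered sites.
    """

    chrom: str
    pos: int  # 1-based plus-strand reference position
    strand: str  # '+' or '-'
    context: str  # 'CpG', 'CHG' or 'CHH'
    meth: int
    unmeth: int

    def __post_init__(self):
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth

    @property
    def level(self):
        """Methylation level in [0, 1], or None for an uncovered site."""
        cov = self.coverage
        if cov == 0:
            return None
        return self.meth / cov


class Methylome:
    """Ordered per-cytosine methylation counts for one sample.

    Sites are stored in a DataFrame sorted by ``(chrom, pos, strand)`` and
    unique on that key.  Interval queries use the package-wide coordinate
    convention (see module docstring).
    """

    def __init__(self, df: pd.DataFrame, name: str = "", genome_id: str = "",
                 validate: bool = True):
        df = df.loc[:, _METHYLOME_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["meth"] = df["meth"].astype(np.int64)
        df["unmeth"] = df["unmeth"].astype(np.int64)
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        df = df.reset_index(drop=True)
        if validate:
            if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
                raise ValueError("negative read counts in methylome")
            if not df["strand"].isin(["+", "-"]).all():
                raise ValueError("invalid strand in methylome")
            if not df["context"].isin(CONTEXTS).all():
                raise ValueError("invalid context in methylome")
            if df.duplicated(["chrom", "pos", "strand"]).any():
                dup = df[df.duplicated(["chrom", "pos", "strand"])].iloc[0]
                raise ValueError(
                    f"duplicate site {dup['chrom']}:{dup['pos']}{dup['strand']}")
        self.df = df
        self.name = name
        self.genome_id = genome_id

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"Methylome({self.name!r}, {len(self)} sites)"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Methylome):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def coverage(self) -> np.ndarray:
        return (self.df["meth"] + self.df["unmeth"]).to_numpy()

    @property
    def levels(self) -> np.ndarray:
        """Per-site level; NaN where coverage is 0 (missing)."""
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lev = self.df["meth"].to_numpy() / cov
        lev[cov == 0] = np.nan
        return lev

    def subset_context(self, contexts) -> "Methylome":
        if isinstance(contexts, str):
            contexts = {contexts}
        sub = self.df[self.df["context"].isin(set(contexts))]
        return Methylome(sub, name=self.name, genome_id=self.genome_id,
                         validate=False)

    def query(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Sites falling in 0-based half-open interval ``[start, end)``.

        A 1-based site position p is inside iff ``start < p <= end``.
        """
        sub = self.df[self.df["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, start + 1, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return sub.iloc[lo:hi]

    def sites(self):
        """Iterate over :class:`CytosineSite` records (small inputs only)."""
        for row in self.df.itertuples(index=False):
            yield CytosineSite(row.chrom, int(row.pos), row.strand,
                               row.context, int(row.meth), int(row.unmeth))


def merge_symmetric_cpg(m: Methylome) -> Methylome:
    """Collapse CpG dyads onto the plus-strand cytosine.

    A plus-strand CpG at position ``p`` and the minus-strand CpG at ``p+1``
    report the same dyad; their counts are summed into a single plus-strand
    record at ``p``.  Minus-strand CpGs without a plus-strand partner are
    re-anchored at the plus-strand C position ``p-1``.  Non-CpG sites pass
    through unchanged.
    """
    df = m.df
    cpg = df[df["context"] == "CpG"].copy()
    other = df[df["context"] != "CpG"]
    if len(cpg) == 0:
        return Methylome(df, name=m.name, genome_id=m.genome_id, validate=False)
    # anchor every CpG record at the plus-strand C of its dyad
    minus = cpg["strand"] == "-"
    cpg.loc[minus, "pos"] = cpg.loc[minus, "pos"] - 1
    cpg["strand"] = "+"
    merged = (cpg.groupby(["chrom", "pos"], as_index=False, sort=False)
              .agg(meth=("meth", "sum"), unmeth=("unmeth", "sum")))
    merged["strand"] = "+"
    merged["context"] = "CpG"
    out = pd.concat([merged[_METHYLOME_COLUMNS], other[_METHYLOME_COLUMNS]],
                    ignore_index=True)
    return Methylome(out, name=m.name, genome_id=m.genome_id)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def contains_site(self, pos: int) -> bool:
        """Does 1-based cytosine position ``pos`` fall in this interval?"""
        return self.start < pos <= self.end


class IntervalSet:
    """Collection of labelled genomic intervals with fast membership queries."""

    _COLUMNS = ["chrom", "start", "end", "strand", "label"]

    def __init__(self, df: pd.DataFrame, name: str = ""):
        df = df.copy()
        for col, default in (("strand", "."), ("label", "")):
            if col not in df.columns:
                df[col] = default
        df = df.loc[:, self._COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
            raise ValueError(
                f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)
        self.name = name
        self._index = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = np.maximum.accumulate(sub["end"].to_numpy())
            self._index[chrom] = (starts, ends)

    @classmethod
    def from_intervals(cls, intervals, name: str = "") -> "IntervalSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.strand, iv.label)
                for iv in intervals]
        return cls(pd.DataFrame(rows, columns=cls._COLUMNS), name=name)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"IntervalSet({self.name!r}, {len(self)} intervals)"

    def intervals(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  row.strand, row.label)

    def label_counts(self) -> dict:
        return self.df["label"].value_counts().to_dict()

    def subset_by_label(self, label: str) -> "IntervalSet":
        return IntervalSet(self.df[self.df["label"] == label], name=label)

    def contains_sites(self, chroms, pos) -> np.ndarray:
        """Membership of 1-based cytosine positions in any interval.

        Returns a boolean array: True where ``s < pos <= e`` for some
        interval ``[s, e)`` of the set.
        """
        chroms = np.asarray(chroms)
        pos0 = to_zero_based(np.asarray(pos, dtype=np.int64))
        out = np.zeros(len(pos0), dtype=bool)
        for chrom in np.unique(chroms):
            if chrom not in self._index:
                continue
            starts, cummax_ends = self._index[chrom]
            sel = chroms == chrom
            p = pos0[sel]
            idx = np.searchsorted(starts, p, side="right") - 1
            ok = idx >= 0
            hit = np.zeros(len(p), dtype=bool)
            hit[ok] = cummax_ends[idx[ok]] > p[ok]
            out[sel] = hit
        return out

    def overlaps_intervals(self, chroms, starts, ends) -> np.ndarray:
        """For each query interval, does it overlap any interval of the set?"""
        chroms = np.asarray(chroms)
        qs = np.asarray(starts, dtype=np.int64)
        qe = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(qs), dtype=bool)
        for chrom in np.unique(chroms):
            if chrom not in self._index:
                continue
            set_starts, cummax_ends = self._index[chrom]
            sel = chroms == chrom
            idx = np.searchsorted(set_starts, qe[sel], side="left") - 1
            ok = idx >= 0
            hit = np.zeros(int(sel.sum()), dtype=bool)
            hit[ok] = cummax_ends[idx[ok]] > qs[sel][ok]
            out[sel] = hit
        return out


@dataclass
class GeneModel:
    """Gene with TSS/TES in *transcription order*.

    For a plus-strand gene ``tss < tes``; for a minus-strand gene
    ``tss > tes`` in genome coordinates.  ``tss``/``tes`` are 1-based
    positions of the first/last transcribed base.  Strand-aware windows
    (promoter, upstream) are derived here so that "10 kb upstream" is
    unambiguous everywhere else.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list = field(default_factory=list)

    def __post_init__(self):
        if self.strand == "+":
            if not self.tss < self.tes:
                raise ValueError(f"{self.gene_id}: + strand requires tss < tes")
        elif self.strand == "-":
            if not self.tss > self.tes:
                raise ValueError(f"{self.gene_id}: - strand requires tss > tes")
        else:
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def start(self) -> int:
        """0-based genomic start of the gene span."""
        return min(self.tss, self.tes) - 1

    @property
    def end(self) -> int:
        """0-based half-open genomic end of the gene span."""
        return max(self.tss, self.tes)

    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               self.strand, self.gene_id)

    def promoter(self, width: int = 2000) -> GenomicInterval:
        """Promoter: the ``width`` positions ending at (and including) the
        TSS, strand-aware."""
        if self.strand == "+":
            start, end = max(0, self.tss - width), self.tss
        else:
            start, end = self.tss - 1, self.tss - 1 + width
        return GenomicInterval(self.chrom, start, end, self.strand,
                               self.gene_id)

    def upstream(self, width: int = 10000) -> GenomicInterval:
        """The ``width`` bp strictly upstream of the TSS, strand-aware."""
        if self.strand == "+":
            start, end = max(0, self.tss - 1 - width), self.tss - 1
        else:
            start, end = self.tss, self.tss + width
        if start >= end:  # TSS at the chromosome edge
            end = start + 1
        return GenomicInterval(self.chrom, start, end, self.strand,
                               self.gene_id)

    def body_with_upstream(self, width: int = 10000) -> GenomicInterval:
        """Gene body plus ``width`` bp upstream (DMR-gene association window)."""
        up = self.upstream(width)
        return GenomicInterval(self.chrom, min(self.start, up.start),
                               max(self.end, up.end), self.strand, self.gene_id)


_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PWM:
    """Position frequency/weight matrix for a TF binding motif.

    ``counts`` is a 4 x L non-negative matrix, rows ordered A, C, G, T.
    ``background`` holds the 4 background base frequencies (sum 1).
    """

    motif_id: str
    counts: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: PWM must have 4 rows (A,C,G,T)")
        if self.counts.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: motif length must be >= 4")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative PWM entries")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def probabilities(self, pseudocount: float = 0.0) -> np.ndarray:
        """Column-normalised probability matrix (columns sum to 1)."""
        c = self.counts + pseudocount
        return c / c.sum(axis=0, keepdims=True)

    def log_odds(self, pseudocount: float = 0.01) -> np.ndarray:
        """log2 odds vs background, with per-cell pseudocount."""
        p = self.probabilities(pseudocount)
        return np.log2(p / self.background[:, None])

    def max_score(self, pseudocount: float = 0.01) -> float:
        return float(self.log_odds(pseudocount).max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


def motif_family(motif_id: str) -> str:
    """Heuristic family key for grouping paralogous motifs.

    Strips a trailing paralog letter after a digit (MEF2A/B/C/D -> MEF2)
    and otherwise trailing digits (EGR1/EGR2 -> EGR).
    """
    m = re.match(r"^(.*\d)[A-Za-z]$", motif_id)
    if m:
        return m.group(1)
    return motif_id.rstrip("0123456789") or motif_id


class MethylomePanel:
    """Named methylomes aligned on a common CpG universe.

    ``levels`` and ``coverage`` are DataFrames indexed by ``(chrom, pos)``
    with one column per methylome.  An entry with coverage 0 (or NaN) is
    missing, distinct from level 0.
    """

    def __init__(self, levels: pd.DataFrame, coverage: pd.DataFrame,
                 name: str = ""):
        if not levels.index.equals(coverage.index) or \
                list(levels.columns) != list(coverage.columns):
            raise ValueError("levels and coverage must be aligned")
        self.levels = levels
        self.coverage = coverage
        self.name = name

    @classmethod
    def from_methylomes(cls, methylomes: dict, name: str = "") -> "MethylomePanel":
        lev, cov = {}, {}
        for sample, m in methylomes.items():
            idx = pd.MultiIndex.from_frame(m.df[["chrom", "pos"]])
            lev[sample] = pd.Series(m.levels, index=idx)
            cov[sample] = pd.Series(m.coverage, index=idx)
        levels = pd.DataFrame(lev).sort_index()
        coverage = pd.DataFrame(cov).sort_index().fillna(0).astype(np.int64)
        levels[coverage == 0] = np.nan
        return cls(levels, coverage, name=name)

    @property
    def names(self) -> list:
        return list(self.levels.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.coverage == 0

    def __len__(self) -> int:
        return len(self.levels)

    def __repr__(self) -> str:
        return (f"MethylomePanel({self.name!r}, {len(self)} sites x "
                f"{len(self.names)} methylomes)")
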