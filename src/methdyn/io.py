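"""Readers and writers for the external formats the pipeline touches.

Formats: Bismark-style cytosine reports (TSV, 6-7 columns), BED3/6/12,
minimal GTF (gene lines), JASPAR PFM text, FASTA (via Biopython),
expression TSV, and the package's own DMS table / DMR BED outputs.
All writers round-trip through their readers.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CONTEXTS, GeneModel, IntervalSet, Methylome, PWM


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# cytosine reports

def read_cytosine_report(path, context_filter=None, name: str = "",
                         genome_id: str = "") -> Methylome:
    """Read a Bismark-style per-cytosine report.

    Tab-separated columns: chrom, pos (1-based), strand, count_methylated,
    count_unmethylated, context[, trinucleotide].  ``context_filter`` is an
    optional set of contexts to retain (e.g. ``{"CpG"}``).
    """
    if isinstance(context_filter, str):
        context_filter = {context_filter}
    rows = []
    last = {}  # chrom -> (pos, line_no), to detect unsorted input
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}: line {line_no}: expected >=6 tab-separated "
                    f"columns, got {len(fields)}")
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {line_no}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise FormatError(
                    f"{path}: line {line_no}: negative read count")
            if context not in CONTEXTS:
                raise FormatError(
                    f"{path}: line {line_no}: unknown context {context!r}")
            if chrom in last and pos < last[chrom][0]:
                raise FormatError(
                    f"{path}: line {line_no}: position {pos} out of order "
                    f"within {chrom} (previous line {last[chrom][1]})")
            last[chrom] = (pos, line_no)
            if context_filter is not None and context not in context_filter:
                continue
            rows.append((chrom, pos, strand, context, meth, unmeth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "meth", "unmeth"])
    return Methylome(df, name=name, genome_id=genome_id)


def write_cytosine_report(m: Methylome, path) -> None:
    df = m.df.copy()
    df["tri"] = np.where(df["context"] == "CpG", "CGN", "CNN")
    df[["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED and gene models

def read_bed(path, name: str = "") -> IntervalSet:
    """Read BED (>=3 columns, 0-based half-open); column 4 becomes the label."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {line_no}: BED needs >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {line_no}: {exc}") from None
            if start >= end:
                raise FormatError(
                    f"{path}: line {line_no}: start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((chrom, start, end, strand, label))
    return IntervalSet(pd.DataFrame(rows, columns=IntervalSet._COLUMNS),
                       name=name or str(path))


def write_bed(intervals: IntervalSet, path, score: str = "0") -> None:
    with open(path, "w") as fh:
        for row in intervals.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                     f"{row.label}\t{score}\t{row.strand}\n")


def read_gene_models(path) -> list:
    """Read gene models from BED6/BED12 or minimal GTF (gene lines only).

    GTF is detected by a 9-column layout with an attribute field; otherwise
    BED is assumed (name column = gene id, strand column required).
    """
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 9 and fields[8].strip():
                genes.append(_gene_from_gtf(fields, path, line_no))
            elif len(fields) >= 6:
                genes.append(_gene_from_bed(fields, path, line_no))
            else:
                raise FormatError(
                    f"{path}: line {line_no}: need BED6/BED12 or GTF gene line")
    return genes


def _gene_from_bed(fields, path, line_no) -> GeneModel:
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    gene_id, strand = fields[3], fields[5]
    if start >= end:
        raise FormatError(f"{path}: line {line_no}: start >= end")
    exons = []
    if len(fields) >= 12:  # BED12 block structure
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
    tss, tes = (start + 1, end) if strand == "+" else (end, start + 1)
    return GeneModel(gene_id, chrom, strand, tss, tes, exons)


def _gene_from_gtf(fields, path, line_no) -> GeneModel:
    chrom, _, feature, start_s, end_s, _, strand, _, attrs = fields
    if feature not in ("gene", "transcript"):
        raise FormatError(
            f"{path}: line {line_no}: minimal GTF supports gene lines only, "
            f"got feature {feature!r}")
    start, end = int(start_s), int(end_s)  # GTF is 1-based inclusive
    gene_id = None
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith("gene_id"):
            gene_id = part.split(None, 1)[1].strip('" ')
            break
    if gene_id is None:
        raise FormatError(f"{path}: line {line_no}: missing gene_id attribute")
    tss, tes = (start, end) if strand == "+" else (end, start)
    return GeneModel(gene_id, chrom, strand, tss, tes)


def write_gene_models_bed(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t"
                     f"{g.strand}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM

def read_pfm(path) -> list:
    """Read JASPAR PFM motifs: ``>ID`` header then 4 rows A/C/G/T.

    Accepts both bare count rows (``1 2 3 4``) and letter-prefixed
    bracketed rows (``A [ 1 2 3 4 ]``).
    """
    pwms = []
    current_id, current_rows, header_line = None, [], 0

    def _flush(line_no):
        if current_id is None:
            return
        if len(current_rows) != 4:
            raise FormatError(
                f"{path}: motif {current_id!r} (line {header_line}): expected "
                f"4 rows, got {len(current_rows)}")
        lengths = {len(r) for r in current_rows}
        if len(lengths) != 1:
            raise FormatError(
                f"{path}: motif {current_id!r} (line {header_line}): rows of "
                f"unequal length {sorted(lengths)}")
        pwms.append(PWM(current_id, np.array(current_rows, dtype=float)))

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no)
                current_id = line[1:].split()[0]
                current_rows, header_line = [], line_no
                continue
            if current_id is None:
                raise FormatError(
                    f"{path}: line {line_no}: counts before any '>' header")
            row = line
            if row[0] in "ACGTacgt" and (len(row) == 1 or not row[1].isdigit()):
                row = row[1:]
            row = row.replace("[", " ").replace("]", " ")
            try:
                values = [float(x) for x in row.split()]
            except ValueError as exc:
                raise FormatError(f"{path}: line {line_no}: {exc}") from None
            current_rows.append(values)
    _flush(line_no=-1)
    return pwms


def write_pfm(pwms, path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.counts:
                fh.write(" ".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict:
    """Read FASTA into ``{name: uppercase sequence string}``."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# DMS / DMR outputs

DMS_COLUMNS = ["chrom", "pos", "level_a", "level_b", "delta", "p", "p_adj",
               "cov_a", "cov_b", "is_dms"]


def write_dms_table(dms: pd.DataFrame, path) -> None:
    dms.loc[:, DMS_COLUMNS].to_csv(path, sep="\t", index=False,
                                   float_format="%.10g")
def read_dms_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"chrom": str, "pos": np.int64,
                            "cov_a": np.int64, "cov_b": np.int64,
                            "is_dms": bool})
    return df.loc[:, DMS_COLUMNS]


def write_dmr_bed(dmrs, path) -> None:
    """Write DMRs as BED6+ (score = mean |delta|; extra columns n_dms,
    direction, frac_dms_consistent, frac_cpg_consistent, mean_delta,
    member positions)."""
    with open(path, "w") as fh:
        for i, r in enumerate(dmrs):
            members = ",".join(str(p) for p in r.member_positions)
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tDMR{i + 1}\t"
                f"{abs(r.mean_delta):.10g}\t.\t{r.n_dms}\t{r.direction}\t"
                f"{r.frac_dms_consistent:.10g}\t{r.frac_cpg_consistent:.10g}\t"
                f"{r.mean_delta:.10g}\t{members}\n")


def read_dmr_bed(path):
    from .dmr import DMRRecord  # deferred: avoid import cycle
    dmrs = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {line_no}: expected 12 columns")
            dmrs.append(DMRRecord(
                chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                n_dms=int(fields[6]), direction=fields[7],
                frac_dms_consistent=float(fields[8]),
                frac_cpg_consistent=float(fields[9]),
                mean_delta=float(fields[10]),
                member_positions=[int(x) for x in fields[11].split(",")]))
    return dmrs


# ---------------------------------------------------------------------------
# expression tables, ground truth

def read_expression_table(path) -> pd.DataFrame:
    """Gene x sample TPM table; first column = gene id (index)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_table(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
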