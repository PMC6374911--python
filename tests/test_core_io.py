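"""Core types, coordinate conventions and file round-trips."""

import numpy as np
import pandas as pd
import pytest

from methdyn import io as mio
from methdyn.core import (GeneModel, GenomicInterval, Methylome, PWM,
                          merge_symmetric_cpg, motif_family)
from methdyn.dmr import DMRRecord

from conftest import make_intervals, make_methylome


# ---------------------------------------------------------------------------
# cytosine reports

def _write_report(tmp_path, lines, name="r.cov"):
    path = tmp_path / name
    path.write_text("".join(line + "\n" for line in lines))
    return path


def test_read_cytosine_report_parses_and_filters(tmp_path):
    path = _write_report(tmp_path, [
        "chr1\t100\t+\t7\t3\tCpG\tCGG",
        "chr1\t150\t+\t1\t9\tCHH\tCAT",
        "chr1\t200\t-\t5\t0\tCpG\tCGA",
    ])
    m = mio.read_cytosine_report(path, context_filter={"CpG"})
    assert len(m) == 2
    assert m.levels[0] == pytest.approx(0.7)
    only_chh = mio.read_cytosine_report(path, context_filter={"CHH"})
    assert list(only_chh.df["context"]) == ["CHH"]
    everything = mio.read_cytosine_report(path)
    assert len(everything) == 3


def test_read_cytosine_report_rejects_malformed(tmp_path):
    unsorted = _write_report(tmp_path, [
        "chr1\t200\t+\t1\t1\tCpG\tCGG",
        "chr1\t100\t+\t1\t1\tCpG\tCGG",
    ])
    with pytest.raises(mio.FormatError, match="line 2"):
        mio.read_cytosine_report(unsorted)
    negative = _write_report(tmp_path, ["chr1\t100\t+\t-1\t3\tCpG\tCGG"],
                             name="neg.cov")
    with pytest.raises(mio.FormatError, match="negative"):
        mio.read_cytosine_report(negative)


def test_cytosine_report_round_trip(tmp_path):
    m = make_methylome([10, 55, 300], [3, 0, 9], [1, 5, 0])
    path = tmp_path / "rt.cov"
    mio.write_cytosine_report(m, path)
    assert mio.read_cytosine_report(path) == m


def test_merge_symmetric_cpg():
    df = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1"],
        "pos": [100, 101, 300],
        "strand": ["+", "-", "+"],
        "context": "CpG",
        "meth": [3, 2, 1], "unmeth": [1, 2, 4]})
    merged = merge_symmetric_cpg(Methylome(df))
    assert len(merged) == 2
    dyad = merged.df[merged.df["pos"] == 100].iloc[0]
    assert (dyad["meth"], dyad["unmeth"], dyad["strand"]) == (5, 3, "+")
    lone = merged.df[merged.df["pos"] == 300].iloc[0]
    assert (lone["meth"], lone["unmeth"]) == (1, 4)


def test_merge_symmetric_cpg_empty_and_ch_passthrough():
    empty = Methylome(pd.DataFrame(columns=["chrom", "pos", "strand",
                                            "context", "meth", "unmeth"]))
    assert len(merge_symmetric_cpg(empty)) == 0
    ch = make_methylome([50, 51], [1, 2], [3, 4], context="CHH")
    assert merge_symmetric_cpg(ch) == ch


# ---------------------------------------------------------------------------
# coordinate conventions

def test_site_in_interval_convention_exhaustive():
    """1-based cytosine p is in BED [s, e) iff s < p <= e."""
    for s in range(0, 100):
        for e in range(s + 1, 101):
            iv = GenomicInterval("chr1", s, e)
            for p in range(1, 101):
                expected = s < p <= e
                assert iv.contains_site(p) == expected, (s, e, p)


def test_intervalset_membership_matches_brute_force(rng):
    for _ in range(5):
        n_iv = rng.integers(1, 40)
        starts = rng.integers(0, 5000, size=n_iv)
        widths = rng.integers(1, 400, size=n_iv)
        ivs = make_intervals([("chr1", int(s), int(s + w))
                              for s, w in zip(starts, widths)])
        pos = rng.integers(1, 6000, size=2000)
        got = ivs.contains_sites(np.full(len(pos), "chr1"), pos)
        brute = np.array([any(s < p <= s + w
                              for s, w in zip(starts, widths))
                          for p in pos])
        assert np.array_equal(got, brute)


def test_methylome_query_matches_brute_force(rng):
    pos = np.unique(rng.integers(1, 10_000, size=500))
    m = make_methylome(pos, 1, 1)
    for _ in range(20):
        a, b = sorted(rng.integers(0, 10_000, size=2))
        if a == b:
            b += 1
        got = set(m.query("chr1", int(a), int(b))["pos"])
        assert got == {int(p) for p in pos if a < p <= b}


# ---------------------------------------------------------------------------
# BED / genes / PFM

def test_bed_round_trip_and_labels(tmp_path):
    path = tmp_path / "x.bed"
    path.write_text("chr1\t0\t100\tCGI\t0\t+\nchr2\t50\t80\tshore\t0\t-\n")
    ivs = mio.read_bed(path)
    first = next(ivs.intervals())
    assert (first.chrom, first.start, first.end, first.label) == \
        ("chr1", 0, 100, "CGI")
    out = tmp_path / "y.bed"
    mio.write_bed(ivs, out)
    assert mio.read_bed(out).df.equals(ivs.df)


def test_bed_invalid_coordinates(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t10\t10\tx\n")
    with pytest.raises(mio.FormatError, match="line 1"):
        mio.read_bed(path)


def test_enhancer_class_counts(tmp_path):
    path = tmp_path / "enh.bed"
    path.write_text("".join(f"chr1\t{i * 10}\t{i * 10 + 5}\tCon\n"
                            for i in range(800)))
    ivs = mio.read_bed(path)
    assert ivs.label_counts() == {"Con": 800}


def test_gene_models_bed_and_gtf(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t999\t2000\tgplus\t0\t+\nchr1\t4999\t7000\tgminus\t0\t-\n")
    genes = {g.gene_id: g for g in mio.read_gene_models(bed)}
    assert (genes["gplus"].tss, genes["gplus"].tes) == (1000, 2000)
    assert (genes["gminus"].tss, genes["gminus"].tes) == (7000, 5000)
    gtf = tmp_path / "genes.gtf"
    gtf.write_text('chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tgene_id "gp";\n')
    (gp,) = mio.read_gene_models(gtf)
    assert (gp.tss, gp.tes) == (1000, 2000)


def test_gene_windows_are_strand_aware():
    plus = GeneModel("p", "chr1", "+", tss=10_000, tes=20_000)
    minus = GeneModel("m", "chr1", "-", tss=20_000, tes=10_000)
    # promoter covers (TSS-2kb .. TSS]
    assert plus.promoter().contains_site(10_000)
    assert plus.promoter().contains_site(8_001)
    assert not plus.promoter().contains_site(8_000)
    assert not plus.promoter().contains_site(10_001)
    assert minus.promoter().contains_site(20_000)
    assert minus.promoter().contains_site(21_999)
    assert not minus.promoter().contains_site(22_001)
    # upstream window is strictly before the TSS
    assert plus.upstream(10_000).contains_site(9_999)
    assert not plus.upstream(10_000).contains_site(10_000)
    assert minus.upstream(10_000).contains_site(20_001)
    assert minus.upstream(10_000).contains_site(30_000)


def test_pfm_reading(tmp_path):
    path = tmp_path / "m.pfm"
    path.write_text(">M1\n" + "\n".join(["1 2 3 4 5 6 7 8"] * 4) + "\n")
    (pwm,) = mio.read_pfm(path)
    assert pwm.length == 8
    assert np.allclose(pwm.probabilities().sum(axis=0), 1.0)
    bad = tmp_path / "bad.pfm"
    bad.write_text(">M2\n1 2 3 4\n1 2 3\n1 2 3 4\n1 2 3 4\n")
    with pytest.raises(mio.FormatError, match="unequal"):
        mio.read_pfm(bad)


def test_pfm_round_trip_and_jaspar_bracket_style(tmp_path):
    pwm = PWM("MA0001", np.arange(1, 21, dtype=float).reshape(4, 5))
    path = tmp_path / "rt.pfm"
    mio.write_pfm([pwm], path)
    (back,) = mio.read_pfm(path)
    assert back.motif_id == "MA0001"
    assert np.array_equal(back.counts, pwm.counts)
    jaspar = tmp_path / "j.pfm"
    jaspar.write_text(">MA0004.1 Arnt\nA [ 4 19 0 0 ]\nC [16 0 20 0 ]\n"
                      "G [ 0 1 0 20 ]\nT [ 0 0 0 0 ]\n")
    (arnt,) = mio.read_pfm(jaspar)
    assert arnt.counts.shape == (4, 4)
    assert arnt.counts[0, 1] == 19


def test_motif_family_grouping():
    assert motif_family("MEF2A") == motif_family("MEF2C") == "MEF2"
    assert motif_family("EGR1") == "EGR"
    assert motif_family("CTCF") == "CTCF"


# ---------------------------------------------------------------------------
# DMS / DMR output round-trips

def test_dms_table_round_trip(tmp_path):
    df = pd.DataFrame({
        "chrom": ["chr1", "chr1"], "pos": [100, 200],
        "level_a": [0.1, 0.9], "level_b": [0.6, 0.9],
        "delta": [0.5, 0.0], "p": [1e-5, 1.0], "p_adj": [2e-5, 1.0],
        "cov_a": [20, 30], "cov_b": [25, 31], "is_dms": [True, False]})
    path = tmp_path / "dms.tsv"
    mio.write_dms_table(df, path)
    back = mio.read_dms_table(path)
    pd.testing.assert_frame_equal(back, df)


def test_dmr_bed_round_trip(tmp_path):
    dmrs = [DMRRecord("chr1", 99, 600, n_dms=5, direction="hyper",
                      frac_dms_consistent=1.0, frac_cpg_consistent=0.875,
                      mean_delta=0.21, member_positions=[100, 200, 400, 500,
                                                         600])]
    path = tmp_path / "dmr.bed"
    mio.write_dmr_bed(dmrs, path)
    (back,) = mio.read_dmr_bed(path)
    assert back == dmrs[0]


def test_interval_and_site_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 5, 5)
    with pytest.raises(ValueError):
        make_methylome([10, 10], [1, 1], [1, 1])  # duplicate site
    with pytest.raises(ValueError):
        GeneModel("g", "chr1", "+", tss=100, tes=50)
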