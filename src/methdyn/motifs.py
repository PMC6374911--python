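"""Known-motif enrichment with flank-derived background.

Targets (e.g. the DMS loci of a co-methylation module) are compared
against same-width regions placed a fixed offset up- and downstream of
each target (two background regions per target, minus boundary losses).
Sequences are scanned on both strands with log-odds PWM scores; a
sequence is a hit when its best score reaches a fraction of the motif's
maximum achievable score.  Enrichment is an upper-tail binomial test of
the target hit count against the background hit rate, significant at the
conventional 1e-10 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PWM, IntervalSet, motif_family
from .network import ModuleAssignment, parse_locus_id

DEFAULT_CUTOFF = 1e-10


def build_flank_background(targets: IntervalSet, offset: int = 2000,
                           chrom_sizes: dict | None = None):
    """Same-width background regions ± (offset + width) from each target.

    Each target [s, e) spawns a left region ending ``offset`` bp before s
    and a right region starting ``offset`` bp after e.  Regions falling
    off-chromosome or overlapping any target are dropped and counted.

    Returns ``(IntervalSet, report)`` with ``report`` holding
    ``n_targets``, ``n_background``, ``n_dropped_bounds`` and
    ``n_dropped_overlap``.
    """
    rows, n_bounds, n_overlap = [], 0, 0
    candidates = []
    for t in targets.df.itertuples(index=False):
        width = t.end - t.start
        shift = offset + width
        candidates.append((t.chrom, t.start - shift, t.end - shift))
        candidates.append((t.chrom, t.start + shift, t.end + shift))
    for chrom, start, end in candidates:
        size = None if chrom_sizes is None else chrom_sizes.get(chrom)
        if start < 0 or (size is not None and end > size):
            n_bounds += 1
            continue
        if targets.overlaps_intervals([chrom], [start], [end])[0]:
            n_overlap += 1
            continue
        rows.append((chrom, start, end, ".", "background"))
    bg = IntervalSet(pd.DataFrame(rows, columns=IntervalSet._COLUMNS),
                     name="flank_background")
    report = {"n_targets": len(targets), "n_background": len(bg),
              "n_dropped_bounds": n_bounds, "n_dropped_overlap": n_overlap}
    return bg, report


_CODE = np.full(256, 4, dtype=np.int8)  # 4 = N / unknown
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _best_score(codes: np.ndarray, lo5: np.ndarray) -> float:
    """Best log-odds score over all offsets of one strand."""
    L = lo5.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return -np.inf
    scores = np.zeros(n)
    for j in range(L):
        scores += lo5[codes[j:j + n], j]
    return float(scores.max())


def scan_pwm(sequences: dict, pwm: PWM, score_fraction: float = 0.8,
             pseudocount: float = 0.01) -> pd.DataFrame:
    """Scan sequences with a PWM on both strands.

    N positions contribute 0 log-odds.  A sequence is a hit when its best
    score is at least ``score_fraction`` times the maximum achievable
    score.  Sequences shorter than the motif are flagged and never hit.

    Returns a DataFrame (seq_id, best_score, hit, too_short).
    """
    lo = pwm.log_odds(pseudocount)
    lo5 = np.vstack([lo, np.zeros(pwm.length)])  # N row scores 0
    # reverse-complement scan realised by scanning with the flipped matrix
    lo5_rc = lo5[[3, 2, 1, 0, 4], ::-1]
    threshold = score_fraction * pwm.max_score(pseudocount)
    rows = []
    for sid, seq in sequences.items():
        codes = _encode(seq)
        if len(codes) < pwm.length:
            rows.append((sid, -np.inf, False, True))
            continue
        best = max(_best_score(codes, lo5), _best_score(codes, lo5_rc))
        rows.append((sid, best, best >= threshold, False))
    return pd.DataFrame(rows, columns=["seq_id", "best_score", "hit",
                                       "too_short"])


@dataclass
class MotifHitSummary:
    motif_id: str
    n_target: int
    n_target_hit: int
    n_bg: int
    n_bg_hit: int
    p_binomial: float
    enriched: bool
    family: str = ""

    def __post_init__(self):
        if self.n_target_hit > self.n_target or self.n_bg_hit > self.n_bg:
            raise ValueError("hits exceed totals")
        if not self.family:
            self.family = motif_family(self.motif_id)


def motif_enrichment_test(n_target: int, n_target_hit: int, n_bg: int,
                          n_bg_hit: int, motif_id: str = "",
                          cutoff: float = DEFAULT_CUTOFF) -> MotifHitSummary:
    """Upper-tail binomial enrichment of target hits over the background
    hit rate.  A background with zero hits floors the null rate at
    ``1 / (2 * n_bg)`` so the tail probability stays defined."""
    if n_bg == 0:
        raise ValueError("empty background")
    p0 = n_bg_hit / n_bg
    if p0 == 0.0:
        p0 = 1.0 / (2 * n_bg)
    p = float(stats.binom.sf(n_target_hit - 1, n_target, p0)) \
        if n_target_hit > 0 else 1.0
    return MotifHitSummary(motif_id=motif_id, n_target=n_target,
                           n_target_hit=n_target_hit, n_bg=n_bg,
                           n_bg_hit=n_bg_hit, p_binomial=p,
                           enriched=p <= cutoff)


def extract_sequences(genome: dict, intervals: IntervalSet,
                      prefix: str = "region") -> dict:
    """Pull interval sequences out of ``{chrom: sequence}``."""
    out = {}
    for i, iv in enumerate(intervals.df.itertuples(index=False)):
        seq = genome.get(iv.chrom, "")
        out[f"{prefix}_{i + 1}"] = seq[iv.start:iv.end]
    return out


def enrichment_table(targets: dict, background: dict, pwms,
                     score_fraction: float = 0.8,
                     cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Scan target and background sequence sets with every PWM and test
    enrichment; rows sorted by binomial p."""
    rows = []
    for pwm in pwms:
        t_scan = scan_pwm(targets, pwm, score_fraction)
        b_scan = scan_pwm(background, pwm, score_fraction)
        summary = motif_enrichment_test(
            len(t_scan), int(t_scan["hit"].sum()),
            len(b_scan), int(b_scan["hit"].sum()),
            motif_id=pwm.motif_id, cutoff=cutoff)
        rows.append({"motif_id": summary.motif_id,
                     "family": summary.family,
                     "n_target": summary.n_target,
                     "n_target_hit": summary.n_target_hit,
                     "n_bg": summary.n_bg, "n_bg_hit": summary.n_bg_hit,
                     "p_binomial": summary.p_binomial,
                     "enriched": summary.enriched})
    return (pd.DataFrame(rows)
            .sort_values("p_binomial", kind="mergesort")
            .reset_index(drop=True))


def cluster_motif_report(assignment: ModuleAssignment, genome: dict,
                         pwms, offset: int = 2000, width: int = 200,
                         score_fraction: float = 0.8,
                         cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Per-module known-motif enrichment.

    Module loci (parsed from ``chrom:start-end`` ids) are extended to a
    fixed ``width`` centred on the locus, the flank background is built at
    ``offset`` bp, and every PWM is tested.  The unassigned label 0 is
    skipped.  Returns the concatenated per-module tables sorted by p
    within module.
    """
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    tables = []
    for module in sorted(assignment.sizes):
        loci = assignment.loci_of(module)
        rows = []
        for locus in loci:
            chrom, start, end = parse_locus_id(locus)
            center = (start + end) // 2
            s = max(0, center - width // 2)
            e = min(chrom_sizes.get(chrom, center + width), s + width)
            if e > s:
                rows.append((chrom, s, e, ".", locus))
        if not rows:
            continue
        targets_iv = IntervalSet(
            pd.DataFrame(rows, columns=IntervalSet._COLUMNS),
            name=f"module_{module}")
        bg_iv, _ = build_flank_background(targets_iv, offset=offset,
                                          chrom_sizes=chrom_sizes)
        if len(bg_iv) == 0:
            continue
        table = enrichment_table(
            extract_sequences(genome, targets_iv, prefix="target"),
            extract_sequences(genome, bg_iv, prefix="bg"),
            pwms, score_fraction=score_fraction, cutoff=cutoff)
        table.insert(0, "module", module)
        tables.append(table)
    if not tables:
        return pd.DataFrame(columns=["module", "motif_id", "family",
                                     "n_target", "n_target_hit", "n_bg",
                                     "n_bg_hit", "p_binomial", "enriched"])
    return pd.concat(tables, ignore_index=True)
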