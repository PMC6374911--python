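"""Synthetic bisulfite data with known ground truth.

Generates genomes with controlled CpG density, beta-binomial methylomes
(bimodal baseline levels, negative-binomial coverage, binomial read
sampling), two-condition pairs with spiked differential regions,
multi-cell-type panels with designated hypo/hyper sites, planted
co-methylation blocks, motif-embedded sequence sets and zero-inflated
expression tables.  Every generator is a deterministic function of its
configuration and seed.

The defaults emulate the data regime the analysis assumes: ~10-60x
usable coverage (negative binomial, mean 20, size 5), a bimodal CpG
methylation landscape dominated by the hypermethylated mode, spiked
regions of ~1 kb placed in CpG-island-like (0.10/bp) stretches against a
0.02/bp genome background, and demethylation (hypo) spikes drawn from
the hypermethylated compartment so the nominal effect size survives
clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import IntervalSet, Methylome, PWM

CELL_TYPES = ("excitatory", "PV", "VIP", "astrocyte", "oligodendrocyte")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic scenarios.

    ``baseline_mixture`` is a tuple of ``(weight, alpha, beta)`` Beta
    components for the genome-wide methylation level distribution; the
    default places ~72% of mass in the hypermethylated mode, ~25% in the
    hypomethylated mode and almost none in between (bimodal landscape).
    ``dmr_spec`` lists spiked regions as ``(width_bp, min_sites, delta,
    direction)``; direction refers to condition B relative to A.
    """

    seed: int = 0
    n_chrom: int = 1
    chrom_length: int = 500_000
    cpg_density: float = 0.02            # CG dinucleotides per bp
    baseline_mixture: tuple = ((0.72, 20.0, 1.0),
                               (0.25, 1.0, 20.0),
                               (0.03, 2.0, 2.0))
    coverage_mean: float = 20.0          # negative binomial mean
    coverage_size: float = 5.0           # negative binomial size (dispersion)
    dmr_spec: tuple = tuple((1000, 10, 0.3, "hypo") for _ in range(20))
    dmr_region_cpg_density: float = 0.10  # CGI-like density in spiked regions
    celltype_n_hypo: int = 400
    celltype_n_hyper: int = 200
    celltype_delta: float = 0.4
    celltype_coverage_mean: float = 30.0
    celltype_coverage_size: float = 100.0  # deep pooled methylomes: near-Poisson
    celltype_missing_rate: float = 0.05
    celltype_universe: int = 5000
    motif_rate_target: float = 0.5
    motif_rate_background: float = 0.05

    def __post_init__(self):
        if self.n_chrom < 1 or self.chrom_length < 1:
            raise ValueError("need n_chrom >= 1 and chrom_length >= 1")
        if not 0 < self.cpg_density < 0.5:
            raise ValueError("cpg_density must be in (0, 0.5)")
        for width, min_sites, delta, direction in self.dmr_spec:
            if not 0 < delta <= 1:
                raise ValueError("spiked delta must be in (0, 1]")
            if direction not in ("hyper", "hypo"):
                raise ValueError(f"invalid spike direction {direction!r}")
        w = sum(c[0] for c in self.baseline_mixture)
        if not np.isclose(w, 1.0):
            raise ValueError("baseline mixture weights must sum to 1")


@dataclass
class GroundTruth:
    """What the generator actually planted, for scoring recovery."""

    true_dmr_intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "direction", "delta"]))
    true_dms_positions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "pos"]))
    true_celltype_sites: dict = field(default_factory=dict)
    module_assignments: np.ndarray = None
    motif_embedded_target_ids: list = field(default_factory=list)
    true_levels: dict = field(default_factory=dict)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3


def _plant_cpgs(codes: np.ndarray, positions0: np.ndarray) -> None:
    codes[positions0] = _C
    codes[positions0 + 1] = _G


def simulate_genome(cfg: SimulationConfig, rng=None):
    """Random genome with CG dinucleotides at ~``cpg_density`` per bp.

    Returns ``(sequences, cpg_map)`` where ``sequences`` maps chromosome
    name to an uppercase string and ``cpg_map`` is a DataFrame with the
    1-based position of the C of every CG occurrence.  The background
    sequence is scrubbed of accidental CG dinucleotides, then CGs are
    planted at Bernoulli(``cpg_density``) positions, so the CpG map is
    exactly the planted set plus nothing else.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    sequences, rows = {}, []
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        length = cfg.chrom_length
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        # remove accidental CG dinucleotides (replace the G with A)
        acc = np.flatnonzero((codes[:-1] == _C) & (codes[1:] == _G))
        codes[acc + 1] = _A
        keep = rng.random(length - 1) < cfg.cpg_density
        pos0 = np.flatnonzero(keep)
        # enforce >= 2 bp spacing so planted CGs never overlap
        if len(pos0):
            spaced = [pos0[0]]
            for p in pos0[1:]:
                if p - spaced[-1] >= 2:
                    spaced.append(p)
            pos0 = np.asarray(spaced)
            _plant_cpgs(codes, pos0)
            # scrub any CG recreated at a plant boundary
            acc = np.flatnonzero((codes[:-1] == _C) & (codes[1:] == _G))
            stray = np.setdiff1d(acc, pos0, assume_unique=False)
            codes[stray + 1] = _A
        sequences[chrom] = _BASES[codes].tobytes().decode("ascii")
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos0 + 1}))
    cpg_map = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=["chrom", "pos"])
    return sequences, cpg_map


def draw_baseline_levels(n: int, cfg: SimulationConfig, rng) -> np.ndarray:
    """Sample ``n`` true methylation levels from the bimodal baseline."""
    weights = np.array([c[0] for c in cfg.baseline_mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    levels = np.empty(n)
    for i, (_, a, b) in enumerate(cfg.baseline_mixture):
        sel = comp == i
        levels[sel] = rng.beta(a, b, size=int(sel.sum()))
    return levels


def simulate_methylome(cpg_map: pd.DataFrame, true_levels,
                       coverage_mean: float, coverage_size: float = 5.0,
                       seed=None, name: str = "",
                       genome_id: str = "sim") -> Methylome:
    """Beta-binomial read sampling over a CpG map.

    Coverage ~ NegBin(mean, size); methylated reads ~ Binomial(coverage,
    level).  ``coverage_mean`` 0 leaves every site uncovered (missing).
    """
    rng = np.random.default_rng(seed)
    true_levels = np.asarray(true_levels, dtype=float)
    if np.any((true_levels < 0) | (true_levels > 1)):
        raise ValueError("true levels outside [0, 1]")
    n = len(cpg_map)
    if coverage_mean <= 0:
        cov = np.zeros(n, dtype=np.int64)
    else:
        p = coverage_size / (coverage_size + coverage_mean)
        cov = rng.negative_binomial(coverage_size, p, size=n)
    meth = rng.binomial(cov, true_levels)
    df = pd.DataFrame({
        "chrom": cpg_map["chrom"].to_numpy(),
        "pos": cpg_map["pos"].to_numpy(),
        "strand": "+", "context": "CpG",
        "meth": meth, "unmeth": cov - meth})
    return Methylome(df, name=name, genome_id=genome_id)


def _place_spikes(cpg_map: pd.DataFrame, cfg: SimulationConfig, rng):
    """Choose non-overlapping spike windows with enough CpGs; top up the
    CpG map inside each window to ``dmr_region_cpg_density``."""
    cpg_map = cpg_map.copy()
    placed = []  # (chrom, start0, end0, delta, direction)
    occupied = {f"chr{i + 1}": [] for i in range(cfg.n_chrom)}
    for width, min_sites, delta, direction in cfg.dmr_spec:
        for _ in range(1000):
            chrom = f"chr{rng.integers(1, cfg.n_chrom + 1)}"
            start0 = int(rng.integers(width, cfg.chrom_length - 2 * width))
            end0 = start0 + width
            # keep a one-width buffer between spiked regions
            if any(start0 < e + width and end0 > s - width
                   for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start0, end0))
            placed.append((chrom, start0, end0, delta, direction))
            break
        else:
            raise RuntimeError("could not place spiked region; genome too small")
        # top up CpGs inside the window to the regulatory density
        sel = (cpg_map["chrom"] == chrom) & (cpg_map["pos"] > start0) & \
              (cpg_map["pos"] <= end0)
        want = max(min_sites, int(round(width * cfg.dmr_region_cpg_density)))
        have = int(sel.sum())
        if have < want:
            existing = set(cpg_map.loc[sel, "pos"])
            new_pos = []
            candidates = rng.permutation(np.arange(start0 + 1, end0))
            for p in candidates:
                if len(new_pos) >= want - have:
                    break
                if any(abs(p - q) < 2 for q in existing) or \
                        any(abs(p - q) < 2 for q in new_pos):
                    continue
                new_pos.append(int(p))
            cpg_map = pd.concat(
                [cpg_map, pd.DataFrame({"chrom": chrom, "pos": new_pos})],
                ignore_index=True)
    cpg_map = cpg_map.sort_values(["chrom", "pos"]).reset_index(drop=True)
    truth = pd.DataFrame(placed,
                         columns=["chrom", "start", "end", "delta",
                                  "direction"])[
        ["chrom", "start", "end", "direction", "delta"]]
    return cpg_map, truth


def spike_condition_pair(cfg: SimulationConfig):
    """Two-condition contrast with spiked differential regions.

    Outside the spiked regions both conditions share identical true levels
    drawn from the bimodal baseline.  Inside each spiked region the
    baseline is drawn from the compartment matching the spike direction
    (hypermethylated baseline for hypo spikes and vice versa) and condition
    B is shifted by ``delta``, clipped to [0, 1].

    Returns ``(methylome_a, methylome_b, ground_truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    _, cpg_map = simulate_genome(cfg, rng=rng)
    cpg_map, truth_dmrs = _place_spikes(cpg_map, cfg, rng)
    n = len(cpg_map)
    levels_a = draw_baseline_levels(n, cfg, rng)
    levels_b = levels_a.copy()
    dms_rows = []
    for row in truth_dmrs.itertuples(index=False):
        sel = ((cpg_map["chrom"] == row.chrom) &
               (cpg_map["pos"] > row.start) &
               (cpg_map["pos"] <= row.end)).to_numpy()
        k = int(sel.sum())
        if row.direction == "hypo":
            base = rng.beta(20.0, 1.0, size=k)          # hypermethylated start
            shifted = np.clip(base - row.delta, 0.0, 1.0)
        else:
            base = rng.beta(1.0, 20.0, size=k)          # hypomethylated start
            shifted = np.clip(base + row.delta, 0.0, 1.0)
        levels_a[sel] = base
        levels_b[sel] = shifted
        dms_rows.append(cpg_map[sel][["chrom", "pos"]])
    truth = GroundTruth(
        true_dmr_intervals=truth_dmrs,
        true_dms_positions=(pd.concat(dms_rows, ignore_index=True)
                            if dms_rows else
                            pd.DataFrame(columns=["chrom", "pos"])),
        true_levels={"a": levels_a, "b": levels_b})
    seed_a, seed_b = rng.integers(0, 2**31, size=2)
    meth_a = simulate_methylome(cpg_map, levels_a, cfg.coverage_mean,
                                cfg.coverage_size, seed=int(seed_a), name="A")
    meth_b = simulate_methylome(cpg_map, levels_b, cfg.coverage_mean,
                                cfg.coverage_size, seed=int(seed_b), name="B")
    return meth_a, meth_b, truth


def simulate_celltype_panel(cfg: SimulationConfig):
    """Five-cell-type methylome panel with designated specific sites.

    For each type, ``celltype_n_hypo`` sites are hypomethylated (and
    ``celltype_n_hyper`` hypermethylated) in that type only, by at least
    ``celltype_delta`` relative to every other type; the remaining sites
    share a common bimodal baseline.  A ``celltype_missing_rate`` fraction
    of (site, sample) entries is masked to coverage 0.

    Returns ``({name: Methylome}, GroundTruth)``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.celltype_universe
    pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length, 2),
                             size=n, replace=False))
    cpg_map = pd.DataFrame({"chrom": "chr1", "pos": pos})
    base = draw_baseline_levels(n, cfg, rng)
    levels = {t: base.copy() for t in CELL_TYPES}

    n_special = (cfg.celltype_n_hypo + cfg.celltype_n_hyper) * len(CELL_TYPES)
    if n_special > n:
        raise ValueError("universe too small for designated sites")
    special_idx = rng.choice(n, size=n_special, replace=False)
    truth_sites, cursor = {}, 0
    delta = cfg.celltype_delta
    for t in CELL_TYPES:
        hypo_idx = special_idx[cursor:cursor + cfg.celltype_n_hypo]
        cursor += cfg.celltype_n_hypo
        hyper_idx = special_idx[cursor:cursor + cfg.celltype_n_hyper]
        cursor += cfg.celltype_n_hyper
        # hypo-in-t: fully methylated in every other type, t lower by
        # exactly delta (mirrored for hyper-in-t) — the maximally
        # contrasted cell-type-specific pattern
        high = np.ones(len(hypo_idx))
        low = np.zeros(len(hyper_idx))
        for other in CELL_TYPES:
            levels[other][hypo_idx] = high
            levels[other][hyper_idx] = low
        levels[t][hypo_idx] = high - delta
        levels[t][hyper_idx] = low + delta
        truth_sites[t] = {
            "hypo": set(int(p) for p in pos[hypo_idx]),
            "hyper": set(int(p) for p in pos[hyper_idx])}

    methylomes = {}
    for t in CELL_TYPES:
        m = simulate_methylome(cpg_map, levels[t],
                               cfg.celltype_coverage_mean,
                               cfg.celltype_coverage_size,
                               seed=int(rng.integers(0, 2**31)), name=t)
        if cfg.celltype_missing_rate > 0:
            mask = rng.random(len(m)) < cfg.celltype_missing_rate
            df = m.df.copy()
            df.loc[mask, ["meth", "unmeth"]] = 0
            m = Methylome(df, name=t, genome_id=m.genome_id, validate=False)
        methylomes[t] = m
    truth = GroundTruth(true_celltype_sites=truth_sites,
                        true_levels=levels)
    return methylomes, truth


def simulate_comethylation_matrix(n_blocks: int = 2, block_size: int = 100,
                                  n_samples: int = 20,
                                  within_corr: float = 0.9,
                                  n_noise: int = 0, seed=0):
    """Methylation-level matrix with planted co-methylation blocks.

    Rows within a block share a latent profile with pairwise correlation
    ~``within_corr``; blocks are mutually independent; ``n_noise`` extra
    rows are pure noise (truth label 0).  Values are squashed into [0, 1]
    around 0.5 so they read as methylation levels.

    Returns ``(DataFrame loci x samples, truth labels array)``.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    r = np.sqrt(within_corr)
    for b in range(n_blocks):
        signal = rng.standard_normal(n_samples)
        noise = rng.standard_normal((block_size, n_samples))
        rows.append(r * signal + np.sqrt(1 - within_corr) * noise)
        labels.extend([b + 1] * block_size)
    if n_noise:
        rows.append(rng.standard_normal((n_noise, n_samples)))
        labels.extend([0] * n_noise)
    x = np.vstack(rows)
    values = np.clip(0.5 + 0.15 * x, 0.0, 1.0)
    index = [f"chr1:{1000 * (i + 1)}-{1000 * (i + 1) + 200}"
             for i in range(len(values))]
    matrix = pd.DataFrame(values, index=index,
                          columns=[f"methylome_{j + 1}"
                                   for j in range(n_samples)])
    return matrix, np.asarray(labels)


def random_sequences(n: int, length: int, seed=0, prefix: str = "seq") -> dict:
    """Uniform-random A/C/G/T sequences keyed ``prefix_i``."""
    rng = np.random.default_rng(seed)
    return {f"{prefix}_{i + 1}":
            _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
            for i in range(n)}


def embed_motif(targets: dict, background: dict, pwm: PWM,
                rate_t: float, rate_b: float, seed=0):
    """Plant consensus motif instances into sequence sets.

    A fraction ``rate_t`` of target sequences (``rate_b`` of background)
    receives one consensus instance at a random offset.  Returns
    ``(targets, background, embedded_target_ids)``; inputs are not
    modified.
    """
    rng = np.random.default_rng(seed)
    consensus = pwm.consensus()

    def _embed(seqs: dict, rate: float):
        ids = sorted(seqs)
        n_embed = int(round(rate * len(ids)))
        chosen = list(rng.choice(ids, size=n_embed, replace=False)) \
            if n_embed else []
        out = dict(seqs)
        for sid in chosen:
            seq = out[sid]
            if len(seq) < len(consensus):
                continue
            off = int(rng.integers(0, len(seq) - len(consensus) + 1))
            out[sid] = seq[:off] + consensus + seq[off + len(consensus):]
        return out, chosen

    new_targets, embedded = _embed(targets, rate_t)
    new_background, _ = _embed(background, rate_b)
    return new_targets, new_background, embedded


def demo_pwm(motif_id: str = "MEF2A") -> PWM:
    """A strongly peaked 10 bp MEF2-like (CTATTTATAG) count matrix, used as
    the planted motif in synthetic scenarios."""
    consensus = "CTATTTATAG"
    counts = np.full((4, len(consensus)), 2.0)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, b in enumerate(consensus):
        counts[idx[b], j] = 94.0
    return PWM(motif_id, counts)


def simulate_expression(genes, seed=0, frac_not_expressed: float = 0.25,
                        n_samples: int = 2, mu: float = 2.0,
                        sigma: float = 1.2,
                        not_expressed_below: float = 1.0):
    """Zero-inflated lognormal TPM table with tercile structure.

    Returns ``(table, labels)``: a gene x sample TPM DataFrame and a gene
    -> {none, low, mid, high} Series.  Labels are derived from the mean
    TPM with the same rule the profiling module applies (threshold,
    ascending terciles), so they are recoverable downstream.
    """
    from .profiles import expression_groups  # shared grouping rule
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n = len(genes)
    silent = rng.random(n) < frac_not_expressed
    base = np.exp(rng.normal(mu, sigma, size=n))
    base[silent] = 0.0
    table = pd.DataFrame(
        {f"sample_{j + 1}": base * np.exp(rng.normal(0, 0.05, size=n))
         for j in range(n_samples)},
        index=pd.Index(genes, name="gene_id"))
    table[table < 1e-12] = 0.0
    labels = expression_groups(table.mean(axis=1),
                               not_expressed_below=not_expressed_below)
    return table, labels


def spiked_intervals_to_bed(truth: GroundTruth) -> IntervalSet:
    df = truth.true_dmr_intervals.copy()
    df["strand"] = "."
    df["label"] = df["direction"]
    return IntervalSet(df[["chrom", "start", "end", "strand", "label"]],
                       name="true_dmrs")
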