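# Methods

This note records the statistical model behind each component, the
parameters that matter, what the synthetic data does and does not
emulate, and the numerical/design choices made where the design was
genuinely open.

## Differential methylation testing

Per CpG, read counts from two samples form a 2×2 table (condition ×
methylated/unmethylated). The two-sided Fisher exact p sums all
hypergeometric point probabilities (fixed margins) not exceeding the
observed one; probability ties are resolved with a relative tolerance of
1e−7, the dominant convention. The implementation enumerates the
hypergeometric pmf per margin triple and caches it, so a run over ~10⁵
sites re-computes each distinct margin once; the pmf sum is normalised
by its total so a full-support sum is exactly 1 in floating point.
Only sites covered ≥ `min_cov` (default 10) in *both* samples are
tested — an asymmetric 9×/50× site is excluded. CpG dyads are merged
onto the plus-strand cytosine before testing (CpG methylation is
symmetric; CH is not and keeps strands separate); merging is a flag on
the conversion step for users who want strand-resolved CpGs.

### FDR calibration

*m₀ estimation.* With B = 20 equal-width bins over [0, 1], the smallest
bin index *i* whose count does not exceed the mean count of bins *i..B*
marks the start of the uniform tail, and *m₀ = (B/(B−i+1)) ·
count(bins i..B)*, clipped to [0, m]. On pure-null uniform p-values the
ratio m₀/m sits at ~0.99–1.0; on a 90/10 null/alternative mixture at
~0.9. Inputs with fewer than 20 p-values skip estimation (m₀ = m).

*Adaptive step-up.* `p_adj(i) = min over j with p(j) ≥ p(i) of
min(1, m₀ · p(j) / rank(j))`; monotone in p, order-invariant, and equal
to textbook Benjamini–Hochberg when m₀ = m (property-tested against a
brute-force oracle). DMS status is adjusted p ≤ alpha (default 0.05).

*Sequential permutation.* The permutation null redraws the table from
the hypergeometric distribution with fixed margins — equivalent to
permuting read labels across conditions without storing reads. The
statistic is the exact-test p; sampling stops at h = 10 exceedances or
1000 draws, giving `h/N` on early stop and `(exceed+1)/(max_perm+1)`
otherwise, always in (0, 1]. Because the exact p is available, the
permutation path is a calibration cross-check (default mode uses exact
p + adaptive BH); both paths are exposed since either reading of the
procedure is defensible.

## DMR calling

Single-linkage chaining of DMSs with inter-site gap ≤ `max_gap`
(default 500 bp; a gap of exactly 500 merges — "at most" is inclusive),
never across chromosomes. Filters: (1) ≥ `min_dms` member DMSs
(default 5; the looser variant of the rule uses 4 and is exposed as a
flag — both thresholds circulate and the stricter one is the default);
(2) ≥ 80 % of member DMSs share the majority direction; a 50/50 split is
rejected outright since it cannot reach 80 %; (3) ≥ 80 % of *all*
covered CpGs inside the cluster hull change ≥ `min_delta` (default 0.1)
in the majority direction. The criterion-(3) denominator is covered
CpGs only: a site missing in either sample has no defined delta. The
0.1 magnitude filter applies at the region stage only, not at the DMS
stage. Emitted regions assert their own invariants on construction, and
re-running the two steps on a DMR's member DMSs reproduces the region
(idempotence, tested).

Gene association is strand-aware: a gene collects DMRs overlapping its
body (TSS..TES) or the 10 kb window strictly upstream of the TSS;
promoters are the 2000 positions ending at (and including) the TSS.

## Enrichment statistics

Compartment enrichment uses a 2×2 of foreground/background ×
inside/outside per labelled compartment with a two-sided Fisher test;
the background is the tested-site universe minus the foreground, which
removes coverage confounding relative to "all CpGs". A site overlapping
several compartments counts in each. Odds ratios are ad/bc with ∞ and
NaN sentinels for empty margins; BH q-values across labels accompany
raw p.

Cell-type-specific sites: all C(k, 2) pairwise DMS runs reuse the full
testing/FDR machinery per comparison (no pooled FDR). A site is
hyper-specific for type T when it is a DMS with T-higher methylation in
≥ 75 % of the comparisons involving T in which it was testable
(k = 5: 3 of 4; untestable comparisons leave a 3-of-3 denominator).
Sites qualifying as both hyper and hypo (possible only pathologically)
are dropped from both sets.

DMR enrichment on those sites uses the entire pool of cell-type-specific
sites as control: the reported fold is the hit-rate ratio against the
full pool (what is plotted), while the Fisher table contrasts the
foreground against the rest of the pool (a well-formed 2×2). Empty sets
yield NaN ("undefined"), not zero. The TF-overlap test is an upper-tail
binomial with null rate p₀ = fraction of control CpGs (covered ≥ 10×,
not differential) inside TF sites; a degenerate p₀ = 0 with observed
hits is floored at 1/(2·n_control).

## Metaprofiles

Anchor-centred curves assign each covered site within ±`flank`
(default 5000 bp, 50 bins — the axis span is a display choice, exposed
as config) of an anchor centre to a signed-offset bin, flipping the sign
for minus-strand anchors; a site near several anchors contributes once
per anchor. Per-bin mean and SEM are over site-level methylation values
(SEM = sd/√n, ddof = 1; single-site bins report SEM 0, empty bins NaN
with n = 0) — site-level averaging is what makes a "± SEM" band
meaningful. The DMS frequency curve divides per-bin DMS counts by
per-bin tested-site counts and normalises by the global DMS rate, so a
uniform scatter sits at 1 in every bin.

Metagene curves rescale the gene body to `body_bins` (default 60)
between TSS and TES, strand-aware with the TSS always on the left, and
bin flanks (default ±100 kb, 50 bins) in absolute bp. Bin methylation
is read-count weighted (Σmeth/Σcoverage) — the appropriate pooled
estimate for sparse CH data — with site-level SEM carried alongside.
CH profiles combine both strands relative to gene orientation.
Expression groups: genes with mean TPM < 1.0 (threshold configurable;
the cutoff is a convention, not a claim) are "not expressed"; the rest
are ranked (ties broken by gene id, stable) and split into terciles,
the lowest tercile absorbing the remainder first (301 → 101/100/100).
The fold-change utility treats the ≥ 1.5 boundary as inclusive, with a
default pseudocount of 0: 0/0 is excluded, x/0 counts as infinite
change.

## Co-methylation modules

Preprocessing keeps DMSs within TSS−10 kb..TES of ≥ 1 gene, chain-merges
loci ≤ 200 bp apart (merged level = coverage-weighted mean per
methylome), and drops loci with missing data in any methylome; each
step's removal count is recorded in the matrix provenance. The network
uses unsigned adjacency |corr|^6, topological overlap
`TOM(i,j) = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`,
average-linkage clustering on 1−TOM with a static cut at 0.75, minimum
module size 30, eigen-profile = first principal component of the
row-standardised module submatrix (sign-oriented to the module mean
profile), and iterative merging of modules with eigen-profile
correlation ≥ 0.75 (largest correlation first, ties to the smaller
module id, deterministic). These are the canonical weighted-network
defaults; no parameter set is claimed from data, and all are arguments.
Dynamic tree cutting is deliberately *not* re-implemented — the static
cut is a documented simplification, and the practical consequence is a
coarser module boundary for weakly separated blocks. Large inputs can
be pre-partitioned by k-means into blocks (`detect_modules_blockwise`,
fixed seeding, deterministic) with cross-block merging, mirroring
two-level blockwise clustering. The clustering contains no randomness:
identical input and parameters give identical assignments.

## Motif enrichment

Backgrounds are same-width regions shifted ± (offset + width) from each
target (offset default 2000 bp), so each lies entirely ≥ offset away;
regions off-chromosome or overlapping any target are dropped and
counted, leaving exactly 2×targets minus reported losses. Scanning uses
log₂-odds scores with a per-cell pseudocount of 0.01 against the PWM
background frequencies, on both strands (realised by scanning with the
reverse-complemented matrix); N bases contribute 0 log-odds; a sequence
is a hit when its best score reaches `score_fraction` (default 0.8) of
the maximum achievable score. The hit threshold is configuration, not a
claim — published scanners differ here, and the enrichment contract
(binomial upper tail of target hits at the background hit rate,
significant at p ≤ 1e−10) is independent of it. Zero background hits
floor the null rate at 1/(2·n_bg). Per-module reports extend module
loci to a fixed 200 bp centred window, and group motifs into families
by identifier prefix (MEF2A/B/C/D → MEF2) for reporting only.

## Synthetic data: what it emulates, and what it does not

The generators encode the data regime the analysis assumes:

* **Genome.** Random sequence scrubbed of accidental CG dinucleotides,
  with CGs planted at Bernoulli(0.02/bp) — the mammalian genome-average
  CpG density; spiked regions are topped up to 0.10/bp, the density of
  CpG islands and island shores where differential regions concentrate.
  The CpG map is exactly the planted set.
* **Methylomes.** Beta-binomial reads: true levels from a bimodal Beta
  mixture (~72 % hypermethylated mode Beta(20,1), ~25 % hypomethylated
  Beta(1,20), ~3 % intermediate), coverage NegBin(mean 20, size 5) for
  WGBS-grade tissue data, methylated counts Binomial(coverage, level).
  Coverage 0 is missing, distinct from level 0.
* **Spiked pairs.** Outside spiked regions both conditions share
  identical true levels. Spiked regions draw their baseline from the
  compartment matching the spike direction — hypo spikes start from the
  hypermethylated mode and vice versa — so the nominal effect size
  (default 0.3) survives clipping; this mirrors the dominant biological
  mode of regulatory-region demethylation. Default scenario: twenty
  1 kb regions with ≥ 10 CpGs each on a 500 kb locus set.
* **Cell-type panel.** Five types over a 5000-site candidate
  variable-site universe; 400 hypo- and 200 hyper-designated sites per
  type sit at the methylation rails in all non-focal types (level 1.0 /
  0.0) and differ by exactly 0.4 in the focal type; coverage
  NegBin(mean 30, size 100) — deep pooled public methylomes are
  near-Poisson, unlike tissue WGBS; 5 % of entries masked missing.
  Recovery is scored over testable designated sites (covered ≥ 10× and
  not masked in the focal methylome): an uncovered site is undetectable
  for any method, so counting it against recall would measure the mask,
  not the caller.
* **Modules, motifs, expression.** Planted co-methylation blocks share
  a latent profile (pairwise correlation ~0.9) squashed into [0, 1];
  motif scenarios embed the consensus of a strongly peaked 10 bp
  MEF2-like matrix into a fraction of uniform-random sequences;
  expression tables are zero-inflated lognormal with recoverable
  tercile structure.

Every generator is a pure function of (config, seed).

What passing these benchmarks does **not** show: robustness to
correlated biological replicates (the pair has none), bisulfite
non-conversion and mapping artefacts (not modelled), non-uniform genome
composition (background sequence is iid), realistic motif co-occurrence
and GC-matched backgrounds (flank backgrounds only), or the behaviour of
the histogram m₀ estimator under p-value discreteness worse than the
coverage regime simulated. Results on real WGBS data depend on those
factors; the benchmarks establish correctness of the statistics, not
field performance.

## Numerical choices and degenerate inputs

All-zero contingency tables are errors; odds ratios use ∞/NaN sentinels
rather than pseudocounts. Empty foregrounds, empty anchor sets, zero
DMS (frequency normalisation undefined) and empty backgrounds raise
rather than return silent zeros. Constant matrix rows make correlation
undefined and are rejected with the offending row named. Interval
conventions: BED 0-based half-open everywhere, cytosine positions
1-based, a site p inside [s, e) iff s < p ≤ e, converted in exactly one
utility. Scenario problem sizes (500 kb–2.5 Mb loci, 5000-site panels,
200-locus matrices) are chosen so the full benchmark battery recomputes
from scratch in well under a minute on one CPU — small enough to run on
every change, large enough for the Monte-Carlo bands used.

## Known limitations

No smoothing or dispersion-shrinkage DML model (deliberately out of
scope); CH-context differential testing is not offered (profiling
only); the static tree cut can split weakly separated modules; the
motif scan does not calibrate per-motif p-values by dinucleotide
shuffling; GO enrichment is not included. Readers and writers target
the plain-text dialects described above; BAM/bigWig are out of scope.
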