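# Methods

This note documents the models, the conventions that make results
well-defined, the synthetic-data generator's assumptions, and the numerical
and design choices made where more than one reasonable option existed.

## Coordinate conventions

All intervals are 0-based half-open `[start, end)` (BED convention)
internally; readers convert at the boundary. Strand is carried but used only
for promoter construction: for a `+` gene the promoter is
`[tss − upstream, tss + downstream)`, mirrored for `−` genes, with starts
clipped at 0. The default window is 2,000 bp upstream / 500 bp downstream —
a common choice for proximal promoters — and is exposed on the CLI because
promoter definitions legitimately vary. Peak summits are not used; all
overlap and distance computations use full peak intervals. Distances between
intervals are edge-to-edge gaps (bases strictly between), so overlap — and
exact abutment — give distance 0 and "same chromosome" is a prerequisite
(cross-chromosome distances are reported as unreachable/infinite).

## Co-binding and hypergeometric enrichment

Binding is binarized: a region is bound by a factor iff at least one peak
overlaps it, regardless of peak multiplicity, since the quantities of
interest (Venn counts, percentages of bound promoters) are region counts.
For a universe of N regions with K bound by A, n bound by B and k by both,
enrichment is the hypergeometric upper tail P(X ≥ k) — enrichment only; the
analyses never test depletion. The tail is evaluated as a log-sum-exp over
log pmf terms built from `gammaln`, because co-binding of large peak sets
over tens of thousands of promoters routinely produces p-values far below
the double-precision underflow threshold; the reported −log₁₀ p is computed
directly on the log scale and is always finite (`p_hyper` itself may
underflow to 0 in extreme cases and is reported alongside for convenience
only). The universe N is an explicit input everywhere — whether it is all
annotated promoters or only bound ones changes the test, so the caller must
say which set they mean.

For regions bound by A but not co-bound by B, the pipeline also counts those
whose nearest B peak lies within a configurable window (default 10 kb) of
the region. Because the natural denominator of that proximal fraction is
ambiguous (all A-bound regions, or only the non-co-bound remainder), both
fractions are always reported.

## TAD co-occupancy

Domain sets are first de-overlapped by the keep-shortest rule: while any
overlap remains, discard the longest interval currently involved in an
overlap (ties discard the larger start, so the leftmost of two equal-length
domains survives). The rule is deterministic, order-independent, and
idempotent; the result is overlap-free, which makes midpoint assignment a
partition. Note the rule is *discard-longest-first*, which is not always the
same set as *keep-shortest-first* greedy selection on overlap chains — the
test suite pins the intended behaviour with a three-interval chain example.

Each peak is assigned to the unique domain containing its midpoint (a peak
straddling a boundary belongs to exactly one domain); peaks whose midpoint
falls outside every domain are dropped rather than pooled into an
inter-domain bin. Enrichment of domains occupied by both factors is scored
two ways and both are always emitted:

* the hypergeometric test on binarized occupancy, as above;
* a permutation test whose null preserves the length–count relationship:
  domains are split into quantile length strata (default 10 bins, sizes
  differing by at most one, length ties broken by genomic position), and
  each iteration independently permutes the vector of per-domain factor-A
  counts within each stratum, likewise factor-B, then recounts domains with
  both factors. Default 10,000 iterations; a single seeded generator drives
  all shuffles, so results are bit-reproducible. The empirical p-value uses
  the add-one formula (1 + #{null ≥ obs}) / (1 + n_perm), bounded below by
  1/(n_perm + 1).

The statistic is integer-valued and its null is often heavily tied; the
add-one empirical p is therefore conservative, and the measured type-I error
at α = 0.05 sits slightly below the nominal level (≈ 0.03–0.06 under the
default synthetic conditions). Shuffling *counts* within strata (rather than
re-placing individual peaks) matches the modelled question — whether
occupied domains coincide — while exactly conserving each stratum's count
multiset, which the test suite asserts inside the permutation loop.

## Expression cascade

The pipeline starts from an exon × sample integer count matrix (alignment
and per-exon counting are upstream concerns). Stages:

1. **Biotype filter** — keep protein-coding, pseudogene and lincRNA exons by
   default.
2. **RPKM** — count / (exon length in kbp × library size in millions).
   Library size defaults to the column sums of the supplied matrix; an
   explicit aligned-read vector can override it, because true library sizes
   include reads outside the retained exons.
3. **Expression filter** — keep exons strictly above RPKM 10 in at least one
   sample (both cut and sample count configurable; strictness matters at the
   boundary and is pinned by tests).
4. **Fold-change filter** — on group-mean RPKM with a pseudocount (default
   1) to keep zero-expression exons well-defined, keep exons with ratio
   r > 4 or r < 1/4 (strict, two-sided on the ratio scale, i.e.
   |log₂ r| > 2).
5. **Gene summary** — per gene and sample, the maximum RPKM over the gene's
   surviving exons.
6. **Correlation and clustering** — Spearman correlation between samples
   over the differential exons (rank-based, so the raw/log-RPKM choice is
   immaterial); hierarchical clustering of genes with Ward linkage on the
   1 − Spearman dissimilarity after per-row z-scoring (population SD;
   zero-variance rows become all-zeros with a warning and are assigned
   distance 1 to every other row). Pairs of samples involving a constant
   column have undefined rank correlation and are reported as missing,
   never coerced to 0. Merge ties follow SciPy's deterministic
   lowest-index order; the dendrogram can be exported as Newick with
   height-difference branch lengths.

## Synthetic data: what it emulates, and what it does not

The generator produces every input the pipeline consumes, with defaults that
define the package's study conditions:

* **Domains** — 200 non-overlapping domains tiling three 60 Mb chromosomes
  with random gaps, lengths log-uniform on [50 kb, 2 Mb] so that length
  strata are genuinely heterogeneous (max/min length ratios ≫ 10). 150
  peaks per factor (400 bp each) give per-factor domain occupancy around
  35–45%. This deliberately scales *down* real TAD analyses (thousands of
  domains, occupancy near saturation): with only 200 domains, saturated
  occupancy would collapse the both-occupied statistic onto N and make the
  permutation null degenerate, so moderate occupancy is the regime in which
  the reduced-size study conditions remain informative.
* **Planted co-occupancy** — each factor-B peak is, with probability ρ
  (default 0.8), placed inside the domain containing a random factor-A
  peak's midpoint ("domain" mode) or within 10 kb of a random A peak
  ("near" mode, the regulatory-element regime); otherwise uniform. ρ = 0
  gives independence; ρ = 1 forces every B-occupied domain to hold an A
  peak.
* **Expression** — log-normal per-exon base means (median 100 counts,
  log-SD 1); 40% of exons near-silent in all groups (so the RPKM filter has
  realistic work — most annotated exons are unexpressed in any one tissue);
  20% of exons differential at a true ratio of 8 (half up, half down),
  comfortably past the 4-fold cut in both directions, so a noiseless
  fold-change filter retains exactly the planted set. Four groups — source,
  untreated knock-in, induced knock-in, target — with 2 samples each.
  The induced group's mean traverses fraction w (default 0.25) of each
  exon's *log* fold change: μ_induced = μ_source^(1−w) · μ_target^w. The
  geometric form was a deliberate choice over an arithmetic mixture: an
  arithmetic mean at w = 0.25 already covers ~53% of the log fold change of
  up-regulated exons while barely moving down-regulated ones, which places
  the induced group asymmetrically and does not robustly reproduce the
  partial-conversion correlation ordering; the geometric mixture moves every
  differential exon the same fraction of its log fold change and has the
  same endpoints (source profile at w = 0, target profile at w = 1). Counts
  are negative-binomial (variance μ + φμ², dispersion φ = 0.1, a typical
  bulk RNA-seq magnitude) with mild log-normal per-sample size factors
  (log-SD 0.1).

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: peak width and score distributions, clustering of
regulatory elements (promoters and enhancers are uniform, not gene-dense),
chromosome-scale coverage biases, GC/mappability artifacts, correlated
expression within co-regulated modules beyond the planted two-profile
structure, and isoform-level exon sharing (every exon maps to exactly one
gene). The synthetic results validate the statistical machinery, not any
biological claim.

All generators derive their streams from a single seed (independent
sub-streams per generator), so every output is bit-reproducible.

## Problem sizes

The shipped test-suite and acceptance-script runs use the default study
conditions: 200 domains with 150 + 150 peaks; 200 null replicates at 199
permutations for calibration and 50 replicates at 999 permutations for
power; 2,000-exon matrices over 8 samples, with 50 seeds for the trajectory
ordering check and 20 seeds per mixture weight for monotonicity; and 10,000
permutations wherever a single test is reported (the default n_perm). These
sizes were chosen so each statistic's sampling variability is small relative
to the effects being checked.

## Known limitations

* The permutation and hypergeometric tests share the binarized-occupancy
  view; neither models peak counts beyond presence/absence, and domains with
  many peaks are not weighted more.
* Quantile length strata equalize counts, not length spans; extremely skewed
  length distributions can place dissimilar lengths in one stratum (increase
  `--n-bins` when domains span several orders of magnitude).
* The empirical p-value's floor is 1/(n_perm + 1); strong enrichments
  saturate there and should be ranked by the hypergeometric −log₁₀ p
  instead.
* `remove_overlapping_keep_shortest` is quadratic per overlap cluster in the
  worst case; fine for domain-scale inputs (10³–10⁴ intervals), not intended
  for read-scale data.
* The BED reader applies no score/IDR filtering; if peak quality filtering
  is wanted, it must happen upstream.
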