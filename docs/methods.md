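# Methods

This note documents the models, numerical choices and limitations behind
`curvemut`, in the spirit of a package's statistical reference manual. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Dinucleotide-model shape features

A property value of a region is the dot product of the region's overlapping
dinucleotide frequencies with a 16-entry parameter vector. This is the
classical "frequency-weighted" formulation of sequence-dependent DNA
structure: it is linear in composition, so it captures regional averages of
step properties, not the three-dimensional trajectory of the helix. No
pentamer shape models or Monte-Carlo structure prediction are attempted —
the linear dinucleotide model is the deliberate scope.

The shipped table has 17 properties assembled from published compilations
(nearest-neighbour duplex thermodynamics; crystallographic base-step
geometry; a wedge-angle curvature composite; stacking, stiffness,
deformability, bendability and groove scales — provenance in the TSV
header). Two caveats:

- The original dinucleotide parameter sets behind the curvature literature
  are not uniquely fixed; different compilations differ in normalization
  and sign conventions. The engine is therefore *table-driven*: every
  analysis accepts a user TSV, and every structural guarantee in the test
  suite (oracle equivalence, linearity, window consistency) is
  table-independent. Correlation magnitudes computed with the shipped table
  are self-consistent within this package but are expected to differ in
  detail from values computed with other parameter sets.
- Physically strand-symmetric scales satisfy `v(d) = v(revcomp(d))`;
  signed step parameters (tilt, shift) are antisymmetric. Dinucleotides are
  counted on the given strand by default (matching CDS-oriented analyses);
  `strand_agnostic=True` averages a value with its reverse-complement score
  for genome scans. `symmetrized()` builds an explicitly strand-symmetric
  table.

Ambiguous bases: dinucleotides containing non-ACGT characters are skipped
and the denominator reduced; windows losing more than 10% of their
dinucleotides are flagged. Coordinates are 0-based half-open internally and
1-based inclusive in user-facing tables.

Site-centred scores use a 101-bp window (50 bp each side); sites whose
window overruns the contig are unscoreable and reported as such, except in
the CDS-only landscape simulation where the window is clipped at the CDS
boundary (no genomic flanks are assumed there; documented in
`synthetic._site_curvature_for_cds`).

## Landscape construction

A *potential nonsense site* is a coding position where at least one
single-base substitution converts the codon to TAA/TAG/TGA; the terminal
stop codon is excluded, and a position counts once even when two
substitutions there create stops (the substitution set is retained). The
packaged wild-type *URA3* CDS (804 bp, S288C) has 104 such sites, verified
against an exhaustive all-substitutions oracle.

Deduplication: identical mutations (same position, ref, alt) on the same
plate count once — recurrences within a plate are overwhelmingly clonal.
Records whose ref base mismatches the reference sequence are hard errors,
not skips, because silent coordinate-convention bugs are worse than loud
ones. The per-site count is the number of *distinct plates* observing a
stop-creating substitution at the site.

Windowed mutation rate = total counts / number of potential sites in the
window; windows with zero potential sites are flagged and excluded from
correlations. On disjoint windows the rate×sites totals conserve the
mapped count (a tested invariant).

### Model ladder

Per-site counts are regressed by OLS on (ladders of) one-hot base
identities at offsets 0, ±1, ±2, ±3 and the site-centred 101-bp curvature.
The response is the raw per-site count: it is what the landscape reports,
and OLS keeps the AIC comparison transparent. AIC uses the full Gaussian
convention `n·ln(RSS/n) + n·ln(2π) + n + 2(k+1)` with k+1 counting the
error variance; the convention is uniform across models so Δ-orderings are
convention-free, but *absolute* AIC values are only meaningful within one
run. RSS is floored at 1e-12 so a perfectly fitted (constant) response
keeps AIC finite, in which case the parameter penalty alone orders nested
models. All models are fitted on identical rows (sites with a complete
−3..+3 context and finite curvature); zero-variance predictors are dropped
with a warning. The logistic variant (mutated/not per site) uses the same
design matrix with a binomial likelihood and flags diverging coefficients
(|estimate| > 15 or non-convergence) as separation.

### Correlations

Spearman correlations are computed per property on the shared window grid
with pairwise-complete observations; constant tracks are flagged rather
than given a ρ. The partial correlation is the textbook first-order formula
on rank-transformed variables, with a t approximation on n−3 degrees of
freedom; a constant control contributes zero rank correlation, so the
partial estimate then equals the plain Spearman ρ.

### Binned per-type rates

Genome positions are ranked by 101-bp curvature and cut into equal-size
bins (`np.array_split`: sizes differ by ≤1). SNV types are
pyrimidine-normalized (purine-reference SNVs complemented), the standard
mutational-signature convention; the per-bin, per-type rate divides SNV
counts by samples × at-risk positions (positions whose base or complement
matches the type's reference pyrimidine).

## Permutation nulls

Both nulls are seeded (`numpy.random.default_rng`) and return the full null
vector alongside raw and add-one-corrected p-values
(`(b+1)/(n_perm+1)`, inclusive counting); the corrected value is the
default, so "beyond all 1000 nulls" reports p = 1/1001, never 0. Tie
detection uses a 1e-9 relative tolerance because statistics recomputed
along different floating-point summation orders can differ by ~1e-15.

*Dispersion*: statistic = sample SD (ddof=1) of per-site counts; null =
multinomial uniform assignment of the observed total to the sites;
upper-tail.

*Context-matched*: statistic = mean 101-bp curvature over observed sites;
each replicate draws, per observed site, a uniform random position with the
identical centred k-mer (k = 3 default, 7 supported) from the rest of the
genome; lower-tail. Design choices where the procedure is underdetermined:
sampling is with replacement across sites within a replicate (keeps every
context feasible); *all* observed positions are excluded from every pool,
not just the focal one; recurrent observed positions each draw their own
pseudo-site; contexts are taken on the reference strand as written (a
symmetrized table plus `strand_agnostic` scoring is the supported route to
strand-agnostic matching). A context with no alternative position is an
error listing the offending k-mers. `check_contexts=True` asserts context
identity per draw (test mode).

The region-restricted variant intersects the sampling universe with one
annotated region class; `context_match=False` relaxes matching to k=1
(pseudo-sites share only the mutated base).

Calibration is a tested property: when observed sites are themselves drawn
uniformly from the index, the corrected p is uniform (fraction below 0.05
within binomial bounds over 200 simulated datasets).

## Fluctuation assay

Only the p0 method and rank tests are implemented — colony counts from
Luria–Delbrück-style experiments are heavily overdispersed (jackpots), so
Poisson statistics on raw counts are invalid, while `P(zero plates)` is
clone-size-free: `rate = −ln(p0)` per culture. p0 = 0 is an explicit error
(rate not estimable by this method), p0 = 1 returns rate 0 with a warning.
Uncertainty is a plate-level percentile bootstrap (1000 resamples, seeded);
relative rates bootstrap both strains independently. VMR uses the sample
variance (ddof=1). Full MSS maximum-likelihood estimation and
plating-efficiency corrections are out of scope by design.

## Synonymous design

The search is simulated annealing (geometric cooling, default 0.9995 per
step) over single-codon synonymous swaps, scored by signed curvature minus
a large penalty (1e4 per unit) for violating the GC/CAI/structure
tolerances; the best *feasible* sequence seen is returned, so the reported
trace is non-worsening by construction. Annealing was chosen because the
neighborhood is tiny and discrete, the method is trivially seedable, and on
exhaustively enumerable toys (≤4 degenerate codons) it provably reaches the
brute-force optimum — a tested property. Non-convergence returns a
diagnostic result, never an exception. Default tolerances quantify "largely
unchanged": GC ±0.01 (absolute), CAI ±0.05, mean 20-nt windowed MFE ±5% —
deliberately user-tunable free parameters, since no canonical values exist.
CAI is the geometric mean of relative-adaptiveness weights over coding
codons (stop excluded); weights come from a user TSV or from relative
synonymous codon usage of a reference gene set (zero-count codons get a
small pseudo-weight so CAI stays defined). The folding engine is an
injected callable: a zero stub (tests), a toy GC counter (oracle checks),
or a ViennaRNA-backed engine when available; engine calls are memoized
during the search.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the analyses assume:

- `simulate_genome` — i.i.d. or first-order-Markov sequence hitting a
  target dinucleotide composition in the long-sequence limit.
- `simulate_site_mutations` / `simulate_cds_landscape` — exponential
  curvature→rate link `λ_i = λ0·e^(−β·z_i)`; exponential because rates must
  stay positive and because curvature effects are reported as rate ratios.
  Per sample/plate, sites mutate independently; the CDS variant emits only
  stop-creating substitutions (the selection analogue) with at most one
  record per (plate, site, substitution).
- `simulate_fluctuation` — Poisson(m) events per plate, geometric clone
  sizes (mean = `burst_dispersion` ≥ 1). This is the simplest mechanism
  giving overdispersion (VMR > 1) while keeping `P(zero) = e^(−m)` exact,
  so the p0 estimator's target is analytic.
- `simulate_selection_table` — a full synthetic stand-in for a sequenced
  selection-screen mutation table (the real one is a supplementary data
  file, not shipped here). It is *conditioned on the published summary
  marginals* of such a screen — 452 deduplicated mutations (154 nonsense /
  293 missense / 5 synonymous), 54 nonsense transitions vs 100
  transversions, per-site plate counts spanning 0–8, ~1000 raw isolates —
  while drawing the free structure stochastically: which sites are hit
  follows curvature-biased weights `e^(−β·z)` times a per-substitution
  transition/transversion rate ratio implied by the target tallies (URA3
  offers only 14 transition-type vs 109 transversion-type stop-creating
  substitutions, so transitions must be per-substitution hotter), plate
  assignments are random, and clonal duplicates pad the raw table. The
  default β comes from `effect_size_from_rate_ratio`: a 10% relative
  curvature decrease multiplying the rate by 1.7 converts, through the
  exponential link, to β = ln(1.7)/0.1 × (sd/mean) per standardized unit
  (≈0.33 on the packaged CDS and table).

What passing tests on these data do **not** show: that any particular real
genome exhibits the effect (the generators *install* the curvature→rate
dependence they are asked to), nor that the shipped parameter table matches
the historical one (correlation magnitudes are internally consistent, not
externally calibrated), nor anything about sequencing error, selection on
missense alleles, or repair-pathway biology, none of which are modeled.

## Problem sizes and determinism

Default analysis sizes were chosen so any workstation reproduces them in
seconds: 1000 permutations per test, 60-kb synthetic genomes for
genome-scale analogues, 200 simulated datasets for calibration checks,
10⁴ plates for estimator-bias checks, and a few thousand annealing steps
per design. Every stochastic routine takes an explicit seed;
`scripts/acceptance.py` derives all stage seeds from one `--seed`, and the
CLI records its seed, inputs (with checksums) and parameters in a run
manifest whose re-execution is byte-identical.

## Known limitations

- Shape scores are compositional averages; two sequences with equal
  dinucleotide content get equal scores regardless of arrangement.
- The context-matched null matches k-mer context but not broader features
  (replication timing, chromatin), which real analyses may need to control.
- OLS on small counts is a pragmatic choice for AIC comparison, not a
  generative model of counts; a Poisson GLM would be the natural extension.
- The designer optimizes one objective; multi-property trade-offs are only
  handled through the constraint box.
- `region_restricted_null` assumes a single-contig annotation frame;
  multi-contig genomes require per-contig calls.
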