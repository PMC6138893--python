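# curvemut

Intrinsic DNA curvature as a *cis* determinant of local mutation rate:
a tested, reusable pipeline for building mutational landscapes of coding
sequences from selected loss-of-function mutant collections, scoring
dinucleotide-model DNA shape features, testing curvature/rate associations
against bespoke permutation nulls, estimating mutation rates from
fluctuation assays, and designing synonymous gene variants with altered
curvature.

## The scientific problem

Mutation rates vary along the genome, and sequence-intrinsic (*cis*)
determinants of that variation are poorly characterized beyond the few-bp
scale of nucleotide context. One candidate *cis* feature is the physical
shape of the double helix: **intrinsic DNA curvature**, the
sequence-dependent deflection of the helical axis arising from interactions
between neighboring base pairs. `curvemut` implements the full analysis
chain needed to ask — and answer — whether regions of low curvature mutate
faster, for users such as yeast geneticists running 5-FOA/canavanine
selection screens, and genomicists relating mutation catalogs to sequence
features.

## The model at its core

All shape features are **dinucleotide-frequency linear scores**. For a
region *S* with overlapping-dinucleotide frequencies *f_d* (16 dinucleotides
*d*), the value of property *P* is

```
P(S) = Σ_d  f_d · v(P, d)
```

with `v(P, d)` a 16-entry parameter vector per property. The package ships
a 17-property table (curvature, tilt, roll, twist, thermodynamic and groove
scales, …; provenance in the file header); users may supply their own TSV.
GC content is computed separately.

On top of this scorer sit five analyses:

1. **Landscape** — enumerate *potential nonsense sites* (positions where one
   substitution creates TAA/TAG/TGA), count distinct plates observing each
   (dedup rule: identical mutation on the same plate counts once), derive
   per-window mutation rates `Σ counts / #sites`, and relate rate to shape
   via Spearman/partial correlations and an AIC ladder of OLS models.
2. **Resampling** — (a) a dispersion test: is the SD of per-site counts
   larger than under uniform multinomial assignment? (b) a context-matched
   null: is the mean 101-bp curvature at observed mutation sites lower than
   at random sites with identical centered k-mer context? Empirical p-values
   use the add-one correction `(b+1)/(n_perm+1)`.
3. **Fluctuation** — mutation rate per culture by the p0 method,
   `rate = −ln(p0)` with `p0` the fraction of zero-colony plates; VMR
   diagnostics; one-tailed Mann–Whitney comparisons; bootstrap CIs.
4. **Design** — simulated annealing over single-codon synonymous swaps to
   raise/lower curvature while GC (±0.01), CAI (±0.05) and mean 20-nt
   windowed MFE (±5%) stay near the wild type; protein sequence preserved
   exactly.
5. **Synthetic data** — generators for every input class, with an
   exponential curvature→rate link `λ_i = λ0·e^(−β·z_i)` (z = standardized
   101-bp curvature) so all stages are testable end to end without any
   external data.

## Worked example

Build the landscape of the packaged wild-type *URA3* CDS from a synthetic
selection table (a generated stand-in for a sequenced 5-FOA mutant
collection), then test dispersion and the curvature correlation:

```python
import curvemut as cm
from curvemut.landscape import (enumerate_potential_nonsense_sites,
                                per_site_counts, classify_mutation)
from curvemut.resampling import dispersion_test
from curvemut.synthetic import simulate_selection_table

table = cm.load_default_table()
ura3 = cm.load_ura3_cds()

raw = simulate_selection_table(ura3, table, seed=2018)
dd = raw.deduplicate()
land = per_site_counts(enumerate_potential_nonsense_sites(ura3), dd)
res = dispersion_test(len(land.sites), land.counts, n_perm=1000, seed=1)

rate = cm.window_mutation_rate(land, L=100, step=10)
curv = cm.window_profile(ura3.sequence, 100, 10, "curvature", table)
corr = cm.correlate_features(rate, [curv])[0]
```

Output:

```
sequenced isolates: 1000; distinct mutations after dedup: 452
nonsense: 154  missense: 293  synonymous: 5
potential nonsense sites: 104; per-site plate counts 0..8
dispersion: observed SD = 1.689, null mean = 1.211, p = 0.000999
curvature vs windowed rate (L=100): Spearman rho = -0.615, p = 1.2e-08
```

Reading: the 104 potential nonsense sites collected far more variable
per-site counts (SD 1.69) than any of 1000 uniform reassignments of the same
154 mutations (p = 1/1001) — the landscape is over-dispersed — and windows
with low intrinsic curvature have systematically higher mutation rates
(strongly negative Spearman correlation).

The same analyses are available from the shell:

```bash
curvemut --seed 1 simulate --what selection-table --cds ura3.fasta --out sim/
curvemut --seed 1 landscape --cds ura3.fasta --mutations sim/mutations.tsv --out land/
curvemut --seed 1 permute --mode dispersion --cds ura3.fasta \
         --mutations sim/mutations.tsv --out perm/
```

Every run writes a `manifest.json` (inputs + checksums, parameters, seed,
package version) and is byte-reproducible from it.

## Layout

- `src/curvemut/shape.py` — property tables, window/flank scoring
- `src/curvemut/landscape.py` — sites, counts, correlations, model ladder
- `src/curvemut/resampling.py` — permutation nulls
- `src/curvemut/fluctuation.py` — p0 rates, VMR, rank tests
- `src/curvemut/design.py` — CAI, structure strength, annealing designer
- `src/curvemut/synthetic.py` — data generators
- `src/curvemut/cli.py` — `curvemut` command
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
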