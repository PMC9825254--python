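# Methods

`hapsweep` detects and classifies hard versus soft selective sweeps from
phased haplotype panels, with explicit support for contrasting the X
chromosome with autosomes, and ships the forward simulation machinery needed
to calibrate and validate the scan. This note records the models, the
defaults and why they are what they are, the numerical choices, and what the
synthetic data do and do not establish.

## Haplotype homozygosity statistics

An analysis window's haplotype frequency spectrum `p_1 >= p_2 >= ...` yields

- `H1 = sum_i p_i^2` — haplotype homozygosity;
- `H12 = (p_1 + p_2)^2 + sum_{i>=3} p_i^2` — homozygosity after pooling the
  two most frequent haplotypes, sensitive to both hard sweeps (one dominant
  haplotype) and soft sweeps (a few dominant haplotypes);
- `H2 = H1 - p_1^2` and the ratio `H2/H1`, which rises monotonically with
  the softness of a sweep and, jointly with H12, separates hard from soft.

Missing data enter in two ways, mirroring how inbred-panel data are
processed. A haplotype with more than 10% missing calls in a window is
assigned frequency `1/N` (its identity is unreliable; treating it as a
singleton is conservative against inflating homozygosity). Haplotypes at or
below the cutoff are grouped by exact identity with residual MISSING treated
as a third allele state — two haplotypes differing only at a masked site are
*not* merged. The alternative (wildcard matching) would inflate H12; the
third-state rule errs the other way and is the implementation's standing
choice.

## Windows calibrated by SNP density

Windows are defined in SNPs (default 401) so H12 does not co-vary with local
diversity. Physical length follows from the median density: at the autosomal
median S/bp of 0.0345 a 401-SNP window spans 11,623 bp; at the X median of
0.0227 it would span 17,665 bp. To keep X and autosomal windows comparable
in physical length the X window is recalibrated to
`0.0227 x 11,623 ≈ 264 SNPs` (half-up rounding of the physical length first,
then of the SNP count, reproduces the DGRP calibration arithmetic; 265 is accepted
via configuration), and autosomal windows are down-sampled to the same SNP
count, with a fresh uniform subsample per window from a seeded stream.

Significance uses a 1-per-genome FDR line: the 10th highest H12 among
neutral simulations numbering ten times the count of independent analysis
windows. Peaks are consecutive above-threshold windows, valued at their
highest window; candidates are accepted highest-first with a 500-kb
exclusion radius between apex centers (strictly closer candidates are
dropped; the 500-kb radius groups windows produced by one selective event),
and peaks overlapping recombination-map intervals below 5e-7 cM/bp are
masked, since low recombination itself elevates haplotype homozygosity.

The footprint heuristic `L ≈ s / (ln(Ne*s) * rho)` (rho in Morgans/bp,
i.e. cM/bp divided by 100) is exposed as a utility for judging which
selection strengths a window length can capture. It is a heuristic only;
its plug-in values are order-of-magnitude guides.

## Forward Wright–Fisher engines

Both engines simulate a sexed diploid population of `N` individuals with
non-overlapping generations. Each offspring draws a mother in proportion to
female fitness and a father in proportion to male fitness (fecundity
selection), sex is Bernoulli(1/2), and fitness at the focal locus is
`1 : 1 + h*s : 1 + s` for 0/1/2 copies. X transmission: females carry two X
copies, males one (received from the mother); fathers pass their X to
daughters unrecombined. Dosage compensation is assumed throughout — a
hemizygous carrier male has the homozygous fitness `1 + s` (under
sex-specific selection, the homozygous effect of the male coefficient).
Simulating the same `N` individuals under X transmission automatically
yields 3/4 the mutational input of an autosomal run at equal per-copy rates,
which is exactly the `theta_X = 0.75 * theta_auto` convention; the
"adjusted N_eX" variant raises the X run to `4N/3` individuals instead.

Parameters are population-scaled: `theta_A = 4*Ne*mu_A` for the adaptive
rate, `theta_neutral` per 10-kb locus (default 40, i.e. 0.004 per bp — the
value implied by mu = 1e-9/bp at Ne = 1e6), rho in cM/bp (default 5e-7).
Rescaling by `Q` divides Ne and multiplies `s`, mutation and recombination
rates by `Q`, leaving `theta` and `Ne*s` invariant; it is reliable for
`|s*Q| < 0.1` and a warning is raised beyond that.

Two implementations share this model:

1. **Full engine** (`Population`): every individual carries a recombining
   10-kb locus with infinite-sites neutral mutations (uniform positions,
   duplicate positions rejected; crossovers Poisson over the locus with no
   interference). Used for neutral calibration, single-origin
   standing-variation runs and haplotype sampling.
2. **Sparse engine** (`SelectedLocusSim`): tracks only carriers of the focal
   allele, each copy labelled by its mutational origin, with exact
   multinomial/hypergeometric sampling of carrier offspring and a geometric
   fast-forward across carrier-free generations. Because neutral sites have
   no fitness effect, the selected-locus law is identical to the full
   engine's — the sparse engine is a marginalization, not an approximation —
   and the two are checked against each other distributionally in the test
   suite (fixation probabilities, Haldane's `2hs` oracle). Two deliberate
   O(mu^2) shortcuts: the conditional mutation count after a fast-forward is
   drawn as `1 + Binomial(copies-1, mu)`, and on the X the fast-forward uses
   the expected copy number `1.5N`.

At most one adaptive allele per chromosome copy is modelled; a new mutation
hitting a carrier copy is a no-op.

## Experiment designs

All four replicated designs classify a fixed sweep as **soft** when the
sampled 100 copies carry two or more distinct origin labels and **hard**
when exactly one.

- **Recurrent beneficial mutations**: mutations enter at `theta_A` and the
  run ends at fixation of the allele across all copies.
- **Dominance shifts / constant dominance**: recurrent deleterious
  mutations (`theta_del`, `s_d < 0`, `h_d`) for a 10-Ne burn-in; at the
  environmental shift selection becomes (`s_b = -s_d`, `h_b`) and mutation
  stops (optionally continuing, in which case the fraction of sampled
  origins predating the shift is reported). Outcomes partition into
  `no_sgv` (no copies at the shift), `lost`, `hard`, `soft`.
- **Single-origin standing variation**: one deleterious mutation at the
  locus center of the full engine, re-introduced on loss until it reaches a
  conditioning frequency PF; selection then flips to beneficial and runs to
  fixation (loss restarts the conditioning). Softness is proxied by the
  number of distinct haplotypes bearing the allele in the sample, since a
  single origin can recombine onto multiple backgrounds.
- **Sexual antagonism**: `Ne*s_b = 100` in the advantaged sex and
  `s_d = -k*s_b` with `k = 0.1` in the other, same `h` in both sexes
  (sex-specific dominance is not modelled); runs that hit the generation
  cap are reported as a separate `not_fixed` category.

Desk-scale defaults are Ne = 2,000 with `Ne*s = 100` and `theta` at study
values, 300–1,000 replicates per parameter combination; compound-parameter
invariance under rescaling is what licenses working at this size, and the
directional contrasts (origins increasing with theta_A, fewer origins on
the X, dominance shifts softening autosomal sweeps at the expense of lost
sweeps, scarcer standing variation on the X, antagonism with male
disadvantage hardening the X) are asserted as one-sided rank or proportion
tests at alpha = 0.01.

Two directional expectations did not survive implementation and are
reported as the model's own findings. First, with equal individual counts
and `theta_X = 0.75 theta_auto`, sweeps fix *faster* on the X at both
dominance extremes, because hemizygous exposure of the last wild-type
copies accelerates the X's end phase more than the 25% lower mutational
input slows its start; the faster-X direction for recessive alleles is
asserted, and no test asserts a slower X for dominant ones. Second, the
X-versus-autosome origins deficit vanishes for fully dominant mutations:
at `h = 1`, dosage compensation makes per-copy establishment identical on
the two chromosome classes, and the X's lower mutational input is offset
by its smaller copy pool (a surviving origin sits at higher frequency and
clears the sample-detection floor more easily) together with its faster
end phase — at `theta_A = 0.4` the contrast is statistically null (3,000
replicates per side) and at `theta_A = 4` it reverses. The corresponding
dominant-case acceptance assertion therefore fails by design rather than
being weakened; the recessive-to-additive contrasts are robust.

## ABC hard/soft classifier

Training simulates sweeps at `theta_A = 0.01` (hard regime) and
`theta_A = 10` (soft regime) with nuisance priors `s ~ U[0,1]`,
`T_E ~ U[0, 1e-3] x 4Ne` (time since selection ceased), `PF ~ U[0,1]`
(frequency when selection ceased) and `h ~ U[0,1]`. Selected-locus dynamics
run on the sparse engine at a desk-scale Ne of 1,000; each replicate's
sample window is assembled from a fresh msprime neutral background at the
scan's SNP density: copies sharing an origin inherit that origin's
background row (their common ancestor), plus Poisson mutational noise
proportional to the origin's age. The noise clock runs at the nominal
constant-Ne model size (2.7e6), not the engine's: `mu*t` is only
rescaling-invariant when `s` is rescaled too, and the priors draw `s`
unrescaled, so a desk-scale clock would inflate within-sweep mutation by
roughly the Ne ratio. Within-sweep recombination leakage is not modelled;
the star-genealogy approximation (all noise private to a copy) is standard
for sweeps.

The Bayes factor at an observed `(H12, H2/H1)` point is the ratio of soft
to hard training points within Euclidean distance strictly less than 0.1.
`BF <= 1` calls hard, `BF > 1` soft, `BF >= 30` strong soft; a point with
no training neighbors is `unclassified` rather than defaulted. The grid of
nodes (step 0.025) exists for visualization and caching; classification
always re-counts at the observed point, removing grid-step sensitivity.
X-mode training offers both standard conventions: 0.75-scaled Ne without
hemizygosity (the coalescent convention) and explicit hemizygous forward
runs.

## Synthetic DGRP-like data

Neutral arms are msprime coalescent samples (n = 100 haplotypes) with
mutation rate set so the expected sample density matches the target
(autosome-like 0.0345/bp, X-like 0.0227/bp via Watterson's
`S/bp = theta*a_n`), rho = 5e-7 cM/bp, and X arms at 0.75 Ne. Sweeps are
embedded parametrically: `round(PF*n)` rows become copies of one core
haplotype (hard) or of k cores with Dirichlet(1,...,1) relative frequencies
(soft), plus Poisson noise. Defaults: span 50 kb (the footprint heuristic
gives ~1 Mb for s = 0.05, so 50 kb is conservative while keeping analysis
windows inside the span even at swept-region density), noise 1.5 mutations
per swept haplotype, and k = 10 origins for soft sweeps — the scale implied
by the `theta_A = 10` soft regime the classifier trains on (the Ewens
expectation at theta = 10 is ~24 origins in n = 100; k = 10 is a
conservative representative). Cores are required to be pairwise distinct at
5+ sites, otherwise a "soft" fixture can collapse into one observable
haplotype class and its truth label would be wrong by construction.
Missingness mimics masked residual-heterozygosity tracts: contiguous
per-haplotype tracts (20 kb) to a per-haplotype target fraction drawn from
U[0, 0.15], then heavy site-level dropout at a configurable fraction of
sites, intended to be fed through the >=50% site-call filter.

What passing the end-to-end test shows: on two 1-Mb arms with two hard and
two soft sweeps, the scan + FDR + peak + ABC pipeline recovers and labels
planted sweeps of moderate-to-strong effect under realistic density and
missingness. What it does not show: performance on real demography
(admixture, bottlenecks), inversion polymorphism, gene conversion, or
sweeps much weaker/older than the planted ones; the fixture matches DGRP
only in mean density and missingness structure, not in site-frequency
spectrum or LD detail.

## Numerical and procedural choices

- Half-up rounding for all SNP-count/length calibrations (reproduces the
  DGRP calibration values 11,623 / 17,665 / ~265).
- IBD filtering is one-shot on the original table; higher thresholds never
  remove more strains, and refiltering the retained set is a no-op.
- Down-sampling to `k` strains keeps the smallest per-chromosome missing
  fractions, ties broken lexicographically by strain id for determinism.
- Diversity: `pi` per site uses the unbiased `2*p*q*n_c/(n_c-1)` with
  site-specific callable counts; bootstrap CIs are percentile, resampling
  10-kb windows (the estimator's unit), 1,000 replicates by default.
- LD: R² over haplotypes non-missing at both sites, allele frequencies
  restricted to [0.05, 0.95], at least 4 complete pairs; smoothing averages
  R² in 20-bp distance bins to 300 bp and 150-bp bins beyond. The pair set
  is all pairs within one window length, which is what the sliding
  formulation visits.
- Peak ties (equal apex H12) rank by smaller coordinate; window coordinates
  are first/last SNP positions with the center at their midpoint.
- Seeds: every stochastic entry point takes an explicit seed or Generator;
  replicate batches derive per-replicate seeds from a SeedSequence, so any
  replicate is individually reproducible.

## Known limitations

- The sparse engine raises if more than ~8,000 origins segregate
  simultaneously (never approached at the study's theta values).
- The full engine's per-generation cost grows with segregating neutral
  sites; it is meant for Ne up to a few thousand at 10-kb loci.
- The ABC training generator is a desk-scale stand-in for coalescent
  simulations under fitted demographies; an import path accepts externally
  generated (H12, H2/H1) tables for users with their own null models.
- Classification near the neutral corner (low H12) is intrinsically
  ambiguous; equal local densities yield BF = 1, which the convention
  assigns to "hard".
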