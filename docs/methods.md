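# Methods

`crossim` simulates recurrent genomic selection in a self-pollinated crop and
ranks candidate crosses by the predicted trait values of in-silico progeny.
This note documents the model, its assumptions, the defaults, the numerical
choices, and what the synthetic benchmark does and does not show.

## Genome and trait model

The simulated species is diploid with 20 linkage groups of 150 cM each.  A
quantitative trait is controlled by a configurable number of biallelic loci
(30 or 100 in the benchmark), placed uniformly at random over the groups with
continuous positions — continuous placement matches the crossover model and
makes coincident loci a probability-zero event (ties, if constructed
manually, are broken by locus order).  Inheritance is strictly additive: no
dominance, epistasis, mutation or sex linkage.

Effect magnitudes are drawn i.i.d. from Gamma(shape 0.4, scale 1.66), the
long-tailed architecture standard in genomic-selection simulation (mean
0.664, variance 1.102).  Each locus's favorable allele is assigned to founder
A or B with probability 1/2 by default, so both founders of the biparental
population contribute favorable alleles, as in a real elite-by-elite cross;
an `all_positive` mode assigns every favorable allele to founder A for the
symmetric architecture.  After the initial population is built, all effects
are multiplied by one constant so that the sample variance (ddof = 1) of
genetic values in that population is exactly 1.0; this fixes the trait unit.
The scaling reference is the F8 initial population, not the F2, because the
F8 set is what the selection scheme starts from.

Genotypes are coded +1 (homozygous founder A), 0 (heterozygous), -1
(homozygous founder B); the genetic value is GV = Σ_j s_j β_j x_j with
s_j = +1 when A is favorable and -1 otherwise, so the favorable homozygote
always contributes +β_j and the ideal genotype reaches Σ|β|.

Phenotypes add independent N(0, σ²_e) noise with σ²_e = σ²_g (1-h²)/h² at
σ²_g = 1.  σ²_e is held constant over cycles even as genetic variance erodes
(the standard convention; realized heritability therefore declines in later
cycles), and environmental deviations are redrawn at every phenotyping.

## Meiosis

Crossovers follow a no-interference model: Poisson(L/100) crossover events
per group with uniform positions, the process underlying the Haldane map
function r(d) = (1 - e^(-2d/100))/2.  Two implementations coexist:

* a per-meiosis engine that simulates explicit crossover events (and can
  report crossover counts);
* a batch engine used by everything population-scale: the parental phase at
  the first locus of each group is a fair coin and flips between consecutive
  loci with probability r(d).  Because a Poisson process has independent
  increments, this is *exactly* the same distribution at the mapped loci, not
  an approximation; the two engines are cross-checked against each other and
  against the Haldane closed form in the tests.  Restricting simulation to a
  subset of loci (the prediction model's markers) is likewise exact, which is
  what makes ranking ~19,000 crosses x 200 progeny per call affordable.

Phase at the start of each group is redrawn per gamete (no cross-group phase
correlation).  The F8 initial population descends from one fully heterozygous
F1: n independent F2 offspring, each advanced by six further single-seed
descent selfings — seven meioses in total, leaving expected residual
heterozygosity 2^-7 ≈ 0.78% per locus.

## Prediction model

The marker-effect model y = μ + Σ β_j x_j + ε is fitted with the lasso
(scikit-learn's coordinate descent), penalty chosen at the minimum of the
10-fold cross-validated error over a 100-point decreasing λ path (eps 1e-3).
The minimum-CV rule (not the 1-SE rule) is used.  Fold assignment is
randomized from the caller's generator and the fold seed is stored in the
model metadata, so fits are reproducible.  The intercept is unpenalized;
predictors stay on the raw code scale since all columns share the same unit.
In simulation mode the predictors are the true trait loci (no
marker-discovery step is modeled); in empirical mode they are whatever
markers the supplied model file names.  A constant training response returns
an intercept-only model with a warning rather than an error.

## Cross ranking and strategies

For every unordered pair of parents (no self-crosses; n plants give
C(n,2) candidates) the engine simulates `n_f1` F1 plants, selfs each
`n_f2_per_f1` times, computes PVs of all F2, and scores the cross by the
mean PV of its k best progeny ('high' direction; k worst for 'low').  The
tail mean rewards crosses with a good mean *and* a large progeny variance.
The reported per-cross variance is the sample variance of all progeny PVs.
Ranking is best-first with ties broken by ascending parent indices; the
chunked random-number consumption is fixed, so a seed fully determines the
ranking file bytes.

The six benchmark strategies spend an identical budget of 10 F1 per cycle:
S1/S5/S10 take the top 1/5/10 ranked crosses (10/2/1 F1 each); P1 crosses
the two plants with the best own PVs (10 F1); P5/P10 chain the top 5/10
plants round-robin ((1,2),(2,3),…,(k,1); 2/1 F1 each).  P5's pairing is not
uniquely dictated by the scheme's description; round-robin is adopted by
analogy with P10.  Each F1 is selfed equally often to pool a 200-plant F2
population (divisibility of the budget is enforced).

For the S strategies inside the benchmark the per-candidate simulation uses
n_f1 = 5, n_f2_per_f1 = 40 (200 progeny, k = 10), mirroring the 200-plant
populations the scheme actually grows; the count is configurable since
heterozygous parents (from cycle 2 on) make genuinely variable F1.  In
empirical mode the default is 5 F1 x 50 F2 = 250 progeny with
k = max(1, floor(0.05 n)) — 10 of 200, 12 of 250 — overridable via
`--top-k`.

## Selection scheme

Five cycles by default.  The cycle-1 model is trained on the initial F8
population's phenotypes and shared by all strategies of a replicate; models
are retrained at odd cycles (3, 5) on the current population only
(non-cumulative training) and reused at even cycles.  Metrics are computed
on each cycle's newly produced F2 population, with the initial population
reported as cycle 0: maximum genetic value (MGV), proportions of trait loci
fixed favorable / fixed unfavorable / unfixed (a locus where every
individual is heterozygous counts as unfixed), and selection accuracy
(Pearson r between PV and GV; reported as NaN with a warning when either is
constant, and excluded from means).  When every trait locus is fixed, no
selection can change the population and the last record is carried forward
unchanged to the end of the scheme.

Within a replicate all strategies consume the same initial population and
architecture and independent downstream random streams (per-strategy child
seeds of one master seed), making the per-cycle comparison a matched-pairs
design; strategy contrasts use a two-sided paired t-test on per-replicate
MGVs with Bonferroni adjustment (p × number of comparisons, capped at 1).

## Problem sizes in the shipped tests and acceptance script

The full-scale benchmark (50 replicates, all six strategies, both QTL
counts, three heritabilities) is available through `run_experiment` and the
CLI.  The shipped test suite and `scripts/acceptance.py` exercise a
scaled-down version chosen as a sensible desk-scale design: 10 matched
replicates at QTL = 30, h² = 1.0, comparing S10 vs P10 over five cycles
(genetic gain) and S1 vs S10 over two cycles (the single-cross bottleneck
in segregating-locus proportion).  Distributional checks use 1e5 gametes
(Haldane), 1e4 lineages (single-seed-descent heterozygosity), and 10–20
refit replicates (selection accuracy at h² = 1).

## Synthetic empirical-mode panel

`generate_fixture` fabricates the inputs a real deployment would read: a
biparental RIL panel (default 194 lines, simulated F2 + SSD to F8) genotyped
at 513 mapped markers of which 29 carry effects, phenotypes at a chosen h²
(default 0.6), and a lasso model fitted to those phenotypes.  It emulates
the *shape* of a real soybean panel but none of its biology: markers are
placed uniformly rather than along a real map, effects are gamma draws
rather than mapped QTL, there is no genotyping error, missingness,
segregation distortion, or genotype-by-environment interaction, and
phenotypes come from the same additive model the predictor assumes.  Tests
passing on this panel therefore demonstrate the machinery (bookkeeping,
determinism, statistical behavior under the stated model), not predictive
performance on real data.

## Known limitations

* No crossover interference; genetic map only (no physical coordinates).
* Heterozygous loci read from coded genotype files get an arbitrary phase
  (phase is not identifiable from codes); harmless for inbred panels, wrong
  for strongly heterozygous input.
* Accuracy of empirical-mode rankings is bounded by the supplied marker
  model; no marker discovery or model validation is performed here.
* Environmental variance fixed at its initial-population value; no
  multi-environment or GxE structure.
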