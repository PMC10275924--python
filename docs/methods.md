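# Methods

This note documents the models implemented in `aedes_gss`, the default
parameters and why they hold their values, what the synthetic-data
generators do and do not emulate, and the numerical conventions used
throughout.

## Sex-locus genetics (`aedes_gss.genetics`)

*Aedes* sex determination is modelled as a biallelic locus on chromosome 1:
females are m/m, males are m/M.  A haplotype is a sex allele plus an
optional linked fluorophore marker; a genotype is an unordered haplotype
pair.  M/M is rejected as invalid input rather than silently modelled:
mothers never transmit M, so no cross representable in this model can
produce it, and its appearance indicates an upstream data error.

**Recombination.**  Marker–sex-locus linkage is summarized by a single
scalar `r` per strain, the per-meiosis probability of a crossover between
marker and sex locus (`0 ≤ r ≤ 0.5`).  A parent's gamete distribution puts
mass `(1−r)/2` on each parental haplotype and `r/2` on each of the two
recombinant haplotypes (markers swapped between the sex alleles); when the
two haplotypes carry identical marker state the distribution collapses and
recombination is invisible.  Crosses multiply the two parental gamete
distributions and aggregate by genotype.  Recombination is applied
independently in each parent's meiosis at that parent's strain rate; the
sex of origin of observed recombinants is generally unknowable from
phenotype screens, so a symmetric per-parent rate is the natural default —
it is a modelling choice, not an empirical claim.

**Crossing scheme.**  Crossing non-transgenic females of an M-linked strain
to hemizygous marked males of an m-linked strain gives, exactly, a
non-fluorescent offspring class of mass ½ for *every* `r`
(`(1−r)/2` m/M males + `r/2` m/m recombinant females), within which the
female fraction — the contamination a fluorescence sorter cannot remove —
is exactly `r`.  `contamination_closed_form` returns this identity and the
test suite verifies it against full genotype enumeration over a grid of
rates.

**Colony propagation** uses discrete, non-overlapping generations with
fixed numbers of retained mothers and fathers, matching a per-generation
sorting maintenance regime.  Three retention policies are modelled: `none`
(retain by sex only; recombinant lineages accumulate roughly linearly in
generation number), `phenotype` (retain only the strain's canonical
(sex, copy-number) classes — what a fluorescence sorter achieves), and
`perfect` (an idealized visual re-check that removes every non-canonical
genotype; the recombinant frequency observed at sorting then stays at the
single-meiosis rate).  The founder pool is filtered under the same policy
as every later generation.  Parent sampling is multivariate
hypergeometric; cohorts are multinomial; everything is seeded.

**Rate estimation.**  Recombination rates of order 1e-4 put normal
approximations far outside their validity, so interval estimates use the
exact (Clopper–Pearson) binomial interval via the beta quantile function;
the tests verify it against direct root finding on the binomial CDF.  The
estimator is agnostic about event clustering: where several recombinants
plausibly descend from a single meiotic event, the user chooses whether to
score them as one event or several (both readings are one `ScreeningRecord`
away).

## Sort calibration and planning (`aedes_gss.sorting`)

Male recovery versus sorting speed is fitted with a degree-two polynomial
and female contamination with a straight line, both by ordinary least
squares.  Replicates are averaged per speed before fitting by default
(replicate-level fitting is a flag).  The contamination line includes an
intercept; r² is computed as 1 − SS_res/SS_tot.  Predictions are clipped to
[0, 1] because a quadratic fit can stray outside physical bounds at the
range edges.  Predicting outside the calibrated speed range warns;
the stochastic sort simulator treats an out-of-range speed as a hard error.

A numerical note: the quadratic that exactly interpolates the three
calibration means (0.915 at 6, 0.696 at 60, 0.269 at 300 larvae/s) has its
vertex at ≈295 larvae/s, so it is monotone decreasing only up to a ~2e-4
uptick at the very top of the range.  The monotonicity test therefore
allows a 1e-3 tolerance, an order of magnitude below replicate noise.

Reservoir concentration maps to sorting speed proportionally through the
single measured anchor (200 larvae/mL ↔ 60 larvae/s); with only one anchor
available, proportionality is the minimal assumption and is isolated in
`concentration_to_speed`.

Planning arithmetic: expected males from a reservoir are floored; larvae
needed for a male target are ceiled (resource planning must never
under-provision).  Both roundings are guarded with a 1e-9 epsilon against
binary representation error (50,000 × 0.5 × 0.696 must give 17,400, not
17,399).  The sort simulator keeps each target-class larva with the
predicted recovery and leaks each non-target larva with the predicted
contamination, as independent seeded binomials.

## Event analysis (`aedes_gss.copas`)

Event tables carry TOF and EXT (size proxies, strictly positive) and two
fluorescence channels (nonnegative) in instrument arbitrary units.  All
analysis happens in log10; fluorescence is offset by one unit before the
log to tolerate zeros (negligible at signal level).

The cleaning pipeline has four stages in fixed order: manual bounds on log
size, bounds on the first two principal components of the size variables,
manual bounds on log fluorescence, and bounds on the first two principal
components of the fluorescence variables.  The *structure* is fixed; the
thresholds are defaults, not doctrine — ±3 SD per variable or component,
all overridable.  Manual-stage bounds use robust statistics (median and
normal-scaled MAD): a visual screen centres on the main cloud, and planted
outliers must not inflate their own inclusion bounds.  PCA stages store the
fitted projection (center, optional scaling, loadings) inside the
`FilterSpec`, so a materialized pipeline is idempotent: re-applying it to
its own output removes nothing.  PCA centers always; scaling is off by
default (the common default of base-R decompositions) and is a flag.

Clustering is standard Lloyd k-means on the (log green, log red) plane —
size variables are filter-only — with seeded random initial centroids and
10 restarts by default, keeping the best within-cluster sum of squares.
`k` is user-specified: 2 for single-strain sorts, 3 when an intermediate
class is expected.  Gates are named rectangles in log-fluorescence space.
All intervals, filters and gates are half-open `[low, high)`; an event
exactly on a boundary is excluded from the gate.  Cluster labels are
1-based.

## Facility model (`aedes_gss.facility`)

A deterministic, steady-state weekly-flow model.  From a weekly male
release target it back-calculates egg demand through sorting recovery, the
sex ratio, stage survivals and hatch, then sizes every colony:

* **Size-sorting systems** (manual or automated pupal sorting): one
  self-sustaining production colony; all larvae of the release line are
  reared to pupation, and males are recovered at the pupal sorter.
* **GSS**: the release line is sorted at L1, so non-kept larvae exit after
  the one-day L1 stage — the driver of the larvae savings.  The rearing
  colony's replacement adults hatch from a dedicated filter colony whose
  own replacements are double-sorted every generation (COPAS pass at L1
  plus a manual pupal re-check) to purge recombinant contaminants.
* **GSS-CS**: two filter/rearing chains (one per strain) feed cross cages
  whose parents are themselves L1-sorted each week; the cross cages lay the
  release-line eggs.

Self-sustaining colonies solve a one-line balance, `F·epf = E_out +
(2F/L)/e`, where `F` is females, `epf` weekly eggs per female, `L` the
adult replacement interval in weeks, and `e` the egg→adult efficiency of
the replacement rearing stream (including sorting losses for filter
colonies); the model raises a divergence error when fecundity cannot cover
replacement demand.  Standing stocks are weekly throughput × stage
residence time in weeks, summed over streams — the natural constant-regime
reading of "individuals present at any time".  Equipment and staff are
provisioned in integer units by ceiling of demand over capacity.  Costs are
computed in euros and converted to dollars once, at a configured rate; all
percent comparisons between systems are provably invariant to that rate
(and tested to be).

**Parameterization.**  The bundled default config
(`src/aedes_gss/data/facility_defaults.yaml`) separates *anchored* values —
measured COPAS recovery of 69.6% at the 60 larvae/s operating speed, ~30%
male recovery for pupal size sorting, a €40k refurbished COPAS quote,
52 operating weeks, 20-year building amortization, and the 1-filter +
1-rearing (GSS) / 2+2 (GSS-CS) colony structure — from *assumed* values
(fecundity, survivals, stage durations, densities, unit costs, staffing
rates), which are field-typical figures chosen once and marked in the
config with per-value provenance comments.  The model code contains no
parameter literals.

**Known limitation.**  With this parameterization the model reproduces the
*direction and ordering* of the published system comparisons (L1 sorting
dramatically cuts larvae, space, diet and labour; the automated pupal
sorter is the most expensive option) but not their magnitudes: it yields
≈−80% larvae for both GSS variants versus manual pupal sorting, where the
original interactive spreadsheet analyses report −65% (GSS) and −46%
(GSS-CS), and correspondingly larger diet savings.  The gap sits in the
colony-chain internals of that spreadsheet (notably how heavily the
GSS-CS double chain weighs), which are not reproducible from its published
description; this model's steady-state chain is deliberately simple and
fully documented instead.  The corresponding acceptance test asserts the
published percentages and is expected to fail under the default
parameterization — a faithful record of the discrepancy rather than a
reverse-fitted configuration.

## Synthetic data (`aedes_gss.synth`)

Generators are pure functions of (config, seed) and provide every input the
other modules consume, with truth labels retained.

* **Events**: log10-normal clouds per phenotype class.  Default placement:
  negative autofluorescence at log-green 1.0, one marker copy at 3.0, two
  copies 0.3 log10 brighter (≈2× signal), all with SD 0.15 — ≥6 SD
  separation between negative and hemizygous so default gates and k-means
  are near-perfect; a `hard` preset narrows this to ~2 SD for stress tests.
  The intermediate nuisance class (dead or low-expressing fluorescent
  larvae) sits midway at log-green 2.0 with a wider SD of 0.25 and
  deliberately falls between the default gates; its proportion defaults to
  2% where enabled.  Size outliers (debris, doublets) draw their size
  uniformly over an inflated log range to exercise the manual size filter.
* **Calibration**: recovery = quadratic(speed) + Gaussian noise truncated
  to [0, 1]; contamination = linear(speed) + noise truncated at 0; default
  three replicates at speeds (6, 60, 300).
* **Screenings**: binomial recombinant counts at a configured true rate.

What passing tests on these data show — and do not show.  The generators
emulate the *structure* of sorter output (class geometry in log space,
mixture proportions, sampling noise), not its physics: real arbitrary-unit
scales are instrument-specific, real clouds are skewed and correlated with
size, debris is not uniform, and cloud separations vary with expression
level and larval condition.  Filter and clustering accuracies measured here
are therefore statements about well-specified mixtures, upper bounds on
what identically-configured analysis achieves on real tables.

## Numerical conventions

* Probability distributions validate to 1 within 1e-9 and store only
  positive-mass outcomes; enumeration tests compare at 1e-12.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  simulating function takes an explicit seed and identical inputs give
  bit-identical outputs.
* Genotypes serialize in bracket notation (`m[GFP]/M`), common allele
  first.
* Test problem sizes (cohorts of 2e4–1e5, 200-replicate pilot simulations,
  1,000-replicate coverage experiments) were chosen so the full suite runs
  in well under a minute while keeping Monte-Carlo assertions at ≥3-SD
  separation from their thresholds.
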