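# Methods

## Background and scope

During zebrafish somitogenesis, the paired clock genes *her1* and *her7*
oscillate in presomitic-mesoderm (PSM) cells with a period of about 30
minutes, driven by a cell-autonomous negative feedback loop in which Her1
and Her7 proteins repress their own transcription.  Because the oscillation
period slows from posterior to anterior, all cells in a single-cell-wide
posterior–anterior slice share the same oscillation phase, and 2–3
kinematic waves of expression are visible across the tissue at any moment.
`clockvar` quantifies the cell-to-cell variability of *her1*/*her7*
transcript counts in such phase-grouped populations, compares genotypes at
matched expression levels, and provides a stochastic bursty-transcription
model of the clock for interpreting gene-dosage effects.

## Variability decomposition

For paired per-cell counts `x` (*her1*) and `y` (*her7*) within one slice,
with angle brackets denoting plain population averages (1/n moments,
consistently — never 1/(n−1)):

* uncorrelated variability: `½⟨(x/⟨x⟩ − y/⟨y⟩)²⟩`
* correlated variability: `(⟨xy⟩ − ⟨x⟩⟨y⟩)/(⟨x⟩⟨y⟩)`
* total variability: their sum, algebraically equal to `½(CV²x + CV²y)`.

This is the dual-reporter decomposition: the correlated part captures
factors shared by both genes in a cell (cell volume, shared upstream
state, co-fired bursts — extrinsic-like), the uncorrelated part captures
gene-independent fluctuations (counting/bursting noise — intrinsic-like).
Correlated values may be negative and are reported as-is; the estimator is
centred on zero for independent genes and flooring would bias genotype
comparisons.  Both statistics are invariant under separate rescaling of
`x`, `y`, so volume units and detection efficiency cancel.

The per-slice estimators carry an O(1/n) small-sample bias (the covariance
term scales by (1−1/n)); with the default minimum of 5 cells per slice this
is at most ~20 % for the smallest admitted slices and < 10 % at typical
slice sizes.  Because genotypes are compared with the same slice-size
distribution, the bias largely cancels in comparisons.

Volume correction divides both counts by the cell volume (µm³) before the
statistics are computed.  It removes exactly the component of correlated
variability that is proportional to volume; uncorrelated variability is
unchanged up to a factor `E[1/V]·E[V]` that is ≈1 for realistic volume
spreads (≈6 % at a lognormal log-SD of 0.25).

## Slice pipeline and binning

One variability point is computed per (embryo, half, slice) group with at
least `min_cells` (default 5, configurable) cells; smaller groups and
groups with zero mean expression are dropped and reported.  Left and right
PSM halves are independent slice series.  All slices of a genotype are
pooled (each slice is one observation); per-embryo stratification is
available by filtering the table.  Points are sorted by mean her1+her7
expression (stable sort; ties keep input order) and split into 5
equal-count quantile bins; each bin reports the mean of its members and
the standard error of each component (population SD/√n; error bars of
2 SE are applied at presentation).  Equal-count bins keep per-bin standard
errors comparable; the bin count 5 is the convention of the field's
variability-versus-mean plots.

## Genotype comparison

Variability depends strongly on mean expression, so genotypes are compared
at matched levels: the area under the binned variability curve (AUC,
trapezoid rule — with only 5 bins, higher-order rules are unwarranted) is
integrated over the *overlap* of the two curves' mean-expression ranges,
with linear truncation at the overlap endpoints.  Each of 100 bootstrap
resamples redraws the slice-level points of each genotype with replacement
(the slice is the resampling unit — cells within a slice are not
resampled), rebins, and records the AUC pair.  Resample `r` of both
genotypes uses identically seeded RNG substreams advanced in lockstep, so
pairing by resample index is exact and self-comparison yields identically
zero differences.  A resample whose curve collapses (degenerate x-range or
empty overlap) is redrawn within its own substream, leaving all other
resamples untouched.

Significance is reported two ways:

* `p_value`: paired t-test across the 100 AUC pairs.  This is the
  procedure used in the smFISH literature this package accompanies, and it
  is reproduced faithfully — but note that it is anticonservative by
  construction: its denominator divides the bootstrap SD (an estimate of
  the sampling SD of the AUC itself) by √100, so under a true null
  |t| ≈ 10·|Z| and essentially any comparison is "significant".  In null
  simulations it rejects ~84 % of the time at α = 0.05.
* `p_value_bootstrap`: the two-sided percentile p-value of the
  bootstrapped AUC difference, `2·min(P(d≤0), P(d≥0))`.  This variant is
  calibrated (null rejection ~2.5–4 % at α = 0.05 in the same simulations)
  and is the recommended measure.

Percent differences are likewise reported both from the bootstrap means
(`mean_percent_difference`) and from the full-data curves over their
overlap (`percent_difference_full`).

Supporting tests: two-sample Kolmogorov–Smirnov on per-cell total her
counts for distribution shifts, and Shapiro–Wilk (3 ≤ n ≤ 5000) as an
advisory normality check that never gates the t-test.

## Stochastic clock model

The simulator implements a delayed negative-feedback oscillator with
correlated transcriptional bursting, evolved with the exact (direct-method)
Gillespie algorithm — no tau-leaping, so small-count noise is faithful.

Reactions: *her1*-only and *her7*-only bursts fire at `km(1−α)` each and
joint bursts at `km·α`, so each gene's total burst initiation rate is `km`
for any co-firing fraction α.  The Her1:Her7 heterodimer p17 represses the
mean burst size (not the frequency) as `⟨B⟩ = Bmax/(1+(p17/pdcrit)²)`;
burst sizes are geometric on {1,2,…} with success `1/⟨B⟩` when `⟨B⟩ ≥ 1`
and Bernoulli(⟨B⟩) on {0,1} below one molecule (a continuous-mean
extension; the geometric rule is only defined for means ≥ 1).  Joint
bursts draw the two genes' sizes independently from the current ⟨B⟩; a
`shared_burst_size` switch forces a single shared draw for sensitivity
analysis.  Transcriptional and translational delays are Erlang chains of
`n_delay = 10` sequential steps at per-step rate `n_delay/τ` (mean τ,
variance τ²/n).  Repression reads the current p17 at burst initiation
(no delayed read-back).  Translation reads mature mRNA.  Mature species
degrade first-order; chain intermediates are not degraded by default
(`degrade_intermediates` switches this on).  Dimerisation `kb·p1·p7` and
dissociation `ku·p17` conserve Her protein (dissociation restores both
monomers).

Recording: after a burn-in `T0` (default 300 min ≈ 10 periods) the full
state is stored every `dt_obs` (default 2 min, well below the period) up
to `Tmax`.  A population is `n_cells` trajectories from the same initial
condition on independent `SeedSequence` substreams; per time point,
correlated/uncorrelated variability is computed across cells, and time
points are binned (5 quantile bins) by population-mean total mRNA.

### Default parameters

Detailed kinetic parameters of the zebrafish clock are not individually
measured; the defaults below were chosen to honour the quantities that are
established — clock period ≈ 30 min, mRNA/protein half-lives of 3–5 min,
population-mean total mRNA ≈ 49 molecules — calibrated once and frozen.

| parameter | default | meaning |
|---|---|---|
| km | 1.0 min⁻¹ | total burst frequency per gene |
| α | 0.85 | co-firing fraction (high, consistent with the dominant correlated variability) |
| Bmax | 12 | maximum mean burst size (molecules) |
| pdcrit | 250 | heterodimer count at half repression |
| n_delay | 10 | Erlang chain length |
| τm, τp | 6, 2 min | transcriptional / translational delay |
| kp1 = kp7 | 4.5 min⁻¹ | translation rate per mRNA |
| γ (all) | ln2/3 min⁻¹ | 3-min half-life for mRNAs, proteins, dimer |
| kb, ku | 0.01, 1.0 | dimerisation / dissociation |
| T0, Tmax, dt_obs | 300, 900, 2 min | recording protocol |

With these defaults a single cell oscillates with an autocorrelation
period of 30–32 min at mean total mRNA ≈ 50.  The heterozygous
locus-deletion mutant is modelled by halving `Bmax` (the two homologous
alleles are assumed to fire together, so losing one chromosome halves the
burst size); everything else is unchanged.  Under that change the model
reduces correlated variability by ~35 % while uncorrelated variability is
nearly unchanged — the gene-dosage ordering observed experimentally.

### Closed-form checks

With repression off (`pdcrit → ∞`) and translation off, mature mRNA is a
compound-Poisson (geometric-batch) birth–death process: mean `km·Bmax/γ`,
and Fano factor equal to the mean burst size.  The Fano identity holds
without delay dispersion; with an Erlang chain in place, same-burst
molecules reach maturity at jittered times and the Fano factor falls below
⟨B⟩ whenever the jitter is comparable to the mRNA lifetime.  The test
suite therefore verifies the mean with the default chain but the Fano
factor with `τm = 0` (bursts delivered directly to the mature pool), the
regime in which the closed form is the valid oracle.

## Synthetic smFISH generator

The generator produces cell tables with closed-form ground truth rather
than mechanistic dynamics (the simulator provides those).  Per cell in
slice *s*: volume `V` is lognormal with mean 600 µm³ and log-SD `σV`; a
shared extrinsic factor `E` is lognormal with mean 1 and log-SD `σE`, a
fraction `volume_coupling` of its log-variance contributed by the same
Gaussian that drives `log V`; counts are `Poisson(μ_gene(s)·E)`,
conditionally independent between genes.  The slice means follow the
kinematic-wave profile `μ·(0.55 + 0.45·cos(2π·wave_count·φ))` with a
monotone posterior→anterior phase map φ offset by half a wave so that all
`wave_count` peaks lie inside the tissue.

Expected statistics per slice: correlated `= e^{σE²}−1`; uncorrelated
`= ½(1/μ1(s)+1/μ7(s))`; after volume correction, correlated
`= e^{(c−σV)²+d²}−1` with `c² = volume_coupling·σE²`,
`d² = (1−volume_coupling)·σE²` — the volume-linked share cancels exactly
when `σV = √volume_coupling·σE`, which the defaults satisfy.

Defaults emulate the study conditions: 6 embryos × 2 halves × 25 slices ×
12 cells; `μ1 = μ7 = 45` so the across-slice mean of total her is ≈ 49
molecules; `σE = 0.45` so correlated variability ≈ 0.22 and carries ≈ 75 %
of the total; `volume_coupling = 0.36` (σV = 0.27) so volume correction
filters ≈ 37 % of the correlated component; 3 kinematic waves.

`make_genotype_pair` regenerates a second table with controlled effects:
`correlated_scale` adjusts `σE²` through `ln(1+s·(e^{σE²}−1))`;
`level_scale` and `uncorrelated_scale` both necessarily act on μ (counting
noise is 1/μ), composing as `μ′ = μ·level_scale/uncorrelated_scale`.  Two
consequences worth keeping in mind when interpreting pipeline output on
generated pairs: an isolated level change implies an opposite uncorrelated
change at fixed slice, and — because every pure-Poisson genotype lies on
the same uncorrelated-versus-mean curve — uncorrelated AUC differences at
matched expression levels are ≈ 0 by construction.  Real data contain
bursting contributions to uncorrelated noise that this generator
deliberately omits, so passing recovery tests demonstrate correctness of
the estimators and comparison machinery, not that real uncorrelated
variability is Poisson.

## Numerical and engineering choices

* Population moments everywhere; SEs use population SD/√n.
* Quantile bins by stable sort; `np.array_split` semantics give bin sizes
  differing by at most one.
* Geometric burst sampling in the compiled kernel uses the inverse-CDF
  form `1 + ⌊log u / log(1−s)⌋` with a guard at `u = 0`.
* The Gillespie kernel is numba-compiled (first call compiles, ~5 s); a
  pure-Python `gillespie_step` mirror exists for single-step semantics,
  unit tests, and the delay-chain tracer.
* All randomness flows through explicit seeds (`numpy.random.SeedSequence`
  substreams per embryo, per cell, per bootstrap resample); every result
  object records its seed.
* Degenerate inputs raise typed errors (`SchemaError`, `ValidationError`
  with row numbers, `EmptyInputError`, `DegenerateStatisticError`) rather
  than propagating NaNs; a zero-variance bootstrap comparison reports
  p = 1 with a warning.

## Problem sizes

Default analyses run on 3 600-cell tables (300 slice points).  The test
suite uses 200 null replicates for calibration checks, 10–12 replicates of
10⁴-cell slices for closed-form recovery, and populations of 32–100 cells
over 200–600 min of simulated time for the mechanistic checks; these sizes
keep Monte-Carlo standard errors small relative to the effects asserted
(3 SE criteria throughout).

## Known limitations

* No spatial coupling between cells (Delta–Notch) and no explicit
  two-allele bookkeeping; the deletion mutant is a burst-size surrogate.
* No parameter fitting to data; simulator defaults are a calibrated
  reference set, not estimates with uncertainties.
* Gene-specific CV² curves (her1-only/her7-only) are out of scope.
* The per-slice estimators are biased at very small slices (see above);
  slices below the cell threshold are excluded rather than corrected.
* The paired t-test on bootstrap AUC pairs is reported for fidelity to the
  published procedure but should not be interpreted as a calibrated test;
  use `p_value_bootstrap`.
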