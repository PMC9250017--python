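# clockvar

Transcriptional variability analysis and stochastic modelling of the
zebrafish segmentation clock genes *her1* and *her7*.

## The problem

During somitogenesis, *her1* and *her7* oscillate in presomitic-mesoderm
(PSM) cells every ~30 minutes, driven by a negative feedback loop in which
the Her1:Her7 heterodimer represses both genes.  Single-molecule FISH gives
absolute per-cell transcript counts, and because all cells in a
single-cell-wide posterior–anterior slice share the same oscillation
phase, cell-to-cell variability can be measured within such phase-grouped
populations without confounding by the oscillation itself.

`clockvar` is for researchers analysing this kind of paired two-gene
count data.  It provides:

* the dual-reporter **variability decomposition** per slice — uncorrelated
  `½⟨(x/⟨x⟩ − y/⟨y⟩)²⟩`, correlated `(⟨xy⟩−⟨x⟩⟨y⟩)/(⟨x⟩⟨y⟩)`, and total
  `= ½(CV²x + CV²y)` — with optional cell-volume normalisation and 5-bin
  variability-versus-mean curves;
* **genotype comparison** at matched expression levels: 100× bootstrap of
  slice points, area under the variability curve over the overlapping
  expression range, paired t-test (the published procedure) plus a
  calibrated percentile-bootstrap p-value, KS and Shapiro–Wilk checks;
* a **stochastic clock model**: delayed negative-feedback oscillator with
  correlated transcriptional bursting (co-firing fraction α, geometric
  burst sizes repressed via a Hill function of heterodimer count, Erlang
  delay chains), simulated exactly with the Gillespie algorithm;
* a **synthetic smFISH generator** (Poisson-lognormal mixture with
  kinematic-wave spatial profiles and lognormal volumes) whose expected
  statistics are known in closed form, so the whole pipeline is testable
  end-to-end without any data download.

See `docs/methods.md` for the model definitions, parameter defaults and
their rationale.

## Worked example

```python
from clockvar import (SynthConfig, make_genotype_pair, VariabilityModel,
                      GenotypeComparison)

# wild type plus a locus-deletion heterozygote: one chromosome copy lost,
# -38% expression, correlated variability scaled to 69%
(wt, _), (mut, _) = make_genotype_pair(
    SynthConfig(seed=0), level_scale=0.62, correlated_scale=0.69,
    genotype_b="b567_het",
)

res_wt = VariabilityModel(wt, volume_correct=True).fit()
print(res_wt.summary())

comp = GenotypeComparison(res_wt,
                          VariabilityModel(mut, volume_correct=True).fit()
                          ).fit(component="correlated", seed=42)
print(comp.summary())
```

prints

```
Transcriptional variability decomposition
=========================================================
genotype:            wt
volume corrected:    True
slices retained:     300  (dropped 0)
cells:               3600
correlated share:    65.5%
uncorrelated share:  34.5%

bin   mean her     corr    (2SE)   uncorr    (2SE)    n
  0       0.02   0.1252   0.0258   0.1674   0.0219   60
  1       0.04   0.1206   0.0181   0.0728   0.0075   60
  2       0.08   0.1065   0.0173   0.0394   0.0046   60
  3       0.12   0.1328   0.0138   0.0264   0.0039   60
  4       0.15   0.1359   0.0192   0.0213   0.0026   60

Bootstrap AUC comparison (correlated variability)
=======================================================
b567_het vs wt, 100 resamples, seed 42
full-data AUC:        0.0086 -> 0.0066  (-22.8%)
bootstrap mean AUC:   0.0086 -> 0.0066  (-22.7%)
paired t-test:        t = -40.317, p = 3.05e-63
percentile bootstrap: p = 0
```

Reading the output: with volume correction on, mean expression is in
molecules/µm³, so the bin means are small; correlated variability (~0.12)
dominates uncorrelated except at the lowest expression bin, where Poisson
counting noise (~1/mean) takes over.  The comparison integrates each
genotype's correlated curve over the shared expression range: the mutant's
correlated variability AUC is ~23 % lower in this draw (the generator's
ground truth is −31 %; a single 300-slice dataset recovers it to within
sampling error).  The paired t-test p-value reproduces the published
procedure; `p_value_bootstrap` is the calibrated alternative (0 here means
below the 1/100 resampling resolution).

The same objects drive plots (`res_wt.plot()`), per-slice points
(`res_wt.points`), spatial profiles (`clockvar.mean_spatial_profile`), and
the simulator:

```python
from clockvar import SimParams, simulate_population, sim_variability_curve
snaps = simulate_population(SimParams(), n_cells=100, seed=1)
print(sim_variability_curve(snaps).to_frame())
```

A thin CLI wraps the same library calls:

```bash
clockvar synth --seed 1 --out cells.csv
clockvar analyze cells.csv --volume-correct --out curves.json
clockvar compare cells_a.csv cells_b.csv --resamples 100 --seed 3 --out cmp.json
clockvar simulate --cells 100 --seed 4 --mutant deletion --out sim.json
```

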