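# protflux

Quantitative analysis of proteostasis impairment by arginine-rich
dipeptide-repeat (DPR) peptides — the (PR)20 / (GR)20 products of RAN
translation from the *C9ORF72* repeat expansion — in primary neuron
culture assays. The package is aimed at cell biologists and imaging/
biostatistics analysts who run these assays and want a tested, scriptable
pipeline instead of one-off spreadsheet and MATLAB fragments.

It covers four assay classes, each with a synthetic-data generator whose
ground truth makes the whole pipeline testable without any raw data:

1. **Optical pulse labeling (OPL).** A Dendra2 fusion is photoconverted at
   t = 0; the red signal of each neuron is segmented, tracked and fitted
   with first-order decay `I(t) = I0·e^(−kt)`, giving a per-cell half-life
   `t½ = ln2/k`. Treatment effects are read from the half-life
   distribution with the two-sample Kolmogorov–Smirnov test.
2. **±MG132 ubiquitin flux assay.** The statistic
   `T = mean(treated,+MG)/mean(treated,−MG) − mean(control,+MG)/mean(control,−MG)`
   is tested with a restricted permutation test (50,000 iterations) that
   exchanges lanes between arms only within the same MG132 stratum, with
   an exhaustive-enumeration oracle for validation.
3. **Dose–response.** Survival counts are fitted with the four-parameter
   logistic `y = bottom + (top−bottom)/(1+(x/LD50)^hill)`; LD50 intervals
   come from a within-concentration case-resampling bootstrap (expanded
   percentile).
4. **In vitro Ub-Sic1 degradation.** Drop statistics Δ⁰⁻⁵, Δ⁰⁻¹⁵ with
   one-way ANOVA and Holm-adjusted contrasts versus the uninhibited group.

Plus peptide calculators: average mass and Bjellqvist-pKa isoelectric
point (the HA-tagged (PR)20 and (GR)20 constructs come out at 6.1 and
5.3 kDa with identical pI 12.37).

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Simulate a flux experiment with a true reduction of the +MG/−MG ratio by
1.2 (six lanes per group, 20% densitometry noise) and test it:

```python
import protflux as pf

recs = pf.gen_flux_table(pf.FluxSimParams(
    n_per_group=6, flux_fold=3.0, effect_delta=-1.2, noise_cv=0.2, seed=7))
design = pf.normalize_lanes(recs)
res = pf.restricted_permutation_test(design, B=50_000, seed=11)
print(res.summary())
```

```
Restricted permutation flux test
========================================
T observed  : -1.06206
p (two-sided, magnitude) : 0.0102
iterations  : 50000  mode: full_relabel  seed: 11
group means : treated_plus=1.791, treated_minus=0.9013, control_plus=2.782, control_minus=0.9123
group sizes : treated_plus=6, treated_minus=6, control_plus=6, control_minus=6
```

The observed difference of ratios (−1.06) estimates the planted −1.2;
about 1% of within-stratum relabelings produce a statistic of that
magnitude, so the flux reduction is detected at p ≈ 0.01.

Fit an LD50 from simulated survival counts (true LD50 2 µM, coarse
10-fold grid, 3 coverslips × 3 fields per dose):

```python
fit = pf.FourParamLogistic.from_records(
    pf.gen_dose_response(pf.DoseSimParams(seed=42))).fit()
fit.bootstrap_ld50(n_boot=300, seed=43)
print(fit.summary())
```

```
Four-parameter logistic dose-response fit
================================================
top      : 30 (se 0.916)
bottom   : 7.351e-20 (se 2.55)
LD50     : 1.955e-06 (log10 se 0.13)
hill     : 0.9765 (se 0.3)
R^2      : 0.9655   converged: True
LD50 95% CI : [1.195e-06, 2.846e-06]
per-dose means: 0->31.7, 2e-09->28.2, 2e-08->30, 2e-07->26.7, 2e-06->15.1, 2e-05->2.33, 3.5e-05->1.78
```

The LD50 estimate (1.96 µM) recovers the planted 2 µM and the bootstrap
interval comfortably covers it.

A CLI mirrors the library (`protflux simulate-opl`, `fit-halflife`,
`compare-halflife`, `flux-test`, `fit-ld50`, `degradation`,
`peptide-calc`), with `--config`, `--seed`, `--out-dir` and `--log-level`
global flags; every run logs its resolved configuration and seed so
stochastic outputs replay exactly.

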