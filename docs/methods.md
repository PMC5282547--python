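# Methods

`protflux` implements the quantitative core of a dipeptide-repeat (DPR)
proteostasis study: how arginine-rich peptides such as (PR)20, produced by
RAN translation from the *C9ORF72* hexanucleotide repeat expansion, impair
degradation through the ubiquitin–proteasome system and autophagy in
primary spinal-neuron cultures. The raw data of such a study — time-lapse
microscopy, western blots, survival counts — are emulated by synthetic
generators with known ground truth, so every stage of the analysis can be
validated end to end.

## Optical pulse labeling and per-cell decay

A photoconvertible Dendra2 fusion (e.g. Dendra2–LC3 for autophagic flux) is
photoconverted at t = 0 and the red (TRITC-filter) signal of each neuron is
followed over 12 h at 2-h intervals. The model for one cell is first-order
decay,

    I(t) = I0 · exp(−k t),        t½ = ln 2 / k,

with no additive plateau: the frame background (median intensity outside
all segmented ROIs) is subtracted before fitting, and a free plateau is not
identifiable from seven timepoints. `ExponentialDecay.fit()` runs nonlinear
least squares initialised from the log-linear regression of log(max(I, ε))
on t; standard errors come from the curvature of the objective, and the
half-life SE uses the delta method.

Segmentation uses the green (unconverted) channel only — Otsu threshold,
connected components, area ∈ [20, 2000] px and eccentricity ≤ 0.95 — so
that detection does not favour slow-degrading cells. Tracking is greedy
nearest-centroid matching with a 15-px displacement cap; neurons move very
little between 2-h frames, and ties break deterministically (smallest
distance, then lowest cell id). QC for population statistics requires ≥ 5
of 7 timepoints, convergence, k > 0 with non-negligible decline over the
observed span, and R² ≥ 0.5; all thresholds live in `RunConfig`. Excluded
cells are retained with reason codes for audit.

Population comparisons use the two-sample Kolmogorov–Smirnov test on
half-lives in hours (scipy's exact/asymptotic auto rule). KS p-values are
invariant to monotone transforms, so the hour scale only affects the
additive effect summaries (mean/median shifts), which is how such effects
are naturally reported.

## Restricted permutation test for proteasomal flux

The flux assay measures total ubiquitin with and without a 4-h proteasome
block (MG132), in control and treated arms. After normalizing each lane to
its loading control (and optionally rescaling each blot by its control
−MG132 mean to cancel exposure differences), the statistic is

    T = mean(treated,+MG)/mean(treated,−MG) − mean(control,+MG)/mean(control,−MG).

The null permutes values between arms only *within* each MG132 stratum:
crossing the stratum boundary would detect the (uninteresting, guaranteed)
effect of the blocker itself. The default scheme redraws the arm partition
uniformly within each stratum per iteration (`full_relabel`), which samples
the exchangeable null directly; a single-swap scheme (`transposition`) is
retained for comparison because a one-transposition chain does not sample
that null uniformly in one step. The p-value is the plain proportion of
the 50,000 permuted statistics at least as large in magnitude as the
observed one; ties count toward the null (a strict-inequality variant and a
(b+1)/(B+1) correction are available). `exhaustive_null` enumerates all
allowed relabelings exactly and is the oracle the Monte-Carlo test is
validated against. Type-I calibration at the study design (6 lanes/group,
20% lognormal noise) is checked by simulation; the simulation uses 2,000
permutations per design, which resolves p at the 5e-4 level — ample for a
rejection decision at α = 0.05 — while keeping 1,000 replications quick.

## Dose–response and LD50

Motor-neuron survival (or XTT viability) versus concentration is fitted
with the four-parameter logistic

    y(x) = bottom + (top − bottom) / (1 + (x/ld50)^hill),

by least squares with an analytic Jacobian; `bottom ≥ 0`, the Hill slope is
unconstrained in sign, and vehicle (x = 0) observations inform the top
asymptote only, since zero has no place on a log-concentration axis. Data
with less than a 20% decline across the tested range raise
`NotIdentifiableError` rather than returning a meaningless extrapolated
LD50 (the expected outcome for a non-toxic peptide such as (GR)20).

For count responses the model accepts `variance="poisson"`, which
iteratively reweights the fit by the reciprocal predicted response — the
Poisson mean–variance relation. This matters: on simulated counts the
unweighted fit shows a small but systematic downward bias in log10(LD50)
(≈ −0.02, i.e. −4%), which the weighting roughly halves without changing
the noiseless solution (weights are irrelevant where residuals vanish).

Confidence intervals for the LD50 come from a bootstrap in which all
resamples are refitted simultaneously by a batched Levenberg–Marquardt
solver (rows = resamples), with occasional non-converged rows polished by
the scalar optimizer; a 500-resample interval costs tens of milliseconds.
Two resampling schemes are provided:

* **Case resampling within concentration** (generic responses): with only
  three coverslips per dose, the plain percentile interval is
  systematically narrow (each stratum's resampling variance underestimates
  the sampling variance by (n−1)/n; measured ~88% coverage for a nominal
  95%), so quantile deviations from the point estimate are widened by
  √(n/(n−1)) on the log10(LD50) scale (the expanded percentile interval;
  `expand=False` recovers the plain one).
* **Parametric Poisson bootstrap** (default for Poisson-variance models):
  responses are redrawn from the fitted curve as
  `y* = Poisson(count_scale·µ̂)/count_scale`, with `count_scale` the
  number of raw field counts behind each recorded average. This sidesteps
  the three-cases-per-dose limitation entirely; simulated coverage at the
  study design was ~94% (two independent 300-simulation batches: 92.7%
  and 95.0%), against ~92% for the expanded case-resampling interval.

The recommended experimental procedure mirrors the two-stage design:
screen on an approximately 10-fold grid (2 nM–35 µM), then add a
quarter-log grid centred on the coarse estimate and fit all data pooled.

## In vitro degradation statistics

Ub-Sic1 (a polyubiquitylated model substrate) is presented to purified
proteasomes pre-incubated with peptide at molar ratios 1:0, 1:10, 1:100
(proteasome:peptide), and the loading-normalized substrate band is read at
0, 5 and 15 min. Inhibition is summarised per replicate by the drops
Δ⁰⁻⁵ = s(0) − s(5) and Δ⁰⁻¹⁵ = s(0) − s(15), compared across conditions
with one-way ANOVA; pairwise contrasts against the uninhibited group use
two-sided t tests with Holm adjustment (a standard choice where no
particular post hoc method is dictated). Deltas rather than fitted rate
constants are used because three timepoints per replicate support a
contrast, not a kinetic fit.

## Peptide properties

Average mass is the sum of standard average residue masses plus one water
(18.015 Da); reported kDa values are truncated (not rounded) at one
decimal, the only convention under which the computed masses of the
HA-tagged constructs (6.168 and 5.367 kDa) reproduce the conventional
one-decimal figures (6.1 and 5.3). The isoelectric point solves
net-charge(pH) = 0 by bisection at 1e-3 pH tolerance, with
Henderson–Hasselbalch charges over D, E, C, Y, H, K, R and both termini
using the Bjellqvist pKa set (residue-specific terminal variants included);
the charge function is strictly decreasing in pH, so the root is unique,
and the model is composition-only, so any permutation of the sequence has
the same pI. The HA-tagged constructs are modelled as the dipeptide repeat
followed directly by the C-terminal YPYDVPDYA epitope with no linker; the
sequence is an argument, not a hard-coded constant. (PR)20 and (GR)20 share
the same ionizable composition (20 Arg, 2 Asp, 3 Tyr + termini), hence
identical pI (12.37) despite different masses.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume:

* **OPL stacks** — cells as 2-D Gaussian blobs placed without overlap,
  per-cell half-lives lognormal (default median 20 h, σ_log 0.35, matching
  a wide half-life distribution peaking near 20 h), initial red intensities
  lognormal, constant green channel, Gaussian read noise, optional linear
  drift. Photobleaching is *not* simulated by default — red loss is
  interpreted as degradation, matching the assay's reading — but an
  optional `bleach_rate_per_h` adds an explicit `exp(−bt)` factor to the
  red traces so the confound can be studied; the truth table always
  records the degradation half-life only.
* **Flux tables** — four groups with multiplicative lognormal noise; the
  treated +MG132 mean encodes the flux change so that the true
  difference-of-ratios equals `effect_delta` exactly.
* **Survival counts** — expected counts on a 4PL curve; each coverslip
  records the average of three Poisson field counts, mirroring counting in
  three nonoverlapping fields with per-coverslip averaging.
* **Degradation courses** — first-order loss exp(−rate·factor·t) with
  lognormal band noise; default rate 0.15/min gives near-complete
  uninhibited loss by 15 min, with inhibition factors 1.0/0.5/0.3.

Not emulated: realistic optics (PSF, shot noise statistics per photon),
cell death or division during the 12-h window, neurite signal, blot
saturation and background smears, and plate-position effects. Passing
tests therefore demonstrate correctness of the *computations* under the
assumed error structure, not robustness to every artefact of real
microscopy or densitometry.

## Problem sizes and numerics

Validation runs use sizes chosen to make the checks sharp yet quick: 300
cells per condition on 1200×1200 fields for the end-to-end imaging check
(the planted-shift recovery is compared against the ground-truth table's
realized medians, since at n = 300 the sample median of the lognormal
carries ~0.45 h of irreducible sampling error per group); 1,000 simulated
designs for permutation-test calibration; 500 two-stage simulations with
500-resample bootstraps for LD50 coverage; 20 random small designs against
the exhaustive permutation oracle. Tie counting in permutation p-values
uses a 1e-12 relative tolerance so exact ties are not lost to
non-associative float summation. Decay fits clamp nonpositive
intensities at ε = 1e-12 only inside the logarithm of the initialisation,
never in the objective.

## Known limitations

* Greedy nearest-centroid tracking has no motion model; it is adequate for
  nearly static somata but would swap identities under large drift or
  high density.
* The 4PL fit treats replicates as independent; overdispersion beyond
  Poisson field counting is not modelled.
* The permutation test assumes exchangeability of lanes within a stratum
  across arms; systematic blot-batch effects must be removed first (the
  `batch_rescale` option) or the null is misspecified.
* pI values depend on the pKa set; the Bjellqvist table is the default and
  others can be added, but no claim is made that any set reproduces
  measured titration curves for arginine-rich repeats.
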