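# Methods

## Model and assumptions

The pipeline treats a ceRNA triplet (lncRNA *x*, miRNA *z*, mRNA *y*) as a
linear-Gaussian unit: the coupling of interest is the first-order partial
correlation ρ(x, y | z), i.e. the Pearson correlation of x and y after
removing the linear effect of the shared miRNA.  This assumes approximately
linear relations on the analysis scale and no unmodeled confounder beyond z.
Expression values are analyzed after a log2(v + 1) transform by default
(`log2p1=False` to disable): Pearson correlation on raw RNA-seq magnitudes is
dominated by a handful of highly expressed outliers, while the log scale is
close to the scale on which linear co-regulation is usually assumed.

A single sample carries no correlation information on its own.  The
patient-specific quantity is therefore a *leave-one-in* perturbation: with n
normal samples fixed as the reference, each tumor sample is appended
individually and every triplet's partial correlation is recomputed on the
n + 1 points.  The per-patient edge weight is Δρ = |ρₙ₊₁ − ρₙ|.  A single
appended point moves a correlation by O(1/n), so Δρ values are small; what
identifies a perturbed triplet is not the magnitude of one Δρ but the
recurrence of the perturbation across tumor samples, assessed in the
selection step.

## Selection: edge filter, then Z-test

Per tumor sample, an edge survives if |ρₙ₊₁| > 0.7 **and** its two-sided
p-value is below 0.05.  The p-value uses the standard first-order
partial-correlation test, t = ρ·√((n−3)/(1−ρ²)) on n − 3 degrees of freedom
(one conditioning variable); ρ = ±1 maps to p = 0.  The filter is applied to
the perturbed correlation ρₙ₊₁ only; `filter_reference=True` additionally
requires the reference ρₙ to pass.

Triplets then enter a one-sample Z-test: over the m tumor samples that passed
the edge filter, z = mean(Δρ) / (sd(Δρ)/√m), two-sided normal reference,
α = 0.05, with m ≥ `min_samples` (default 3) required.  Samples failing the
edge filter are *excluded* from the mean rather than contributing Δρ = 0;
`use_edge_filter=False` pools all tumor samples instead.  A zero standard
deviation with positive mean yields an infinite z — the triplet is kept and
flagged `degenerate-sd`.

**Caveat (important).** Δρ is an absolute value, so it is nonnegative and its
mean is positive for any triplet with any sampling noise at all; the Z-test
against zero is therefore not a calibrated null-hypothesis test — with enough
samples it rejects for every triplet (mean/sd of a folded distribution is
bounded away from 0).  In this procedure, specificity comes from the edge
filter and the minimum-passing-samples rule: background triplets essentially
never reach |ρ| > 0.7, so they never accumulate the m ≥ 3 passing samples
needed to enter the Z-test.  The measured operating characteristics under the
package's standard synthetic conditions (see `scripts/acceptance.py`) are a
null selection rate near 0 and sensitivity near 1 for planted perturbations.
Because Δρ ≥ 0 makes the two-sided test effectively one-sided, a one-sided
variant is exposed (`one_sided=True`).

## Survival screening

Each RNA of a selected triplet is dichotomized at its **median over the tumor
samples**; values strictly above the median are "high", values at or below are
"low" (a deterministic tie rule; the median is used instead of the mean so
that outliers cannot produce grossly unbalanced arms).  Patients split on the
lncRNA/mRNA pair only: **Group 1** = opposite levels, **Group 2** = same
levels; the miRNA level is carried in the labeling but does not affect
grouping (it shows no survival signal in this design).  Within each group the
two sub-patterns (e.g. lnc-high/mRNA-low vs lnc-low/mRNA-high) form the binary
covariate of a univariate Cox proportional-hazards fit — this is the package's
interpretation of "one Cox p-value per triplet per group", chosen because it
matches the two survival curves reported per group; an alternative coarse
screen using the full 8-level pattern as a categorical covariate with a
likelihood-ratio test is provided (`eight_level_screen`).

Cox fits use lifelines' `CoxPHFitter` with Efron tie handling and a tightened
Newton precision (1e-9) so the estimate matches a direct numeric maximization
of the partial likelihood to ~1e-8.  Triplets with p < 0.01 (raw Wald p, per
the screening design) in at least one group are reported as prognostic;
Benjamini–Hochberg q-values over all fits are attached for reporting and never
drive the screen.  Zero-event sets, single-arm covariates and non-converging
fits are recorded as per-triplet failures, never fatal.  Kaplan–Meier curves
and two-group log-rank tests accompany each dichotomy; without tied event
times the log-rank statistic equals the Cox score test at β = 0.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
RNA-seq count mechanics.  Each gene's log2 expression is Gaussian
(`baseline_log_mean` 8, `baseline_log_sd` 1.2, i.e. raw values around a few
hundred), with independent measurement noise of sd `noise_sd` = 0.1 on the
log scale.  A planted triplet follows a latent-Gaussian model: lncRNA and
mRNA each load on the shared miRNA with coupling `mirna_coupling` = 0.5, and
their residuals are correlated so the conditional correlation given the miRNA
is exactly ρ\* (default 0.9) on the latent scale; in tumor samples the
residual correlation is ρ\* + δ (default δ = −0.5).  Infeasible targets
(|ρ\*| ≥ 1 or |ρ\* + δ| ≥ 1) are rejected at configuration time.  Raw
expression is 2^(latent), so the pipeline's log2(v+1) transform recovers an
image of the latent scale that is affine up to the +1 offset — at these
baselines the distortion of partial correlations is well below estimation
error, and test tolerances (±0.1 on ρ at n = 50) absorb it.

Default study conditions: 50 normal and 50 tumor samples, 20 planted triplets,
480 decoy triplets built from 120 decoy miRNAs with 2 lncRNA and 2 mRNA
partners each (500 candidates total; decoy association pairs are 12× the
planted pairs — integer partner counts that land on a round candidate total).
Survival is exponential with baseline hazard 1/1000 per day; the tumor
samples showing the planted prognostic sub-pattern (Group 1, lncRNA high)
have hazard multiplied by e^β.  Censoring is independent uniform U(0, c) with
c solved numerically so the expected censoring fraction equals
`censoring_rate` (default 0.3) under the baseline hazard; the planted effect
makes the realized rate slightly different, which the replicate-based checks
absorb.

What the generator does **not** emulate: negative-binomial count
overdispersion, library-size differences, batch effects, gene–gene
correlation outside planted triplets, non-exponential hazards, and
informative censoring.  Passing tests therefore demonstrate correctness of
the estimators and the selection logic under the model's own assumptions, not
robustness to real RNA-seq artifacts.

## Numerical choices

- Correlations are clipped to [−1, 1]; variance and partial-correlation
  denominators below 1e-12 are treated as degenerate, excluding the affected
  triplet with a recorded reason instead of failing the run.
- The cohort engine keeps per-triplet raw sums over the normal samples and
  updates them with one tumor sample at a time, so a cohort of T triplets and
  S tumor samples costs O(T·S) with no re-scan of the normal matrix; results
  match per-triplet recomputation to ~1e-10.
- Missing expression values are rejected at load (impute upstream); the
  perturbation statistics have no missing-data semantics.
- Cohort iteration is in sorted sample-id order and every stochastic routine
  takes an explicit seed, so identical inputs and configuration give
  identical outputs (byte-identical for the generator).

## Problem sizes in the test suite and acceptance script

Replicate counts and cohort sizes were chosen to give stable statistics at
interactive runtimes: 1,000 random instances for the oracle-agreement check,
20 null-cohort replicates (500 triplet screens) for type-I rates, 3 default
cohorts for perturbation sensitivity, and 20 replicates of 500 patients for
hazard-ratio recovery.

## Known limitations

- The Z-test inherits the nonnegative-statistic issue described above; treat
  the selection as a filter pipeline, not as per-triplet inference with a
  controlled error rate.
- Univariate screening only: no covariate adjustment (age, stage), no
  multivariate or penalized Cox, no time-dependent effects.
- Identifier handling is string-based after one normalization pass (trim,
  lowercase the "mir" token; optional −5p/−3p collapsing, off by default
  because it changes triplet counts); Ensembl↔symbol mapping is delegated to
  a user-supplied two-column file.
- The reference network assumes the normal samples are homogeneous; a
  contaminated or tiny normal set (< ~20 samples) makes ρₙ noisy and inflates
  every patient's Δρ.
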