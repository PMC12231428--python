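# Methods

This note documents the models, the numerical choices and their rationale,
what the synthetic-data generator does and does not emulate, and the known
limitations. Nothing here reports an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Generative model of the synthetic cohort

**Phenotypes.** CTQ total scores are integers from a truncated normal on
[25, 61]. The published summary statistics of such cohorts (mean 34.7,
SD 7.8) describe the *bounded* score, so the generator solves the two
truncated-moment equations for the underlying normal's location and scale
rather than plugging the targets in directly — naive plug-in would inflate
the mean by ~1.6 points because the truncation is strongly asymmetric.
Integer rounding perturbs the moments by far less than one standard error at
the cohort sizes used.

**Ground-truth EC.** A stable random matrix: self-connections fixed at
−0.5 /s (the conventional prior decay rate of linear DCM, time constant
2 s), off-diagonal entries nonzero with probability 0.15 and Gaussian with
SD 0.2 /s, shrunk by 10% steps in the rare case the spectral abscissa is
non-negative. These defaults give weakly coupled, comfortably stable
dynamics; much stronger coupling pushes the system toward instability and
makes the discrete-time map `exp(A·TR)` visibly nonlinear in `A`.

**Score link.** For subject *s* with standardized score *z_s*, each of a
set of *effect edges* (all inside one network block, DMN by default) takes
`base + slope·z_s + jitter`; every other off-diagonal edge takes
`base + jitter` with jitter SD `edge_noise_sd`. At the ground-truth level
the per-edge weight-score correlation is `|slope|/sqrt(slope² + jitter²)`.
Defaults: 12 effect edges, slope ±0.06 /s per SD with alternating sign,
jitter 0.09 /s. The alternating sign matters: the feature selector keeps the
most *positively* and most *negatively* correlated features separately, so a
realistic planted signal should populate both tails. These values were
calibrated once, by simulation during design, to place the pipeline in the
weak-effect regime the method targets (estimated-EC edge-score correlations
around 0.25-0.3, DMN-family prediction r around 0.5 at 206 subjects); far
stronger effects are trivially detected by every family including
whole-brain, and far weaker ones by none.

**Forward BOLD model.** `dx/dt = A x + w` integrated by Euler at 0.1 s
(adequate against the 2 s sampling interval and eigenvalues of order
0.5 /s), with a 32 s burn-in that both settles the dynamics and fills the
HRF history. The latent signal is convolved with the canonical double-gamma
HRF (gamma-pdf peaks at 6 s and 16 s, undershoot ratio 1/6, identical across
regions — matching the estimator's shared-HRF assumption), sampled at
TR = 2 s, scaled to unit variance per region so that the measurement-noise
SD (default 0.3) directly sets the SNR (≈3.3), ideally band-pass filtered to
0.01-0.1 Hz by zeroing DFT bins (the rectangular filter typical of
resting-state preprocessing), and z-scored. Defaults: 230 volumes retained,
as in a 240-volume acquisition with 10 dummy volumes discarded.

What the generator does **not** emulate: head motion, physiological
confounds, scanner drift, spatially correlated noise, regionally varying
HRFs, nonlinear (bilinear) dynamics, and subcortical structures. Passing
tests therefore demonstrate the statistical machinery under the model's own
assumptions, not robustness to real-data artefacts.

## 2. EC estimation

**Per-region variational Bayes (`estimate_region`).** In the frequency
domain the linear DCM is one regression per target region: response = the
target spectrum times the discrete derivative operator
`(exp(2πi·m/N) − 1)/Δt`; design = all regions' spectra; the zero-frequency
bin is dropped. Real and imaginary parts stack into one real regression
(equivalent to an isotropic complex-Gaussian likelihood). Priors follow
linear-DCM convention: connection prior mean 0 (−0.5 /s on the
self-connection), prior variance 1, Gamma(2, 1) on the noise precision;
closed-form Gaussian and Gamma updates alternate until the posterior mean
moves less than 1e-6 (cap 500 iterations), and the convergence flag is
reported honestly. With fixed noise precision the update reduces exactly to
ridge regression with penalty `prior_precision / noise_precision` — the
oracle identity the tests check at 1e-8. With no exogenous inputs and a
shared HRF, the HRF spectrum multiplies response and design alike at each
frequency and cancels, so measured-signal spectra are regressed directly.

**Band-limited data need more than the textbook regression
(`estimate_ec_sessions`).** The full-spectrum frequency regression is a
unitary image of the time-domain autoregression, whose residual is
orthogonal to the design by the martingale property. Band-pass filtering
destroys this: on the retained bins the design contains the same innovation
that forms the residual, `x̂(ω) = (e^{iω}I − M)^{-1}ê(ω)` with
`M = exp(A·TR)`, so the naive regression is *biased*, not just noisier —
its many-session asymptote stalls well short of the truth. Three remedies,
applied in the pooled estimator:

1. **HRF whitening.** The residual is the innovation convolved with the
   HRF, hence heteroscedastic across frequency; each row is divided by the
   canonical HRF spectrum magnitude (floored at 1e-3 of its maximum,
   normalised to unit geometric mean).
2. **Endogeneity correction.** The design-residual cross-moment has the
   closed form `E[x̂ û^H] = TR · (e^{iω}I − M)^{-1} Σ_u` per bin, with `Σ_u`
   the residual covariance across regions (estimated from the current fit);
   the summed correction is subtracted from the normal equations and the
   solve repeated three times with 0.5 damping. Damping matters: the
   correction is itself estimated and undamped iteration amplifies its
   noise.
3. **Shrinkage.** A ridge penalty toward the prior mean at 0.2 times the
   mean diagonal of the pooled `XᵀX` — expressed relative to the design
   scale so it is invariant to session count and signal units.

Sessions pool at the sufficient-statistic level (their frequency rows
concatenate), which is how "averaging sessions" is implemented. The
correction hyperparameters (3 iterations, damping 0.5, shrinkage 0.2) were
fixed by parameter-recovery simulation during design and are exposed as
arguments.

**Interpretation caveat.** The frequency regression estimates the
discrete-time generator `(exp(A·TR) − I)/TR`, not `A` itself. For the
weakly coupled regimes generated here the two are proportional to first
order in the off-diagonal (factor `exp(−TR/2·|self|)` ≈ 0.37 at the
defaults), so correlation-based recovery metrics and between-subject
contrasts are unaffected; absolute rate units are compressed.

## 3. Prediction and inference

Feature selection keeps the `k = floor(fraction·P)` most positively and the
`k` most negatively correlated features (ties to the lower index; an error
is raised if `k = 0` or `2k ≥ P`). Standardization uses training-fold
statistics only; ridge (penalty 1.0) and LASSO (penalty 0.1) fits use
scikit-learn with the intercept unpenalised. Penalties are fixed rather
than tuned — the emulated design used a fixed model, and an inner tuning
loop would change what the permutation test calibrates. Fold partitions are
uniform random without stratification; fold r values are averaged within a
repeat, repeats use seeds fanned out from the master seed via
`SeedSequence(master, spawn_key=...)`, which also isolates every
(family, fraction, model) cell so results are independent of execution
order.

A property worth knowing: for a *fixed* dataset the null distribution of
the fold-averaged r is not centred at zero — selection inside the folds
tracks that sample's chance feature-score correlations, and repeated CV
reproduces them (spread roughly ±0.2 at n ≈ 120-200). Zero-centring holds
across independent datasets. This is precisely why significance comes from
the label-shuffled permutation test, which re-runs selection under the
null, and not from a parametric test on r.

The permutation test shuffles scores once per permutation and re-runs the
full cross-validated prediction (one CV loop per permutation by default; a
flag enables full repeated-CV nulls). The p-value uses the add-one
(never-zero) estimator `(1 + #{null ≥ observed})/(1 + n_perm)`, one-sided
as the claim is directional. Bonferroni across the eight families gives the
corrected threshold 0.05/8 = 0.00625.

## 4. Validation experiments and problem sizes

The experiments in `ecpredict.experiments` (shared by the test suite and
`scripts/acceptance.py`) use desk-scale sizes chosen so the whole
validation battery runs in minutes on one CPU while keeping each question
statistically answerable:

* **Recovery**: 20 regions, 230 volumes, 10 pooled sessions, default SNR —
  small enough to run in seconds, large enough that recovery quality is
  dominated by the estimator rather than by trivial dimensionality.
* **Type-I calibration**: 100 null datasets (30-parcel atlas, 100 subjects,
  99 permutations). Features come from the generator's subject EC matrices
  directly: the calibration property concerns the resampling inference,
  which sits downstream of estimation, and 10,000 additional estimator runs
  would not change what is being tested. The calibration band [0.01, 0.12]
  is the binomial 95% envelope around 0.05 for 100 draws plus permutation
  granularity.
* **Pattern replication**: 20 replicate cohorts of 206 subjects on a
  40-parcel atlas (blocks 7,6,5,5,5,5,7 — DMN largest so that 5% selection
  retains at least two features per direction in every family), 5 CV
  repeats, 49 permutations, permutation testing for ridge at the 5%
  threshold (where the emulated design applied it). The replication
  questions are rank-based (which family comes first; is DMN significant
  while others are not), so reduced repeat/permutation counts trade only
  resolution, not validity.

## 5. Known limitations

* The estimator assumes the canonical HRF; regionally varying haemodynamics
  would leak into connectivity estimates (by design, the simulator matches
  the assumption — see §1).
* The endogeneity correction assumes the AR(1)-at-TR structure the
  generator obeys; under model mismatch it degrades toward the uncorrected
  estimator rather than failing loudly.
* Prediction quality is measured by Pearson r only, which ignores
  calibration and scale of the predictions.
* With very small network blocks the 5% selection rule is undefined
  (`k = 0`); atlases for the planted-effect experiments are sized to avoid
  this, and the error is explicit otherwise.
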