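# Methods

## Biophysical model

`neulink` simulates a single-compartment conductance-based neuron with seven
membrane currents: transient sodium in two kinetic variants (`gbar_Na` with
the spike-threshold shift `V_T`, and the faster perisomatic form `gbar_Nat`),
delayed-rectifier potassium (`gbar_Kd`), slow muscarinic potassium (`gbar_M`,
with its time-constant scale `tau_max`), fast non-inactivating potassium
(`gbar_Kv31`), high-threshold calcium (`gbar_L`), and leak.  The membrane
equation is

    C dV/dt = Σ_x gbar_x · gates_x · (E_x − V) + g_leak (E_leak − V) + I_inj + I_noise

with gates following first-order kinetics dx/dt = α_x(V)(1−x) − β_x(V)x.
Thirteen parameters are inferable (see `model.PARAM_NAMES`); the uniform
prior box over them is:

| parameter | range | units |
|---|---|---|
| C | [0.1, 15] | μF/cm² |
| R_input | [20, 1000] | MΩ |
| tau | [0.1, 70] | ms |
| gbar_Nat | [0, 250] | mS/cm² |
| gbar_Na | [0, 100] | mS/cm² |
| gbar_Kd | [0, 30] | mS/cm² |
| gbar_M | [0, 3] | mS/cm² |
| gbar_Kv31 | [0, 250] | mS/cm² |
| gbar_L | [0, 3] | mS/cm² |
| E_leak | [−130, −50] | mV |
| tau_max | [50, 4000] | ms |
| V_T | [−90, −35] | mV |
| r_SS | [0.1, 3] | — |

`r_SS` multiplies both rate constants of the gates of the `gbar_Na` and
`gbar_Kd` currents (m, h, n); values below 1 slow the approach of those
gates to steady state, broadening action potentials — the knob that lets the
single compartment reach pyramidal-like spike widths.

Non-inferred constants: E_Na = +69 mV, E_K = −90 mV, E_Ca = +120 mV,
Q10 = 2.3 applied to every gate rate as Q10^((T_exp − T_ref)/10) with
T_exp = 25 °C and T_ref = 36 °C (the temperature at which the transcribed
rate formulas are stated), step current I_inj = 300 pA on [100, 700) ms of
an 800 ms sweep, and per-step current noise N(10 pA, 1 pA²).  All are
configurable (`PhysConstants`), which also covers recording conditions such
as a different sodium reversal or bath temperature.

### Units and the effective area

C and the maximal conductances are densities while R_input, tau and I_inj
are absolute, so the model carries an implied membrane area.  We use the
unique assignment consistent with all three passive parameters:
A = 10⁻³ · tau / (R_input · C) cm², with total leak conductance 1/R_input.
Under it the passive response is exactly the RC curve with time constant
`tau` and steady-state deflection R_input · I_inj, which the test suite
verifies against the closed form.

### Integration

Gates use exponential Euler.  The membrane equation is linear in V for
frozen gates, so V is also advanced by its exact exponential solution per
step ("exponential Euler" throughout); this is unconditionally stable,
which matters because the prior admits tau = 0.1 ms, where forward Euler at
the default dt = 0.05 ms diverges for strongly conductive cells.  dt =
0.05 ms is part of the model definition: the per-step noise draw makes the
effective noise process dt-coupled.  A convergence test checks that halving
dt leaves extracted features essentially unchanged.  Traces that still
escape ±500 mV (possible only through gate-freezing error at extreme
parameters) are flagged diverged and featurize as all-undefined.

Noise streams are counter-based (Philox keyed by (seed, simulation index)),
so campaign results are independent of batch size and resumable
checkpoints reproduce bit-identically.

## Electrophysiological features

23 summaries per sweep (`features.FEATURE_NAMES`): first- and third-spike
threshold, amplitude, width at half height, AHP depth; spike counts in the
full stimulus window and four sub-windows ([100,175), [100,250), [100,400),
[400,700) ms); amplitude-adaptation ratio (first/second), mean consecutive
amplitude ratio, amplitude CV; ISI adaptation (second/first ISI) and ISI
CV; latency from stimulus onset to first threshold; resting mean over
[0,100) ms; and mean, SD, skewness of V over the stimulus window.

Spikes are detected where dV/dt crosses 20 mV/ms (configurable), the
convention of the standard feature-extraction pipelines for this kind of
data; window membership and ISIs use threshold times; widths interpolate
linearly between samples.  Count-like and ratio-like features are
log-transformed with no offset — a zero count or ratio is *undefined*, and a
sweep is **valid** only if all 23 transformed features are defined and
finite.  This is deliberate: a model fit is useless if it cannot produce,
say, any spike in the second half of the stimulus, and the undefined-feature
rate is itself a headline statistic (about half of random prior draws fail).
The mean consecutive amplitude ratio instead gets a logistic sigmoid.
Skewness of an exactly constant segment is left undefined (0/0).

Feature standardization (z-scoring) is always fitted on the valid rows of a
prior campaign and travels with the campaign library; every distance in the
package is Euclidean in that z-space.

## Posterior inference

The posterior q(θ|x) is a conditional mixture density network: a two-layer
tanh MLP (50+50 units) mapping the 23 z-scored features to the weights,
means and diagonal scales of an 8-component Gaussian mixture over the 13
z-scored parameters, trained by maximum likelihood with Adam (batch 256,
lr 10⁻³, 10 % validation split, early stopping with patience 20), written
directly in NumPy with hand-derived gradients (verified against finite
differences in the tests).  A mixture density network was chosen as the
density estimator because it admits exact log-density, exact sampling and
an analytic gradient in θ — the three operations the pipeline needs — with
very light dependencies.  Sampling rejects draws outside the prior box; the
MAP estimate is the best of 10,000 posterior draws refined by bounded
L-BFGS ascent on the log-density (refinement can only increase density and
is verified monotone).  The uncertainty score per cell is the Monte-Carlo
entropy proxy −Σₖ log q(θₖ|x) over 1,000 posterior draws, optionally
normalized by the least-entropy cell.

### Training schedules and misspecification

Real recordings sit systematically offset from the simulator's feature
manifold.  Training schedules (`TrainingSchedule`):

- `standard`: all valid (θ, x) pairs;
- `best_euclidean`: per observation, the K nearest valid simulations in
  z-space (default K = min(10,000, n_valid/10), deduplicated union);
- `noise_features`: the same subset with isotropic Gaussian noise added to
  the z-scored features — "0.1 SD noise" means 0.1 of each feature's
  campaign SD.  This smooths the training manifold so the estimator
  generalizes across the model–data gap;
- `noise_features_params`: additionally perturbs θ (in θ-SD units);
- `data_augmentation`: clean subset concatenated with its noised copy.

Noise is applied after z-scoring (SD-relative), the reading under which
"x SD noise" is well defined per feature.

### Evaluation protocol

`evaluate_fit` simulates, per observation, the MAP parameters and 10
posterior draws; a simulation *fails* if any feature is undefined, and
otherwise contributes its z-space distance to the observation.  Failures
count only toward the fail percentage, never the distance mean ± SD — both
are reported separately, so neither statistic hides the other.

## Gene linkage (sparse reduced-rank regression)

Expression counts are depth-normalized to CPM, log(1+x)-transformed and
z-scored per gene (the package's own normalization choice, recorded in
model metadata).  The linkage model predicts the 13 z-scored fitted
parameters from genes through a rank-2 latent space, Y ≈ 1μᵀ + XWVᵀ, with a
row-wise (group) elastic-net penalty on the encoder W selecting genes.
Fitting alternates (i) a multi-task elastic-net update of W given the
orthonormal decoder V (solved by scikit-learn's coordinate descent) and
(ii) an orthogonal-Procrustes SVD update of V given W, to a relative loss
tolerance of 10⁻⁶ or 500 iterations, then refits the selected genes without
penalty at fixed rank (relaxed refit, debiasing the shrinkage; can be
disabled).  α defaults to 0.5.  Cross-validation reports pooled held-out R²
(1 − SS_res/SS_tot over all 13 targets) along a λ path; λ selection uses
the usual one-standard-error rule (sparsest model within one SD of the best
CV score), or the CV maximum.

Group-level agreement between fitted and predicted parameter matrices
z-scores both by the mean/SD of the fitted set, averages within labels, and
takes the Frobenius distance; family/type separability is measured by a
multinomial logistic regression on an 80/20 stratified split.

## Synthetic cohorts

`synthetic` generates the study-shaped data every test runs on:

- `make_cells`: family centers uniform in the central 60 % of the prior box
  (re-drawn until the center's simulation is feature-valid), members
  jittered with SD = spread × range (default 0.03), clipped to the box and
  kept only if their own simulation is valid.  Defaults: 6 families × ~150
  cells, mirroring a ~10³-cell cortical Patch-seq study at desk scale.
- `make_observations`: simulate each cell, featurize, z-score with the
  campaign standardizer, add a constant z-space shift δ (the systematic
  model–data mismatch; δ = 0 gives well-specified observations) plus
  N(0, meas_sd²) measurement noise.
- `make_expression`: 400-gene panel with 20 informative genes whose
  log-rates are baseline + loading·z(θ) (loading rows normalized so the
  signal SD in log-rate space equals `loading_scale`, default 1), one
  marker gene per family, negative-binomial counts with dispersion 0.5 and
  lognormal depth variation with CV 0.3 — conventional values for
  plate-based single-cell protocols, not fitted to any dataset.

What the generator does *not* emulate: real transcriptome-wide structure,
dropout beyond NB sampling, batch effects, or the detailed shape of the
real feature-space mismatch (a constant shift is its first-order model).
Passing tests therefore demonstrate correctness and the qualitative
robustness ordering, not real-data performance figures.

## Problem sizes and reproducibility

The published campaign scale (millions of simulations) is cluster work; the
package's own test and acceptance runs use desk-scale campaigns — 20,000
simulations for the shared library, ≥ 5,000–10,000 draws for the
prior-failure-rate estimate, 50 synthetic observations for the
misspecification benchmark, 50,000 pairs for the linear-Gaussian sanity
check — sizes at which every reported quantity is stable to within its
stated tolerance.  One master seed drives everything; child seeds derive
via `SeedSequence(master, salt)` and stay below 2³¹.

## Known limitations

- Single compartment, no calcium dynamics, no additional channel types;
  reversal potentials are temperature-independent constants.
- The validity rule makes zero counts undefined by design; cells that stop
  firing in the second half of the stimulus are "failed" fits even when the
  early response matches.
- The mixture density network underestimates extremely sharp posteriors'
  tails (mixture stragglers) and, like any amortized estimator, inherits
  the coverage of its training manifold.
- sRRR assumes a linear gene→parameter map; the generator plants exactly
  such a map, so its recovery results are a best case.
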