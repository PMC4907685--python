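# Methods

## Model

Each population's state is a pair (x_v, x_I) of mean voltage (mV) and
current; the paired first-order equations implement convolution of
presynaptic input with the alpha kernel κ·t·e^(−κt). Presynaptic firing
is the zero-centred sigmoid S(v) = 1/(1+e^(−ρv)) − 1/2 with rate ρ = 2/3,
so the origin is an equilibrium of the noise-free system and S′(0) = ρ/4.
Time is milliseconds throughout the state space; frequencies are quoted
in Hz (ω = 2πf/1000 rad/ms in the resolvent).

The M1 architecture has four populations — superficial (SP), middle (MP)
and deep (DP) pyramidal plus inhibitory interneurons (II) — with a core
of nine inter-population connections (SP↔MP, SP→DP, II reciprocal with
all three pyramidal pools), four inhibitory self-connections, and
layer-specific exogenous inputs Es/Em/Ed. Three candidate edges (DP→SP,
DP→MP, MP→DP) generate the 8-model space by power set; the winning
variant adds DP→SP only (14 connections). The reduced canonical
microcircuit (CMC) baseline swaps MP for a spiny-stellate pool with
forward SS→SP→DP wiring, II reciprocal to SS/SP/DP, four
self-connections (12 edges) and a single granular input. Its exact edge
set is a declared default of this package: the published diagrams do not
enumerate it, so we adopt the standard canonical-microcircuit graph
restricted to these populations.

Effective connection strengths are `sign × baseline × exp(γ + β_c)`:
γ are intrinsic log-scalings (rest), β_c condition-specific log changes
for grip and post-grip (rest is the zero-modulation reference). Signs
are structural: inhibitory iff the source is II or the connection is a
self-connection (gain/self-inhibition); log-scale parameterisation
preserves them.

## Spectral forward model

The observed auto-spectrum is predicted by linearisation at the fixed
point (the origin, since inputs are zero-mean). Interlaminar conduction
delays D (prior 1 ms on inter-population edges) are treated to first
order: x(t−D) ≈ x(t) − D ẋ(t) gives Q = (I + D∘J)⁻¹ J, which reduces to
J exactly at zero delay. Transfer functions from each laminar input are
H(f) = L (iωI − Q)⁻¹ B with B injecting κ-scaled input into the target
population's current equation and L the observation row (gain × laminar
contributions on voltages; prior contributions 0.2/0.2/0.6/0 for
SP/MP/DP/II). The predicted spectrum is Σ_l |H_l(f)|² S_l(f) + channel
white + channel pink/f, with S_l(f) = gain_l²(white + pink/f) the
one-sided input density. The operator used in fitting evaluates this by
eigendecomposition of Q (batched over parameter vectors), which also
yields the stability check (all Re λ < 0); unstable vectors are flagged
rather than evaluated.

Only the 1×1 auto-spectral density of a single source is modelled, on a
5–45 Hz grid at 0.5 Hz (81 points). Requests outside the band raise an
error; the matrix form of the code would extend to multi-channel
cross-spectra but that is out of scope.

## Default parameters

The prior means of the biophysical parameters are declared in
`m1dcm/defaults.yaml` (version 1) and were constructed to satisfy the
model's design constraints rather than copied from any published table:

- An excitatory–inhibitory loop between populations with rate constants
  κ₁, κ₂ resonates at ω* = √(κ₁κ₂) rad/ms near criticality, with
  critical strength product g₁g₂ = 36(κ₁+κ₂)² at ρ = 2/3. Time
  constants of 4 ms (SP), 7 ms (MP), 16 ms (DP) and 4 ms (II) therefore
  put the DP–II loop near 20 Hz (beta) and the SP–II loop near 40 Hz,
  making the superficial population spectrally faster than the deep one.
- Baseline strengths were then refined by a seeded local search against
  four requirements evaluated on the linearised model: robust stability
  (margin at the prior mean and under log-scale jitter), a rest-spectrum
  peak inside 15–30 Hz, a superficial population peak above the deep
  one, and grip-direction modulators (+0.3 on DP→SP, SP↔MP and the MP
  self-connection) *reducing* integrated beta power, with post-grip
  input increases (Es, Ed) raising it. The frozen defaults give a rest
  peak at 17 Hz, SP/DP population peaks at 43.5/17 Hz, a grip/rest
  beta-power ratio of 0.39 and a post-grip/rest ratio of 1.08.
- The optional DP→MP edge closes a destabilising three-stage excitatory
  loop (DP→MP→SP→DP); its baseline (and MP→DP's) is deliberately weak so
  every enumerated variant is stable at its prior mean.
- Absolute input noise densities are small (1e-6 power/Hz) so the
  stochastic simulation operates in the sigmoid's near-linear regime;
  absolute scale is not identifiable anyway (the observation gain
  absorbs it on the log scale).

Prior variances on the fitted log-scale parameters: 1/16 on γ and β,
1/64 on rate-constant and delay deviations, 1/16 on observation
contributions, 1/8 on gain and noise logs — all configurable.

## Inversion

The data feature is log-power on the shared grid, all conditions fitted
jointly with shared γ and per-condition β; the error model is i.i.d.
Gaussian on log-power with precision τ estimated by closed-form
coordinate updates (or fixed, for conjugate checks). Free-energy ascent
uses damped Gauss–Newton steps (Levenberg–Marquardt on the diagonal),
with sensitivities from central finite differences (step 1e-4, batched).
A step is accepted only if the free energy — recomputed consistently at
the proposed mean with its own Jacobian, covariance and τ — does not
decrease; otherwise damping increases. Accepted-step free energies are
therefore non-decreasing by construction, and a proposal that crosses
the stability boundary (NaN prediction) is rejected like any failed
step, so the returned posterior mean is always admissible. Convergence
is declared when an accepted step improves F by less than `tol`
(default 0.01 nats; recovery experiments use 1e-3 for tighter
convergence, which measurably reduces posterior shrinkage bias). On
linear-Gaussian problems the scheme is exact: posterior mean, covariance
and free energy match the conjugate solution to ~1e-12.

Identifiability: a single-channel spectrum constrains loop products and
input→output pathway combinations, not every edge separately — the
sensitivity matrix at the default truth has a large numerical null space
(roughly 40 of 70 directions). This is intrinsic to one-source DCM and
is resolved by the priors; consequently point recovery of individual
connections shows shrinkage, while the identified subspace is recovered
essentially exactly on noiseless data. Tests and the acceptance script
therefore check correlation/bias of recovered perturbations across
subjects and identified-subspace recovery, not per-edge equality.

## Synthetic data

The generator emulates the study design: 11 subjects by default, 60
handgrip trials, 600 Hz virtual electrode. Spectral mode draws
per-subject parameters (population truth + N(0, 0.1²) jitter on γ),
evaluates the linearised prediction per condition and multiplies
i.i.d. log-normal noise (SD 0.1). Time mode simulates the stochastic
network with RK4 (forcing synthesised spectrally at half-step
resolution and band-limited at 150 Hz, far above the analysis band, to
avoid aliased forcing power in fixed-step integration), switching the
condition modulators at cue onset (grip, 4 s) and release (post-grip),
then runs the empirical feature pipeline. Default condition effects are
+0.3 log units in the directions of the group result (grip: DP→SP,
SP↔MP, MP self; post-grip: Es and Ed input gains); effect size, jitter
and noise SDs are declared configuration, chosen as a moderate,
realistically detectable effect. Everything regenerates bit-identically
from (seed, config).

What the generator does not emulate: sensor-level MEG noise and
beamformer leakage, artefacts, head movement, non-stationarity within
conditions, between-subject differences in κ or observation gain, and
model mismatch (data are generated by the same family that is fitted,
except in model-recovery experiments). Passing recovery tests therefore
demonstrate internal consistency of generator + fitter, not performance
on real recordings.

## Feature extraction

Condition windows are fixed at [−1, 0] s (rest), [1, 2] s (grip) and
[4, 5] s (post-grip) around the visual cue; windows are cut per trial
and concatenated within condition, trials too close to the recording
edges are dropped with a warning. Spectra use an averaged Hann-tapered
periodogram (1 s windows, 50% overlap) interpolated onto the shared
grid; a Yule–Walker autoregressive estimator (order 30) is available
behind a flag. The Morlet spectrogram (7 cycles default) averages power
across trials *before* the percent-change baseline ratio — dividing by a
noisy per-trial baseline would bias stationary data upward by roughly
E[1/B] vs 1/E[B] (measured +12% on white noise at low frequencies).

## Statistics and model comparison

Fixed-effects comparison sums per-subject free energies per model
(appropriate when all subjects are assumed to share one architecture);
relative log evidences, Bayes factors (exp ΔF) and softmax posterior
probabilities under a uniform model prior follow. The conventional
evidence scale is weak < 3 ≤ positive < 20 ≤ strong < 150 ≤ very strong.
Group-level parameter statistics are two-tailed one-sample t-tests
across subjects with Benjamini–Hochberg FDR at q = 0.05 (via
statsmodels); trends are uncorrected 0.05 < p < 0.10. Zero-variance
columns get p = 0 (nonzero mean) or 1, with a warning.

## Numerical choices and validation sizes

- Fixed-step RK4 at dt = 1 ms (0.5 ms validated by step-halving to
  <1% RMS); simulation forcing at dt/2.
- The forward-vs-simulation oracle uses 100 seeded realisations of 8 s
  with 4 s Welch segments, and compares against the *expected* Welch
  estimate (prediction convolved with the window's spectral kernel);
  the per-frequency 3-standard-error criterion is evaluated on a fixed
  seed because the maximum over 81 correlated bins of an exact match
  still brushes 3 SE by chance.
- Parameter recovery: 12 subjects, ±0.3 log-unit perturbations on four
  key connections (SP→DP, DP→SP, II→SP, MP→II), log-noise SD 0.1.
- Model recovery: 20 replicate single-subject cohorts generated by the
  winning model, fitted with the winning model and the reduced CMC;
  preference is ΔF ≥ 3. Observed margins are tens of nats, so one
  subject per replicate suffices.
- Null calibration of the group statistics: 500–1000 replicates of
  11 × 20 standard-normal tables.

## Limitations

- Single source only: no inter-areal connectivity, no volume-conduction
  or lead-field modelling; inputs from other motor nodes appear only as
  exogenous noise terms.
- First-order delay correction; adequate for ~1 ms delays, not for long
  conduction delays.
- The declared default baselines are one stable, constraint-satisfying
  configuration, not estimates from data; absolute parameter values
  carry no empirical meaning, only log-scalings relative to them.
- Fixed-effects model comparison assumes architecture homogeneity across
  subjects; random-effects selection and hierarchical (empirical-Bayes)
  group inversion are out of scope.
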