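# m1dcm — laminar dynamic causal modelling of motor-cortex spectra

Human primary motor cortex (M1) produces strong beta-band (15–30 Hz)
oscillations that fall during voluntary movement (movement-related beta
desynchronisation) and rebound above baseline after it (post-movement beta
rebound). `m1dcm` implements a biophysical model of the cortical column
that explains these spectra mechanistically, and the Bayesian machinery to
fit it to data and compare circuit architectures.

It is written for systems/computational neuroscientists who have a
single-source ("virtual electrode") time series or auto-spectrum per
condition and want laminar effective-connectivity estimates from it.

## The model

Each of four neuronal populations — superficial (layer 2/3), middle
(layer 5A) and deep (layer 5B) pyramidal cells plus inhibitory
interneurons — is a neural mass obeying

    ẋ_v = x_I
    ẋ_I = κU − 2κ x_I − κ² x_v,        U = γ S(x_v) + E

an alpha-kernel synaptic convolution of presynaptic input `U`, with `κ`
the lumped rate constant (1/ms), `S` a zero-centred sigmoid (slope 2/3)
mapping voltage to normalised firing, `γ` the signed effective connection
strengths, and `E` a mixture of white and 1/f noise entering each lamina
separately (Es, Em, Ed). Projections from the interneuron pool and all
self-connections (gain terms) are inhibitory; everything else is
glutamatergic. Connection strengths are parameterised as
`baseline × exp(γ)` with log-scaling coefficients γ (rest) and β
(condition-specific changes from rest to grip and rest to post-grip).

The observed 5–45 Hz auto-spectrum is predicted by linearising around the
fixed point: with the delay-corrected Jacobian `Q` (first-order Taylor
treatment of ~1 ms interlaminar conduction delays), transfer functions
`H(f) = L (2πif·I − Q)⁻¹ B` map each laminar input to the measured
channel, a gain-weighted mixture of population voltages with prior
weights 20% / 20% / 60% for superficial / middle / deep layers (deep
Betz cells dominate the dipole moment). The predicted spectrum is
`Σ |H(f)|² S_in(f)` plus channel noise.

Inversion is by variational Laplace: Gaussian posteriors over the
log-scale parameters obtained by free-energy ascent, where the free
energy `F` bounds the log model evidence. Architectures (8 M1 variants
built from an anatomically grounded core plus optional deep↔middle and
deep→superficial connections, and a reduced canonical-microcircuit
baseline) are compared by fixed-effects summed `F`; a difference of 3
nats is a Bayes factor of about 20:1.

## Worked example

Generate a small synthetic cohort from the winning 14-connection M1
circuit, fit it with that circuit and with the reduced CMC baseline, and
compare the models:

```python
import numpy as np
from m1dcm import SpectralDCM, compare_models, default_ground_truth, synth_cohort
from m1dcm.model_space import CONDITIONS

truth = default_ground_truth(seed=1, n_subjects=3)
cohort = synth_cohort(truth)

F = {"winning_m1": [], "reduced_cmc": []}
for sub in cohort.subjects:
    X = np.vstack([sub.spectra[c] for c in CONDITIONS])
    for name in F:
        F[name].append(SpectralDCM(model=name, tol=1e-3).fit(X).free_energy_)

table = compare_models(np.column_stack([F["winning_m1"], F["reduced_cmc"]]),
                       model_names=["winning_m1", "reduced_cmc"])
print(table.round(3))
```

prints

```
             total_F  relative_logev  ...  posterior_prob  evidence_category
winning_m1   524.726           0.000  ...             1.0               weak
reduced_cmc  401.738        -122.989  ...             0.0        very strong
```

The generating architecture wins by ~123 nats of summed log evidence
(`evidence_category` labels the strength of the best model over each row,
so the best row reads "weak" against itself). Fitting one subject and
reading off a condition effect:

```python
est = SpectralDCM(model="winning_m1", tol=1e-3).fit(
    np.vstack([cohort.subjects[0].spectra[c] for c in CONDITIONS]))
grip = est.posterior_.mean[est.forward_.layout.slice_of("beta_grip")]
idx = est.model_.connection_index("DP", "SP")
print(f"R^2 = {est.score():.3f}, grip DP->SP = {grip[idx]:+.2f} (true +0.30)")
# R^2 = 0.995, grip DP->SP = +0.16 (true +0.30)
```

The fit explains 99.5% of log-spectral variance; the deep-to-superficial
grip modulation is recovered with the expected posterior shrinkage (a
single-channel spectrum identifies pathway combinations, and the prior
resolves the remainder).

A command-line interface wraps the same workflows:

```bash
m1dcm simulate --subjects 11 --seed 1 --out cohort/
m1dcm fit --data cohort/ --model winning_m1 --model reduced_cmc --out fits/
m1dcm compare --fits fits/ --out evidence.csv
m1dcm report --fits fits/ --out report/
```

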