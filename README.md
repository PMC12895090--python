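# streammove

Bayesian dispersal–observation modelling of stream-fish mark–recapture
data.

## The problem

In a small stream, fish movement is effectively one-dimensional: an
individual tagged in one 10-m section either stays, shifts up- or
downstream, or leaves the study reach for good. Observed displacement
between capture occasions is a *biased* readout of the true movement
process, because a fish is recaptured only if it simultaneously survived,
kept its tag, stayed inside the reach, and was detected by the
electrofishing pass. `streammove` implements the dispersal–observation
model that separates these processes, for ecologists analysing
capture–mark–recapture (CMR) data from linear habitats.

## The model

Each *movement replicate* pairs a capture at occasion *t* (location
X₀, metres from the downstream end) with the following occasion. The end
location follows a heavy-tailed Student-t kernel,

    X₁ | X₀ ~ t_ν(X₀, σ),            ν = 5 fixed,

whose dispersion — not its mean — is linked to predictors on the log
scale with the elapsed time η (days) as an offset:

    ln σ = β₀ + Σₖ βₖ xₖ + ln η.

Predictors are body size, distance-weighted densities of each focal
species (density convolved with exp(−λ·d), λ = 0.1 m⁻¹), Julian day,
habitat refuge area and current velocity — the first group z-scored, the
habitat pair normalized by its per-occasion cross-sectional mean. σ is
the t *scale* parameter (the BUGS-style t(μ, σ², ν) convention); the
kernel's true standard deviation for ν = 5 is σ·√(5/3).

The observation layer couples the kernel to a Bernoulli recapture state

    Y ~ Bernoulli(φ·z),     z = 1{0 ≤ X₁ ≤ L},     L = 430 m,

where φ compounds survival, detection and tag retention. For
unrecaptured fish (Y = 0) the latent X₁ is either marginalized in closed
form via the t CDF (default) or imputed by data augmentation inside the
sampler. Inference is adaptive random-walk Metropolis-within-Gibbs with
weakly informative priors (β₀ ~ N(0, 2.5²), βₖ ~ N(0, 1), φ truncated
normal on (0,1)); convergence is judged by split-chain R-hat < 1.1, and
effects are called robust when the posterior mass on one side of zero
reaches 0.95.

## Worked example

Fit the model to a synthetic dataset drawn from the model itself
(300 replicates; true β₀ = ln 0.3 per day, β_size = 0.4, φ = 0.5):

```python
import math, pandas as pd
import streammove as sm

reps = sm.simulate_replicates(300, math.log(0.3), {"body_size": 0.4},
                              phi=0.5, seed=1)
model = sm.DispersalObservationModel.from_replicates(
    reps, species="synthetic creek chub")
res = model.fit(sm.SamplerConfig(n_iter=4000, burn_in=1500, thin=5, seed=1))
print(res.summary())
```

```
Dispersal-observation model — synthetic creek chub
replicates: 300 (recaptured: 134), nu=5, L=430 m
chains: 4, kept draws/chain: 500, mode: marginalized
Species: synthetic creek chub
parameter                     median      2.5%     97.5%  Pr(sign)  robust
beta0                         -1.130    -1.296    -0.943     1.000  *
beta_body_size                 0.444     0.268     0.633     1.000  *
phi                            0.473     0.416     0.536     1.000  *
```

Every 95% credible interval brackets its generating value: exp(−1.13) ≈
0.32 m/day dispersion scale against a truth of 0.30, a body-size effect
of 0.44 against 0.4, and recapture probability 0.47 against 0.5 — even
though only 134 of 300 replicates were ever recaptured. Predicted
movement bands follow from the posterior:

```python
band = res.movement_band(pd.DataFrame({"body_size": [-2.0, 0.0, 2.0]}),
                         eta_ref=93.0)
print(band.bounds[0.9])   # [25.5, 61.1, 155.0] metres
```

i.e. over a 93-day interval, 90% of average-sized fish are predicted to
remain within ±61 m, but large individuals (+2 sd) range within ±155 m —
the size dependence the β_size coefficient encodes.

The same workflow runs from the shell: `streammove simulate` writes a
full 4-species synthetic study (capture, habitat and occasion tables),
`streammove fit` runs the per-species analysis end to end, `streammove
recover` scores credible-interval coverage over repeated
generate-and-fit cycles, and `streammove report` re-summarizes saved
draws.

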