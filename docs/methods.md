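# Methods

## Model

`streammove` fits a dispersal–observation model to one-dimensional
capture–mark–recapture data. The analysis unit is the *movement
replicate*: one capture of a tagged individual at occasion *t*, paired
with the next occasion. Locations are continuous metres from the
downstream end of the reach; a fish captured in section *s* (10-m
half-open intervals) is placed at the section midpoint 10(s−1)+5.

**Movement.** X₁ | X₀ ~ t_ν(X₀, σ) with ν fixed at 5. The Student-t was
chosen over a Gaussian because displacement data in streams are
heavy-tailed: most individuals are sedentary while a few range widely,
and a ν = 5 kernel keeps coefficient estimates insensitive to those
outliers. σ is the *scale* of the location-scale t (the BUGS/JAGS
`dt(mu, 1/sigma^2, nu)` convention). It is sometimes loosely called the
kernel's standard deviation, but for ν = 5 the true standard deviation
is σ·√(5/3); the generator-calibration test pins this identity.

**Dispersion regression.** ln σ = β₀ + Σ βₖxₖ + ln η. The offset ln η
(elapsed days) standardizes movement per unit time, so exp(β₀) is a
per-day dispersion scale; an occasional long inter-survey gap (the
generator plants one 171-day interval among ~93-day intervals) needs no
special-casing. Modelling the *dispersion* rather than the mean reflects
that covariates change how far fish range, not the direction they
prefer.

**Predictors** (all evaluated at the capture occasion and section):
body size (total length, mm), the distance-weighted density of each
focal species, Julian day, habitat refuge area (HRA) and current
velocity. Distance weighting convolves detection-corrected section
densities D_s (count /(p_detect·area)) with exp(−λ·d) over section
midpoints, λ = 0.1 m⁻¹ — neighbours within ~10 m dominate but farther
fish still contribute. Body size, the densities and Julian day are
z-scored (sample sd, n−1) over the replicate rows entering each species'
fit; fitting and standardizing per species keeps coefficients comparable
within a species' model, which is how the models are run (one fit per
species, no pooling). HRA and velocity are instead divided by their
cross-sectional occasion means (per-occasion mean 1), which removes
seasonal level shifts while preserving spatial contrast; an occasion
with all-zero values maps to zero with a warning rather than erroring,
since it carries no contrast to preserve.

**Observation.** Y ~ Bernoulli(φ·z), z = 1{0 ≤ X₁ ≤ L} (closed bounds),
L = 430 m. φ compounds survival, detection and tag retention, constant
across occasions within a species; tag loss is not modelled separately.
For Y = 0 the likelihood marginalizes the latent X₁ exactly:
P(Y=0|X₀) = 1 − φ·[T_ν((L−X₀)/σ) − T_ν(−X₀/σ)]. Replicates of the same
individual across intervals are treated as independent; a fish
recaptured after a skipped occasion re-enters as a fresh replicate and
the intermediate Y = 0 replicate is retained, even though the animal is
later known alive — matching the replicate structure the likelihood
assumes. The likelihood of an observed X₁ is not truncated to [0, L]:
staying is already priced by the φ·z term, and the kernel density at the
observed location is the correct conditional contribution.

**Priors.** β₀ ~ N(0, 2.5²), βₖ ~ N(0, 1²), φ ~ N(0.5, 1²) truncated to
(0, 1) with the truncation normalizer included. ν and λ are fixed, not
estimated (both exposed in configuration).

## Sampler

Adaptive random-walk Metropolis-within-Gibbs over (β₀, βₖ, logit φ);
sampling φ on the logit scale (with the Jacobian) keeps proposals inside
the unit interval. Proposal scales adapt every 50 iterations during
burn-in toward a 0.3 acceptance rate and are frozen afterwards, so the
retained draws come from a fixed-kernel chain. Defaults mirror a
40,000-iteration protocol with 15,000 burn-in and thinning every 30;
kept draws per chain are floor((n_iter − burn_in)/thin) — note that with
those numbers this is 833, not a round 1000. Four chains (seeds
`seed + c`) support the split-chain Gelman–Rubin diagnostic
√((n−1)/n + B/(nW)); the conventional 1.1 threshold flags
non-convergence, and a zero within-chain variance returns NaN with a
warning rather than a spurious pass. Chains initialize from N(0, 0.1)
coefficients and U(0.2, 0.8) recapture probability; a non-finite initial
posterior raises immediately with a diagnostic dump. With a fixed seed
the sampler is bit-for-bit reproducible.

Two modes share these updates. The default *marginalized* mode uses the
closed-form Y = 0 likelihood. The *augmented* mode instead imputes each
unrecaptured replicate's X₁ every iteration — proposing from the current
movement kernel, so the kernel density cancels and the acceptance ratio
reduces to the observation term (1−φ·z′)/(1−φ·z) — which mirrors how the
model is usually run in BUGS/JAGS. The two modes are two routes to the
same posterior; the test suite requires their parameter means to agree
within combined Monte-Carlo standard errors, which is the strongest
internal check on the marginalization algebra.

Log arguments are floored at 1e-300 before taking logs (e.g. 1 − φ·z at
φ → 1), and floored evaluations are counted on a module-level clip
counter so a sampler excursion into a degenerate corner is visible
rather than silent.

## Reporting

Coefficients are summarized by the pooled posterior median and
equal-tailed 95% credible interval (linear-interpolation quantiles);
"traditional" credible intervals are read as equal-tailed, not HPD. The
posterior probability of an effect is the larger of the posterior mass
above and below zero (exact zeros split evenly); ≥ 0.95 is flagged
robust. Movement bands report, along a covariate grid, the distance
within which 50% and 90% of individuals are predicted to remain over a
reference interval η_ref (default 93 days, the mean survey cadence).
The predicted absolute displacement is a mixture over posterior draws of
folded-t distributions with scale σ_d; band endpoints solve the mixture
CDF mean_d[2T_ν(q/σ_d) − 1] = level by bracketed root-finding
(xtol 1e-10), which is deterministic and avoids Monte-Carlo noise in the
figures. Bands use the unconditioned kernel (no truncation to the reach)
and are one-sided from zero because they describe absolute movement;
signed displacement quantiles follow from symmetry.

## Synthetic data

The generator exists so every stage — file parsing through inference —
is testable without any field download.

*Replicate-level* (`simulate_replicates`): covariates iid standard
normal, start locations uniform over section midpoints, displacement
from the t kernel, permanent emigration outside [0, L], recapture
Bernoulli(φ·z). Because its covariates are exactly the ones the model
conditions on, this is the generator behind recovery and acceptance
runs. The reference truth used throughout — β₀ = ln 0.3 (per-day scale),
β_size = 0.4, φ = 0.5, 300 replicates, η = 93 days — gives dispersion
σ ≈ 28 m per interval, modest emigration, and ~45% recapture: an
informative but not easy regime.

*Reach-level* (`generate_reach` / `simulate_individuals` /
`emit_dataset`): a 43 × 10 m reach, 15 occasions at 93-day intervals
with one 171-day gap; habitat drawn at the study's scales (section area
lognormal, mean 32.51 m², sd 9.21; HRA zero-inflated lognormal targeting
mean 0.45 / sd 0.84 m², 30% structural zeros — a declared choice, the
zero fraction not being published; velocity lognormal, mean 0.06 / sd
0.08 m/s). Four default species carry study-scale abundance ranks (creek
chub > bluehead chub ≈ green sunfish > redbreast sunfish) and body-size
distributions (means 92/91/85/96 mm, truncated above the 60-mm tagging
threshold). Individuals enter uniformly over the reach (the true initial
spatial distribution is unknown; uniform is declared, not inferred),
move by the kernel, are captured with per-occasion probability p_detect
and tagged at first capture, and die with per-interval probability
1 − φ/p_detect, so the compound recapture probability equals the φ the
model estimates; default φ = 0.13 with p_detect = 0.4 reproduces the
~11% consecutive-recapture rate typical of single-pass electrofishing
studies at this spatial grain. The emitted dataset records the planted
number of consecutive-occasion recapture events per species, which the
replicate builder must reproduce exactly.

What the reach simulator does *not* emulate: behavioural density
dependence (simulated fish do not react to simulated neighbours —
density covariates are predictors observed at capture, not feedback),
growth between occasions, sex or individual heterogeneity beyond body
size, and detection varying by season. Its density/habitat covariates
are standardized cross-sectionally at each occasion during simulation,
which differs slightly from the fit-time standardization over replicate
rows; for this reason exact parameter-recovery claims rest on the
replicate-level generator, while the reach-level simulator backs
structural and bookkeeping tests. Passing tests therefore demonstrate
correctness of the inference machinery under the model's own
assumptions, not robustness to the ways real field data violate them.

## Numerical and design choices

- t density and CDF go through `scipy.special` (`gammaln`, `stdtr`);
  the sampler's hot path caches kernel terms so a φ-only update
  re-evaluates no t CDF. The cached path is asserted equal (1e-12) to
  the plain likelihood implementation in tests.
- Replicate pairing defaults to consecutive occasions
  (`strict_consecutive`); `next_capture` (pair with the next capture at
  any later occasion, η = actual elapsed days) is available where
  consecutive pairing is too sparse. Recapture tallies are reported both
  as individual×interval events and as distinct individuals, since the
  two conventions are easy to conflate.
- Detection probabilities for density correction are an input table
  (species × occasion); absent a table, densities are used raw with a
  warning. Densities default to all captured conspecifics, not only
  tagged ones (`density_source` configurable).
- Degenerate inputs fail loudly: constant vectors cannot be z-scored,
  φ outside (0, 1) has −∞ prior, out-of-range sections/occasions raise
  naming the row, duplicate (tag, occasion) rows raise.
- Parameter-recovery and acceptance runs use 4 chains × 4000 iterations
  (1500 burn-in, thin 5) on 300-replicate datasets — sizes at which the
  posterior is well resolved and 50-repetition coverage experiments
  complete quickly; the full 40,000-iteration protocol remains the
  library default for real analyses.

## Known limitations

- φ is constant within species (no seasonal or covariate-dependent
  recapture); survival, detection and tag retention are not separable
  from each other or from the data at hand.
- One-dimensional geometry only: no branching networks, no 2-D
  coordinates, no telemetry/antenna detections.
- λ and ν are fixed constants, not estimated; sensitivity to them must
  be probed by re-fitting.
- The augmented sampler's latent proposals come from the prior kernel;
  with extremely tight posteriors over σ this is still valid but mixes
  more slowly than the marginalized path, which is why marginalized is
  the default.
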