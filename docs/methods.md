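# Methods

## Model

For a hatch trait measured on larva *k* of family *j* incubated in
treatment *i*:

    y_ijk = μ + T_i + a_j + b_ij + e_ijk
    a_j   ~ N(0, σ²_F)            shared family effect
    b_ij  ~ N(0, σ²_FS,i)         family-by-treatment effect, one variance
                                  per treatment, independent across
                                  treatments (idh structure)
    e_ijk ~ N(0, σ²_ε,i)          residual, per-treatment or homogeneous

Treatments enter as fixed contrasts against the cold reference level.
Emergence traits extend the fixed part with mean residence temperature
(Mean T, °C), cumulative degree-days (°C·days), and raceway contrasts;
continuous covariates are mean-centred before fitting (centres recorded so
predictions are on the original scale).

Setting the cross-treatment covariances of family effects to zero is a
modelling commitment, not a simplification of convenience: it encodes the
biological hypothesis that a family's rank in one thermal environment
carries no information about its rank in another (cryptic variation
released by stress).  A consequence worth remembering is that σ²_FS,i is
estimated from essentially 10 family-level contrasts per treatment, so its
posterior is wide and right-skewed.

## Sampler

A blocked Gibbs sampler with fully conjugate updates:

1. **Location block.**  All fixed and random effects θ = (β, u) are drawn
   jointly from N(C⁻¹r, C⁻¹) with C = Σ_t W_t'W_t/σ²_ε,t + D⁻¹ and
   r = Σ_t W_t'y_t/σ²_ε,t, where D holds the prior variances (10⁸ for fixed
   effects — effectively flat while keeping every conditional proper — and
   the current component variances for random effects).  One dense Cholesky
   per iteration; the per-treatment Gram matrices are precomputed, so an
   iteration costs O(p³) with p ≈ 45 for the reference design.  The joint
   update avoids the slow mixing that scalar Gibbs exhibits in crossed
   designs.
2. **Variance components.**  σ²_g | u_g ~ IG(a₀ + q_g/2, b₀ + ‖u_g‖²/2).
3. **Residual groups.**  σ²_ε,t | θ ~ IG(a₀ + n_t/2, b₀ + SS_t/2).

Priors default to a₀ = b₀ = 0.001 on every variance (near-flat on the
variance scale).  The reference run length is 400,000 iterations, burn-in
10,000, thinning 100 (3,900 retained draws); validation studies use 20,000
/ 2,000 / 10 (1,800 retained), which diagnostics show is ample for this
model family.  All draws are reproducible from a single integer seed.

Degenerate inputs are rejected loudly: empty residual groups, non-positive
variances, unknown treatment labels, missing-response rows (dropped with a
logged count).

## Summaries

* **Point estimate**: argmax of a Gaussian KDE (Silverman bandwidth,
  1,024-point grid over the draw range).  Constant draw vectors return the
  constant.
* **Interval**: shortest contiguous window of the sorted draws containing
  ⌈0.95·n⌉ points — exact for empirical draws, deterministic, and checked
  against exhaustive window search in tests.
* **Convergence**: Heidelberger–Welch stationarity test (Cramér–von Mises
  statistic of the standardised cumulative-sum process; spectral density at
  zero from an AIC-selected Yule–Walker AR fit on the second half of the
  chain; iterative 10% discards up to half the chain; α = 0.05) plus the
  relative half-width check with ε = 0.1.  Constant chains pass trivially
  with p = 1 by convention.

## Inference products

* **DIC** = D̄ + p_D, p_D = D̄ − D(θ̄), with D(·) the −2 log-likelihood at a
  parameter point and θ̄ the posterior mean of the location effects and
  residual variances.  Selection fits an ordered candidate list (most
  complex first), flags fixed effects whose 95% credible interval spans
  zero, prefers the simplest model within two DIC units of the minimum, and
  finally tests a homogeneous-residual variant whenever the winner carries
  no family-by-treatment interaction.  "Visually comparable fit" is
  operationalised as the ΔDIC ≤ 2 rule alone.
* **Variance-ratio test**: iteration-wise F-ratio profile; tail-area
  probability 1 − (#ratios > 1)/N with *strict* inequality, so identical
  components give tail area 1.0.  The caller fixes the numerator; the code
  warns (never swaps) if the median ratio contradicts the one-tailed
  expectation.
* **Heritability**: H² = 2σ²_F/(σ²_F + σ²_ε + other components), computed
  draw-by-draw and summarised as mode + 95% HPD.  The total is the sum of
  all variance components in the fitted model.  The factor 2 converts
  full-sib family variance to a total-genetic scale; reported values are
  upper bounds on narrow-sense h².  Draws can exceed 1 when the family
  component dominates — they are reported as computed.
* **Reaction norms**: per family × treatment, the posterior of
  (intercept + treatment contrast + family effects).  Intervals reflect
  family-level uncertainty only — residual noise is deliberately excluded,
  since the table describes conditioned means, not predictive draws for new
  larvae.

## Thermal covariates

Degree-days over a residence interval: Σ over calendar days of
max(daily mean − T₀, 0) × (fraction of the day inside the interval), with
T₀ = 0 °C by default (sturgeon growth is nil at freezing).  "Daily
temperature" is the mean of the readings within the calendar day; the
logger series is integrated as a step function (each reading holds until
the next), which makes every quantity exactly computable and testable.  No
upper-threshold or sine-interpolation degree-day variants are offered.

## Synthetic study generator

The generator emulates the reference design: 5 dams × 2 sires each → 10
half-sib families, 30 larvae per family per treatment at hatch
(N = 1,200); a subset of one full-sib family per dam × 18 larvae per
treatment (N = 360) followed to emergence across 3 raceways with 87%
emergence success (missing-at-random Bernoulli).  Thermal regimes:
constant series at the base temperature; fluctuating regimes draw each
day's excursion uniformly from the configured range (1–3 °C/day ambient,
1–9 °C/day anthropogenic) and oscillate sinusoidally about the base, the
sampled waveform rescaled so the realised daily range equals the drawn
excursion exactly.

Generative variance defaults are the package's reference values — e.g. for
body length, family variances (warm, var, amb, cold) = (1.10, 0.46, 0.44,
0.18) and residual variances (0.74, 0.66, 0.49, 0.35); emergence time has
a shared family variance 0.36 with homogeneous residual 2.69.  Quantities
the reference tables do not pin down were chosen once on field grounds and
left alone: hatch grand means sit mid-range of the observed family means
(body length 12.5 mm), treatment shifts follow the temperature-size rule
(warm-incubated larvae ~1 mm shorter at hatch), warm-incubated larvae
spend ~3 days longer in the chambers, hatch timing staggers with
temperature (warm day 6 to cold day 12 post-fertilization), and the
Mean T / Degree-Days slopes on emergence time default to zero (the effect,
where present at all, is slight).  The shared hatch family variance σ²_F
defaults to zero — the treatment-specific component carries the signal —
but is configurable.

What the generator does **not** emulate: egg mortality, mechanistic
development–temperature coupling (hatch offsets are fixed per treatment),
non-Gaussian trait distributions, or selective (non-random) emergence
failure.  Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the stated model, not robustness to real-data
pathologies.

## Validation protocol and known estimator behaviour

The recovery study (`gxevar.protocols.recovery_study`) simulates replicate
studies at the reference design, refits the hatch model with the reduced
sampler run, and averages posterior modes across replicates (default 60;
the acceptance script uses 100).  Two properties of this protocol are worth
stating plainly:

* the **residual variances** (300 observations each) are recovered
  essentially without bias (<2%);
* the **family-by-treatment variances** rest on only 10 family levels, so
  their posteriors are strongly right-skewed and the reported *mode* sits
  systematically below the generative value — the conditional-posterior
  mode scales as q/(q + 2(a₀ + 1)) ≈ 10/12 of the sufficient statistic.
  Across hundreds of replicates the mean recovered mode for a true 1.10 is
  ≈ 0.85–0.95.  This is a property of mode-reporting with few levels and a
  near-flat inverse-gamma prior, shared by the estimator convention this
  package follows, and is why recovery is asserted at ±25% for family
  components but ±10% for residuals.  HPD coverage of the generative values
  stays at the nominal 95%.

## Numerical choices and limitations

* Inverse-gamma draws guard against underflow at tiny shapes by flooring
  the underlying gamma variate at the smallest positive double.
* The KDE mode wobbles on the bandwidth scale for flat-topped posteriors;
  HPD intervals are exact given the draws.
* Single-chain diagnostics only (no Gelman–Rubin); runs are seeded and
  deterministic.
* No pedigree/animal model, no estimated cross-environment covariances
  (us-type structures), no non-Gaussian responses, no survival modelling of
  emergence failure.
* Heritability is only reported when model selection retains a family
  effect without an interaction; with an interaction present a single H²
  is not defined and per-treatment variance shares should be read from the
  summary table instead.
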