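# Methods

## The mixing model

`ventmix` implements the single-observation member of the SIAR family of
Bayesian stable-isotope mixing models. For a consumer with tissue value
X_j on isotope j ∈ {δ¹³C, δ¹⁵N} and K candidate sources:

    X_j | p ~ Normal(m_j, s_j²)
    m_j  = Σ_k p_k (μ_jk + Δ_jk)
    s_j² = Σ_k p_k² (ω_jk² + τ_jk²)
    p ~ Dirichlet(α)

* μ_jk ± ω_jk — source k's isotope distribution (mean ± SD of the measured
  pool, ‰).
* Δ_jk ± τ_jk — trophic discrimination factor (TDF): the diet-to-tissue
  isotopic shift per trophic step. TDFs are keyed by the consumer's feeding
  guild and applied to all of its sources; a per-source TDF list is accepted
  but off by default. The built-in registry carries herbivore
  (Δδ¹³C −0.41 ± 1.14‰, Δδ¹⁵N +2.52 ± 2.50‰) and carnivore
  (+0.91 ± 1.04‰, +3.23 ± 0.41‰) entries; lookups of unregistered guilds
  fail loudly.
* α — prior concentration, flat (all ones) by default. No residual-error
  term is added: each fit is to a single individual (or pooled value), and
  the mixture variance already carries the source and TDF spread.

Assumptions worth stating: sources are Gaussian and independent; proportions
are shared across isotopes (no isotope routing); the consumer integrates its
diet at steady state; TDF uncertainty enters the likelihood variance but TDF
means are known. Fitting is per-individual by default (the pipeline's
`--pooled` switch fits taxon means instead) because intra-species isotope
variation can be large — vent crabs span ~5‰ in δ¹³C — and pooling would
average away exactly the signal of interest.

With `concentration_dependent=True`, mixture weights become
p_k q_jk / Σ_k p_k q_jk for per-source elemental fractions q_jk; with equal
concentrations this reduces exactly to the plain model (tested), and it is
off by default because no concentration data are shipped.

### Sampler

The posterior is sampled by adaptive random-walk Metropolis in isometric
log-ratio (ILR) coordinates z = Vᵀ clr(p), where V is the (K, K−1) Helmert
orthonormal basis; the density transforms with the Jacobian term Σ_k log p_k.
Defaults: 500,000 total iterations split over 4 chains; per-chain burn-in
min(50 000, half the chain); thinning 15. The isotropic Gaussian proposal
scale starts at 2.38/√(K−1) and adapts toward 30% acceptance by a
Robbins–Monro recursion (step (t+10)^−0.6) during burn-in only, so the
post-burn-in chain is a valid time-homogeneous Metropolis sampler. Chains
start from independent Dirichlet(α) prior draws. All randomness flows from
one integer seed through numpy `SeedSequence`; identical seed and inputs
reproduce draws bit-for-bit.

Diagnostics recorded on every result: per-chain post-burn-in acceptance
rate, split-chain R-hat (via ArviZ) with a warning — recorded on the result,
never silent — when any component exceeds 1.05, and an out-of-polygon flag.
The flag is a per-isotope bounding-box screen (consumer outside the
[min, max] of TDF-shifted source means on either axis); a convex-hull test
would be strictly correct for K ≥ 3 but degenerates for K = 2, where the
hull is a measure-zero segment, so the box screen is used uniformly. Fits
of flagged consumers proceed — the likelihood handles them — but the
condition is surfaced.

### Verification oracles

Two independent routes guard the sampler:

* `grid_posterior_mean` enumerates the simplex lattice at a given step
  (≤ 0.02, K ≤ 4), weights nodes by the exact unnormalized posterior, and
  returns the quadrature expectation. MCMC and grid agree within 0.01 on all
  K ≤ 3 test problems, including the shipped study presets.
* `analytic_two_source_point` is the closed-form single-isotope mass balance
  f = (X − Δ − μ₂)/(μ₁ − μ₂), deliberately unclipped so out-of-interval
  consumers are visible. As all SDs shrink to 10⁻³ with a consumer exactly
  on the mixing line, the posterior mean converges to this value (tested to
  0.005).

The log density itself is unit-tested against `scipy.stats.dirichlet` +
`scipy.stats.norm`, and the hand-coded ILR pair against scikit-bio's.

One subtlety: with identical sources the likelihood is *not* constant in p —
the mixture variance Σ p_k²(ω²+τ²) is smallest at the uniform mix — but the
density is exactly symmetric under source relabeling, so posterior means
still sit at 1/K. Tests assert the symmetry, not constancy.

## Amino-acid trophic position

TL = (δ¹⁵N_Glu − δ¹⁵N_Phe − β)/(Δ_Glu − Δ_Phe) + 1, computed from
full-precision replicate means. Defaults β = +3.4‰ and Δ_Glu − Δ_Phe =
+7.6‰ are the standard aquatic-food-web constants; they are mandatory,
visible parameters rather than hidden numbers, and are validated by
recovering both shipped crab trophic positions within ±0.02. Full precision
matters at the second decimal: crab #1's replicate mean 14.1667‰ gives
TL 2.54 where the rounded printed mean 14.2 would give 2.55. The propagated
SD, sqrt(sd_Glu²/n_Glu + sd_Phe²/n_Phe)/|Δdiff|, treats the two amino acids'
replicate errors as independent; it is an extension beyond the usual
point-estimate reporting, and is `None` when either amino acid has a single
replicate.

## End-member inversion

h_j = (X_j − Δ_j − Σ_d w_d m_jd)/f, with the f = 1 pure-diet case exposed
separately. This is point algebra by design — the "simple mass balance" —
so TDF uncertainty is not propagated. The known-diet weights and f are
explicit user inputs: reconstructions of a hypothetical source under a mixed
diet depend strongly on assumed weights and the guild TDF, so the operation
exposes its assumptions rather than baking in a particular recipe. The
result flags, per isotope, reconstructions heavier or lighter than every
known diet item. Round-trip identity (inversion then forward mixing
reproduces the consumer to 1e−12) is tested across f values.

## Synthetic data and calibration

`simulate_consumers` draws tissue values from the mixing model's own
generative distribution — Normal with the mixture mean and variance above —
given true proportions. This emulates the statistical structure the
inference assumes: Gaussian sources, guild TDFs, per-individual independent
observations. It does not emulate per-prey tissue sampling, isotope routing,
spatial gradients with distance from the vent, or temporal variation in vent
chemistry, so passing recovery tests demonstrate internal consistency of the
inference machinery, not robustness to real-data violations of those
assumptions.

Seeding uses one scenario seed with counter-based `SeedSequence` substreams
per consumer, so extending a simulation never perturbs earlier rows.

The calibration scenario mirrors a favourable but realistic design: two
sources 5‰ apart on both axes with 0.3‰ SDs (comparable separation to the
seawater/vent POM pair, tighter spread), truth p = (0.7, 0.3), 100 simulated
consumers fit at 40,000 iterations each. Measured performance: |bias| < 0.01,
RMSE ≈ 0.044, 95%-CI coverage ≈ 0.95.

## Problem sizes and numerical choices

* Published-value reproductions run at the study's 500,000 iterations
  (seconds per fit); oracle-agreement and calibration tests use 40,000 to
  300,000 iterations, sized so Monte-Carlo error is well inside each
  asserted tolerance.
* Comparisons with printed tables use half-up rounding at the printed
  decimals; internal computation is full precision.
* Replicate SDs use the sample (n−1) convention — the two vent-fluid
  measurements then reproduce the printed −18.2 ± 1.1‰ summary, where the
  population convention would give ±0.8.
* A single replicate has an undefined SD, never zero; sources entering the
  mixing model must have explicit SDs (the vent POM preset carries its
  printed two-sample values).
* Grid quadrature drops boundary lattice nodes when any α ≠ 1 (the
  Dirichlet density is singular there); with the flat prior the boundary is
  finite and retained.
* Degenerate inputs fail explicitly: zero mixture variance raises rather
  than producing infinities; off-simplex points, empty replicate lists and
  unknown guilds raise named validation errors.

## Known limitations

* No hierarchical sharing across individuals (MixSIAR-style random effects
  and covariates are out of scope); each consumer is fit independently.
* Two isotopes; the data model is extensible but nothing beyond δ¹³C/δ¹⁵N
  is exercised.
* The grid oracle is exponential in K and restricted to K ≤ 4.
* Snail diet fits are qualitative: the appropriate TDF guild for
  mixed-feeding gastropods is genuinely ambiguous, so the preset applies the
  carnivore TDF and no numeric claims are attached.
* The Bayesian machinery quantifies uncertainty given the model; TDF
  misspecification — the dominant real-world error source in mixing models —
  enters only through τ, not as structural uncertainty.
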