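# ventmix

Quantitative trophic analysis of hydrothermal-vent food webs from stable
isotopes: who eats whom, and how much of the energy is chemosynthetic?

Shallow-water hydrothermal vents host food webs fed by two isotopically
distinct kinds of primary production: ordinary photosynthetic particulate
organic matter (seawater POM) and chemoautotrophic microbial biomass carried
in the vent fluids (vent POM, strongly enriched in ¹³C and depleted in ¹⁵N).
`ventmix` implements the three inference stages used to partition these
energy channels from bulk δ¹³C/δ¹⁵N and compound-specific amino-acid δ¹⁵N
data:

1. **Bayesian isotope mixing model** (SIAR-style). A consumer's tissue value
   for isotope *j* is modelled as

       X_j ~ Normal(Σ_k p_k (μ_jk + Δ_jk),  Σ_k p_k² (ω_jk² + τ_jk²))

   where *p* is the diet-proportion vector on the simplex, μ_jk ± ω_jk the
   source distributions, and Δ_jk ± τ_jk the guild-dependent trophic
   discrimination factors (TDFs). With a Dirichlet(α) prior (flat by
   default), the posterior is sampled by adaptive random-walk Metropolis on
   the isometric log-ratio transform of *p*, and cross-checked against an
   exhaustive simplex-grid quadrature oracle (`grid_posterior_mean`) for
   K ≤ 4 sources.

2. **Amino-acid trophic position.** Glutamic acid δ¹⁵N climbs steeply with
   each trophic transfer while phenylalanine δ¹⁵N barely moves, so

       TL = (δ¹⁵N_Glu − δ¹⁵N_Phe − β) / (Δ_Glu − Δ_Phe) + 1

   with the aquatic-food-web constants β = 3.4‰ and Δ_Glu − Δ_Phe = 7.6‰
   (explicit, overridable parameters) gives a baseline-free trophic level.

3. **End-member inversion.** When a consumer is isotopically outside the
   polygon of measured sources, the mass balance is solved backwards for the
   unmeasured source: h_j = (X_j − Δ_j − Σ_d w_d m_jd) / f, where the known
   diet items m_jd carry weights w_d summing to 1 − f.

A synthetic-data generator (`SimulationScenario`, `recovery_experiment`)
simulates consumers with known diet proportions so every stage is testable
without field samples, and `kst_preset()` ships the source/consumer/TDF
configuration of a shallow-water vent study system (Kueishan Island, Taiwan)
as ready-made mixing problems.

## Worked example

```python
from ventmix import fit_mixing, grid_posterior_mean, kst_preset

problem = kst_preset()["ep_crustacean_venting"]   # consumer: δ13C −19.8, δ15N +6.5
result = fit_mixing(problem, iterations=200_000, seed=1)
print(result.summary().round(3))
```

```
      source  mean    sd  q2.5   q50  q97.5
seawater POM 0.427 0.184 0.067 0.429  0.809
    vent POM 0.573 0.184 0.191 0.571  0.933
```

The posterior mean says ~57% of the venting-area epibenthic crustaceans'
diet derives from vent POM — chemosynthetic primary production — with a wide
but informative 95% credible interval (0.19–0.93); the deterministic grid
oracle gives 0.575 for the same problem, confirming the sampler. The
`examples/` directory has one short script per capability (mixing, trophic
position, inversion, simulation/recovery), each printing its numbers with a
line on what they mean.

A thin CLI mirrors the library for shell use:

```sh
ventmix preset --out data/            # emit the study CSVs
ventmix mix --sources data/sources.csv --consumers data/consumers.csv \
            --tdf data/tdf.csv --iterations 500000 --seed 1 --out results/
ventmix tl-aa --input aa_replicates.csv --beta 3.4 --delta-diff 7.6
ventmix invert --consumer "-13.9,1.1" --guild herbivore
```

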