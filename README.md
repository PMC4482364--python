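# phylobeta

Bayesian phylogenetic beta regression for bounded responses — built around
the question of which ecological and life-history traits predict the
proportional geographic-range decline of Australian rodents, and whether
those correlates differ between the tropical north and the temperate south.

The package is aimed at comparative biologists who have (a) a table of
species-by-region populations with a response in [0, 1] (here: the fraction
of the pre-European range no longer occupied) and candidate trait
predictors, and (b) a rooted phylogeny with branch lengths. It provides the
full analysis path — trait preparation, phylogenetic covariance
construction, MCMC fitting, convergence diagnostics, and report tables —
plus a synthetic-data generator so every stage can be exercised and
validated without any real data.

## The model

Each analysis taxon *i* (a species-by-region population; species straddling
the Tropic of Capricorn enter once per region) has a response
*y<sub>i</sub>* ∈ (0, 1) modelled with the mean–dispersion beta
parameterisation

> y<sub>i</sub> ~ Beta(α<sub>i</sub>, β<sub>i</sub>),  α<sub>i</sub> = μ<sub>i</sub>γ,  β<sub>i</sub> = (1 − μ<sub>i</sub>)γ,

so μ<sub>i</sub> is the mean and γ the dispersion (small γ = bathtub-shaped,
highly dispersed declines). The mean follows a logit-linear predictor

> logit(μ<sub>i</sub>) = **x**<sub>i</sub>ᵀθ + u<sub>i</sub>,

with predictors: region (NS, north = 1), log range size, log female mass,
log rainfall, habitat-openness rank (0 = grassland/shrubland … 4 =
rainforest, unstandardised), and log litter size; continuous predictors are
standardised. Two forms are fitted: main effects (7 coefficients) and
main effects plus all region-by-trait interactions (12).

The species effects carry the phylogeny:

> **u** ~ MVN(0, C<sub>λ</sub>),  C<sub>λ</sub> = λ·C off-diagonal, diag(C) on the diagonal,

where C is the phylogenetic variance–covariance matrix (C[i,j] =
root-to-MRCA branch-length distance) and λ is Pagel's phylogenetic-signal
multiplier (λ = 0: star phylogeny; λ = 1: Brownian motion). Priors:
θ<sub>j</sub> ~ N(0, 1000), λ ~ Uniform(0, 1.2), γ ~ Gamma(0.001, rate
0.001). Exact 0/1 responses are compressed with the Smithson–Verkuilen
transform y′ = (y(n−1) + 0.5)/n before fitting.

Sampling uses an adaptive Metropolis-within-Gibbs scheme (blocks: θ jointly,
each u<sub>i</sub>, log γ, λ, plus likelihood-invariant translation moves
that decouple θ from the mean of **u**), with split-chain R̂, effective
sample size, shortest-interval 95% HPD intervals and Monte Carlo standard
errors computed exactly as reported. Coefficients whose 95% HPDI excludes
zero are flagged *notable*.

## Worked example

Simulate a 61-species fauna from the generative model (true λ = 0.8,
γ = 0.5, region effect +1.22, habitat-openness effect −0.61), then fit the
main-effects model:

```python
from phylobeta import SyntheticConfig, ModelSpec, SamplerSettings
from phylobeta.synthetic_data import simulate_dataset, fit_synthetic
from phylobeta.summaries import summarize_posterior, render_table

config = SyntheticConfig(n_species=61, seed=1)
tree, table, cov = simulate_dataset(config)
chains = fit_synthetic(table, cov, ModelSpec(form="main_effects"),
                       SamplerSettings(n_chains=4, n_adapt=500,
                                       n_keep=5000, seed=1))
print(render_table(summarize_posterior(chains)[
    ["parameter", "mean", "mcse", "hpdi_low", "hpdi_high",
     "ess", "rhat", "notable"]]))
```

```
       parameter    mean   mcse hpdi_low hpdi_high       ess   rhat  notable
       Intercept -1.4742 0.0189  -3.2137    0.3430 2343.6711 1.0012    False
              NS  1.2956 0.0135   0.2965    2.2746 1393.1387 1.0019     True
       log Range  0.1292 0.0055  -0.3434    0.5829 1783.9006 1.0017    False
 log Female mass  0.0924 0.0064  -0.4163    0.5631 1522.7811 1.0036    False
    log Rainfall -0.0241 0.0068  -0.5321    0.4736 1434.8415 1.0005    False
Habitat openness -0.5761 0.0041  -0.9050   -0.2567 1666.0907 1.0013     True
      log Litter -0.1170 0.0070  -0.6373    0.4042 1448.3846 1.0014    False
           gamma  0.4468 0.0040   0.2675    0.6529  675.4433 1.0018     True
          lambda  0.6303 0.0079   0.2869    0.9520  542.1362 1.0111     True
```

Read this as a standard report table: the region effect (+1.30, HPDI
excluding zero) says declines are greater on one side of the regional
split, and the habitat-openness effect (−0.58) says taxa of more open
habitat decline more — both generating effects (1.22, −0.61) are recovered
inside their intervals, as are γ and λ. All R̂ are at 1.0, so the four
chains agree and the concatenated 20 000 draws are usable for inference.

The same analysis runs from files via the CLI:

```sh
phylobeta simulate --seed 1 --out data/
phylobeta fit --traits data/traits.csv --tree data/tree.nwk \
    --model both --chains 4 --iter 5000 --warmup 500 --seed 1 --out run/
phylobeta tabulate --traits data/traits.csv --out run/
```

`run/` then holds chain CSVs, posterior summary tables for both model
forms, region-by-decline-category tabulations, per-genus decline incidence,
regional body-mass descriptives, and a manifest recording the seed, config
hash and convergence verdict.

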