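# Methods

This note documents the model, the numerical and design choices behind the
implementation, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Model and assumptions

The response is a proportion in [0, 1] (proportional geographic-range
decline) observed once per analysis taxon, where an analysis taxon is a
species-by-region population: a species whose range centroid falls on both
sides of the regional split (the Tropic of Capricorn, −23.43665°; a
centroid exactly on the line counts as south) contributes one northern and
one southern taxon with their own trait values.

The likelihood is beta in the mean–dispersion parameterisation,
Beta(μγ, (1−μ)γ), with a logit link: logit(μᵢ) = xᵢᵀθ + uᵢ. The model
assumes a single dispersion γ for all taxa and no zero/one inflation; exact
0/1 observations are handled by transformation, not by a mixture (see
below). Species effects u are multivariate normal with covariance
C_λ — the phylogenetic VCV with off-diagonals scaled by Pagel's λ —
which assumes residual (off-predictor) variation on the logit scale
accumulated along the phylogeny under Brownian motion, attenuated by λ.
The species-effect prior carries **no free scale multiplier**: its
magnitude is fixed by the tree's branch-length units. An optional
depth-normalisation (`normalize_depth`) divides C by its mean root-to-tip
depth; it is off by default, so tree units directly set the random-effect
scale (a deliberate, documented trade-off — see Limitations).

Two fixed-effect forms are supported: main effects (intercept, region
indicator NS with north = 1, standardised natural logs of range, female
mass, rainfall and litter size, and the raw habitat-openness rank 0–4) and
the same plus all five NS-by-trait interactions. Both are fitted from one
`PreparedData` object so standardisation constants are shared.

## Priors and parameterisation choices

* θⱼ ~ Normal(0, sd 1000): effectively flat at the scale of standardised
  predictors.
* λ ~ Uniform(0, 1.2). For λ in (1, 1.2] the transformed covariance can
  lose positive definiteness; such states get log-posterior −∞ (the
  Cholesky factorisation fails and the proposal is rejected), which keeps
  the multivariate-normal density defined without truncating the prior.
* γ ~ Gamma(shape 0.001, **rate** 0.001) by default — a diffuse prior with
  unit mean. A shape–scale reading of the same constants (mean 10⁻⁶) is
  available via `gamma_prior_parameterization="scale"`; the shape–rate
  convention is the default because it is the convention of the HMC
  software family this model class is usually fitted with, and the
  shape–scale reading concentrates implausibly at zero.

## Handling boundary responses

Beta support is the open interval, but real decline data contain exact
zeros (stable species) and occasionally ones. The default treatment is the
Smithson–Verkuilen compression y′ = (y(n−1) + 0.5)/n with n the number of
analysis taxa; a fixed ε-clamp (1e−4) is available. A third rule, `none`,
passes responses through untouched and refuses boundary values. Synthetic
fits use `none`: simulated beta draws are already strictly inside (0, 1),
and compressing them onto shared boundary values creates point masses that
open a spurious high-γ posterior mode (a beta spike can fit identical
values exactly, so the dispersion runs away). This is a real property of
the squeezed model worth knowing about when interpreting fits to data with
many tied boundary values.

## Sampler

`fit_model` is an adaptive Metropolis-within-Gibbs sampler with four block
types per iteration:

1. **θ jointly** — random-walk with per-coordinate scales tracked by a
   running (Welford) variance and a global scale adapted toward acceptance
   0.234;
2. **u element-wise** — single-coordinate random walks; the beta
   likelihood factorises per taxon, and with the precision matrix
   Q = C_λ⁻¹ cached the prior change for one coordinate is O(n), so a full
   sweep is O(n²);
3. **log γ** — scalar random walk with the log-scale Jacobian;
4. **λ** — scalar random walk; each proposal recomputes the Cholesky
   factor, log-determinant and precision of C_λ (O(n³), trivial at n ≲ 100).

In addition, **translation moves** shift θⱼ by δ while moving u by
−δ·X[:, j]. The linear predictor is invariant, so only the priors enter the
acceptance ratio. Without these moves the intercept and the mean of u — an
almost unidentified direction — mix very poorly (split R̂ ≈ 2 at default
settings); with them all parameters reach R̂ ≈ 1.00 at 4 × (500 + 5000)
iterations.

All proposal scales adapt only during the discarded warmup phase
(Robbins–Monro, step c·t^(−0.6)), so kept draws form a valid Markov chain.
Per-chain RNG streams are spawned deterministically from one master seed;
identical seeds give bit-identical chains. `run_chains` exposes the same
contract for an arbitrary log density (joint adaptive random-walk
Metropolis) and is what the analytic-target calibration checks exercise.

Default chain geometry is desk-scale: 4 chains × (500 warmup + 5000 kept),
i.e. 20 000 inference draws after concatenation. The study-scale protocol
(4 × (1000 + 50 000)) is a configuration choice; all package results and
tests use the desk scale, which the recovery experiments show is sufficient
for calibrated coverage at faunas of 60–75 taxa.

## Diagnostics

* **Split-chain R̂**: each chain halved, R̂ = sqrt(((n−1)/n·W + B/n)/W)
  over the split halves; detects within-chain trend that the unsplit
  statistic misses. Undefined (NaN with a warning) when every half is
  constant.
* **ESS**: n / (1 + 2Σρₖ) with autocorrelations (biased, n-denominator,
  FFT-computed) summed until the first lag where ρₖ + ρₖ₊₁ ≤ 0; capped at
  n; a constant chain reports 1. On a single finite chain this estimator
  carries ~5% noise, which the tests accommodate by checking its typical
  value.
* **95% HPDI**: shortest contiguous window over the sorted draws containing
  ⌈0.95 n⌉ of them; ties break toward the lower start index.
* **MCSE**: sd/√ESS. The summary tables report MCSE in the "SE" position
  (its magnitude, ~10⁻²–10⁻³ of the posterior sd scale, is what report
  tables of this kind print) alongside the posterior sd.

Inference is based on the chains concatenated into a single sequence after
diagnostics pass. γ and λ are always-reported rows in the summary and are
flagged as model parameters; an exclude-zero test is meaningless for
positive-support parameters, so the *notable* flag proper applies only to
coefficients.

## Synthetic-data generator

The generator draws a pure-birth (Yule) tree (from 2 lineages, waiting
Exp(k·birth_rate), uniform lineage splits, plus a final Exp(n·birth_rate)
hold so the expected depth is Σ_{k=2..n} 1/(k·b); ultrametric by
construction), log-normal continuous traits (median range ~1.6e5 km²,
mass ~100 g, rainfall ~500 mm, litter ~3.5), a categorical habitat rank
skewed toward open habitats, region by fair coin with straddling
probability 8/61 (straddlers duplicated as separate taxa on the same tip),
genus labels as the maximal clades below half the tree height, and
responses from the model itself: u ~ MVN(0, C_λ), y ~ Beta(μγ, (1−μ)γ).

Default generating values are a 61-species fauna with coefficients
(−1.66, 1.22, −0.45, 0.28, −0.19, −0.61, −0.01), γ = 0.5 and λ = 0.8 —
magnitudes chosen to echo a realistic fitted main-effects model so test
signal-to-noise resembles a real comparative analysis. They are demo
defaults, not claims about any fauna.

At γ = 0.5 the beta tails are so heavy that a double-precision response
loses them: P(1 − y < 10⁻¹⁶) exceeds 10%, and a float simply cannot
represent log(1−y) below ≈ −36.7. Responses are therefore drawn in log
space via the two-gamma construction (y = G_a/(G_a+G_b), with
G_a = G_{a+1}·U^{1/a} for small shapes evaluated in logs), and the exact
log y and log(1−y) accompany the table into the likelihood
(`fit_model(..., response_logs=...)`). Truncating instead of carrying the
exact tails measurably attenuates coefficient recovery.

**What the generator does not emulate**: exact-zero declines (real stable
species), measurement rounding, trait measurement error, correlations
among predictors, phylogenetic structure in the predictors themselves
(only the species effects are tree-structured, matching the fitted model),
and non-ultrametric trees. Passing recovery tests therefore demonstrate
that the inference machinery is correct and calibrated when the model is
true — not that the model is adequate for any particular empirical
dataset.

## Numerical choices

* PSD tolerance: a covariance is accepted when its smallest eigenvalue is
  ≥ −10⁻⁸ × trace(C); MVN densities go through Cholesky, and factorisation
  failure means log-density −∞.
* Duplicate-taxon covariance: two populations on one tip are sister
  lineages of zero divergence — base between-taxon covariance equal to the
  tip's full root-to-tip depth, scaled by λ like every off-diagonal. At
  λ = 1 exactly, duplicated rows make C_λ singular; that single point has
  posterior density −∞ and measure zero under the continuous λ prior.
* Decline categories partition [0, 1] as None = {0}, Low = (0, 0.25],
  Moderate = (0.25, 0.50], High = (0.50, 1] — the contiguous half-open
  reading of the conventional <25% / 26–50% / >50% labels.
* Standardisation uses the sample (n−1) standard deviation; the habitat
  rank is left unstandardised.
* Missing required predictors cause listwise deletion with the dropped
  taxa logged; no imputation.
* Newick dialect: branch lengths required on all non-root edges; a root
  edge length or internal node labels are ignored with a warning.

## Limitations

* Branch-length units are not identified separately from the species-effect
  variance: doubling tree depth doubles the prior variance of u. λ is
  unit-free, but the magnitude of u (and hence how much decline variation
  is attributed to phylogeny) depends on the input tree's scale. The
  `normalize_depth` option makes runs comparable across trees.
* Species effects are sampled, not marginalised (the beta likelihood
  admits no closed-form marginalisation), so the sampler's performance
  degrades with the number of taxa roughly as O(n²) per iteration.
* Fits to data with many identical boundary-squeezed responses can exhibit
  the degenerate high-γ mode described above; inspect the γ chain before
  trusting such fits.
* The random-walk sampler is adequate at comparative-analysis scale
  (tens to low hundreds of taxa); it is not an HMC replacement for large n.
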