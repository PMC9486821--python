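# Methods

`occomm` implements a complete analysis chain for multi-species camera-trap
surveys in a two-stratum forest landscape: natural forest management (NFM)
areas versus licensed planted *Acacia* forest (LPF), surveyed at two forest
management units (FMUs, "Pasin" and "Raplex"). This note records the model,
the data conventions, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Detection histories and effort

Daily records from the two cameras at each station are pooled and condensed
into 5-day occasions anchored at each station's own deployment start (the
two sites were surveyed in different years, so calendar alignment across
stations would be meaningless). A trailing partial occasion is retained;
the effort covariate absorbs its shorter duration. Effort is the number of
functional camera-days in the occasion (0–10 with two cameras); occasions
with zero effort yield *missing* detection cells, never zeros.

Species enter the analysis if they have at least 5 independent records and
are not on a configurable exclusion list (arboreal, reptile and small-mammal
taxa poorly sampled by ground-level cameras, and wide-ranging species that
violate the closure assumption). Records of one species at one station
closer together than 30 minutes count as a single independent event; the
interval is a convention of the camera-trap literature and is configurable.

## Habitat covariates

Four station covariates drive occupancy: a remote-sensed structural
conditions index (SCI, 1–18, higher = less degraded forest), distance to
the nearest access feature (logging road, skid trail or large river),
elevation, and a terrain ruggedness index (TRI). The module computes

* **TRI** as the mean absolute elevation difference between a focal raster
  cell and every other cell of a 3×3 (or 7×7) window, with edge cells using
  the neighbours that exist;
* **village density** as an unnormalized quartic kernel sum,
  `K(d/r) = (1 − (d/r)²)²` within `r = 15 km`. The kernel's global constant
  is deliberately omitted: covariates are z-scored before modelling, so any
  constant factor cancels;
* **distance to access** as the planar minimum distance to a set of shapely
  point/line features (segments treated as continuous). All geometry is
  planar — coordinates must be projected to metres first.

Covariates are z-scaled (mean 0, variance 1) over the modelled stations,
both sites pooled; the scaling constants are stored and re-applied to
prediction grids, and a signature check refuses grids scaled with different
constants. Collinearity screening uses Spearman rank correlation (midrank
ties) with |rho| > 0.7 flagging a pair; of a flagged pair the member whose
single-covariate community fit gives more species with strong support is
retained (ties: more moderate support, then alphabetical).

## The community occupancy model

For species *i*, station *j*, occasion *k*:

    z_ij ~ Bernoulli(psi_ij),  logit psi_ij = beta0_{i, lu(j)} + beta_i' x_j
    y_ijk | z_ij ~ Bernoulli(z_ij p_ijk),
    logit p_ijk = alpha0_{i, fmu(j)} + alpha_eff * e_jk + alpha_road_i * road_j

Species-level parameters are draws from community distributions: occupancy
intercepts have landuse-specific hypermeans/SDs (different baseline
occupancy in NFM vs LPF), covariate slopes have per-covariate community
hypermeans/SDs, detection intercepts have FMU-specific hypermeans/SDs
(the sites were surveyed in different years), and the road effect has one
community distribution. The effort coefficient is a single fixed effect
shared across species.

**Effort scale.** Effort enters detection raw, in functional camera-days
(0–10), and coefficients are reported on that scale with intercepts at
effort 0. Reported community detection intercepts near −5 on the logit
scale therefore correspond to a per-occasion detection probability around
0.05 at full effort (10 camera-days) — the regime typical of this kind of
survey. Internally the sampler mean-centres effort to decorrelate the
intercept from the effort coefficient, and un-centres at reporting time.
With constant effort, only the centred intercept is identified; the
reporting shift then adds prior-driven spread to the raw-scale intercept,
which tests account for by comparing the centred combination.

**Priors** (configurable): hypermeans ~ Normal(0, 1.5²) on the logit scale,
hyper-SDs ~ half-Normal(1), effort coefficient ~ Normal(0, 1.5²). These are
the weakly-informative defaults standard for hierarchical occupancy models.

### Sampler

The latent occupancy states are marginalized out of the likelihood: for a
history with a detection the contribution is `psi * prod Bern(y|p)`, for an
all-zero history `psi * prod(1-p) + (1-psi)`; zero-effort occasions
contribute nothing (verified bitwise in tests). MCMC is a cycle of:

1. vectorized adaptive random-walk Metropolis across species for each
   species-level block (occupancy intercepts per landuse, slopes per
   covariate, detection intercepts per FMU, road effects), with per-scalar
   step sizes adapted toward 0.44 acceptance during burn-in only;
2. a scalar random-walk update for the effort coefficient;
3. conjugate Gibbs updates for hypermeans and log-scale random-walk updates
   for hyper-SDs;
4. *interweaved (non-centred) joint moves* per hyper-group — translate
   (mu, all species values) and rescale (sd, all species deviations)
   proposals. Without these the centred parameterization suffers the
   classic hierarchical funnel when species-level data are weak (notably
   the LPF intercepts, informed by only ~43 stations at low detection
   probability): the hyper-SD gets trapped near zero and species intervals
   are overshrunk. With them, R-hat for all parameters is typically < 1.05
   at desk-scale chain lengths and hyper-SDs are recovered.

`z` is re-sampled from its full conditional at each saved draw (forced to 1
wherever the species was detected). Initialization retries up to 10 times
on a non-finite log-density. Two MCMC profiles are named in the pipeline:
`full` (3 chains × 300,000 iterations, 50,000 burn-in, thin 20 — the full
field protocol) and `desk` (3 × 6,000, 2,000 burn-in, thin 2), the default
for synthetic work.

Convergence is monitored with the classic Gelman–Rubin potential scale
reduction factor; parameters with R-hat ≥ 1.1 are flagged, and zero-variance
cases report NaN (undefined, not converged). Posterior summaries use
percentile credible intervals, with *strong* support when the 95% interval
(2.5–97.5) excludes zero and *moderate* when only the 75% interval
(12.5–87.5) does.

## Landscape prediction and metrics

Predictions use the occupancy half of the model only (detection parameters
never enter; percent area occupied is a state quantity). For every 20th
pooled posterior sample, per-cell occupancy probability is computed from the
cell's landuse intercept and scaled covariates; one Bernoulli occupancy
state is drawn per cell × species × sample. Percent area occupied (PAO) is
100 × the occupied cell fraction per landuse; per-cell richness is the sum
of states over species (an expected-richness variant that sums psi directly
is available behind a flag). Summaries are means/SDs/95% intervals over
samples. Large grids stream sample-by-sample; nothing larger than one
(species × cells) slice is held in memory.

Community metrics operate on mean predicted occupancy per landuse, computed
per posterior sample so the full posterior of each metric propagates:

* **defaunation index** `D = sum w_i (ref_i − foc_i) / sum w_i (ref_i + foc_i)`
  with NFM the reference; range [−1, 1], positive = occupancy lost in LPF.
  Weights default to 1 (body-mass weighting is supported via `weights` but
  not parameterized from trait data).
* **Hill diversity** `D_q = (sum p_i^q)^{1/(1−q)}` with occupancy as the
  abundance proxy, normalized within each landuse; `D_1` uses the
  exponential-Shannon continuity limit, computed in log space for
  robustness to extreme occupancy ratios. Profiles over a q grid
  (default 0–4 by 0.1, markers at 0/1/2) report per-q posterior mean/SD and
  the evenness diagnostic `D_2/D_0`. Naive (identity) similarity is used
  throughout, i.e. classic Hill numbers. A subset variant restricts both
  metrics to flagged threatened/endemic species.

## Synthetic-data generator

The generator is the exact probabilistic inverse of the model, so ingestion
and fitting can be validated end-to-end without field data. Default
conditions mirror the target study design: 142 stations (79 Pasin / 63
Raplex; 99 NFM / 43 LPF), 25 species with 15 flagged threatened/endemic,
5-day occasions, two cameras per station, and a prediction landscape that is
84.6% NFM. Parameter defaults are anchored to the study's community-level
values: detection hypermeans −5.21 (Pasin) and −4.93 (Raplex) logits with
SD 1, effort coefficient 0.20 per camera-day, road effect ~ N(0.2, 0.5²),
SCI slope ~ N(0.25, 0.4²) (the one covariate with a clear community-level
association) and the remaining slopes ~ N(0, 0.3²). Occupancy hypermeans
(1.257 NFM, 0.936 LPF, SD 1) were solved analytically so that
`E[inv_logit(mu + sigma Z)]` — the expected per-cell occupancy over species
and cells, with `sigma²` the total linear-predictor variance — equals the
study's per-cell richness fractions (18.18/25 and 16.85/25). The implied
defaunation index is ~0.04–0.05, matching the study's scale.

Camera failures combine a transient per-camera per-day failure (default
0.02) with a per-day permanent-death hazard (default 0.01); only the
persistent mechanism produces whole occasions with zero effort, which is
what real camera failures do. Deployment length defaults to 12 occasions
(60 days, the study's minimum deployment).

The generator does **not** emulate: spatial autocorrelation in occupancy,
animal movement or home ranges, temporal activity patterns, covariate
collinearity (synthetic covariates are independent by default, so the
screening stage typically reports no pairs), species misidentification, or
unequal deployment lengths across stations. Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to their violation in field data.

## Validation scales and numerical choices

* Likelihood correctness is proven by exhaustive comparison with
  latent-state enumeration on all instance sizes ≤ 3 species × 4 stations ×
  3 occasions at 1e-12 absolute tolerance.
* A single-species intercept-only posterior is checked against dense 2-D
  grid integration (601 × 651 grid) within Monte-Carlo standard error.
* Parameter recovery runs 20 replicate surveys at the full study dimensions
  (25 × 142 × 12) with shortened chains (2 × 2,000, 800 burn-in), asserting
  hypermeans within 3 posterior SDs of truth (≥95% of checks, the nominal
  exceedance being ~0.3%) and pooled 95%-interval coverage of species
  occupancy intercepts in [0.85, 1.0]. Chain lengths here trade precision
  for replicate count; single longer fits give the same picture.
* The acceptance script runs the desk profile on the default conditions
  with a 20,000-cell grid — large enough that binomial noise on PAO and
  richness is well under a percent.
* Ties in covariate retention are broken deterministically (documented
  above); scale/unscale round-trips are exact to 1e-10; Hill-number
  continuity at q = 1 holds to 1e-4 at epsilon = 1e-6.

## Known limitations

* The sampler is single-threaded numpy; the `full` MCMC profile
  (900,000 total iterations) is supported but takes hours, not minutes.
* Covariate slopes are hierarchical (community mean/SD per covariate);
  an independent-fixed-effects variant is not implemented. The community
  reporting of covariate associations presumes the hierarchical reading.
* Detection-intercept identifiability on the raw effort scale degrades as
  effort variance shrinks (see "Effort scale" above); this is a property of
  the parameterization, reported honestly through wider intervals.
* No goodness-of-fit machinery (posterior predictive checks, WAIC) and no
  spatial random effects.
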