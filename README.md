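# occomm — community occupancy analysis for two-landuse camera-trap surveys

`occomm` is a Python library for asking how a terrestrial wildlife
community responds to land-use strata within a managed tropical forest
landscape — specifically, natural forest management (NFM) areas versus
licensed planted (*Acacia*) forest (LPF), surveyed with paired camera traps
at two forest management units. It takes raw camera-trap record and
deployment tables and carries them through to landscape-level biodiversity
summaries with full posterior uncertainty.

## What it computes

At its core is a Bayesian **community occupancy model**. For species *i*,
station *j*, occasion *k*:

```
z_ij  ~ Bernoulli(ψ_ij)          logit ψ_ij  = β0_{i,lu(j)} + β_i' x_j
y_ijk ~ Bernoulli(z_ij · p_ijk)  logit p_ijk = α0_{i,fmu(j)} + α_eff e_jk + α_road,i road_j
```

Species-level intercepts and slopes are draws from community
hyperdistributions (landuse-specific for occupancy, survey-site-specific
for detection), so rare species borrow strength from data-rich ones.
Detection accounts for effort `e_jk` (functional camera-days per 5-day
occasion, 0–10 with two cameras) and on-/off-road camera placement. The
latent states `z` are marginalized out of the likelihood; inference is a
hand-rolled vectorized adaptive MCMC with conjugate hypermean updates and
interweaved non-centred moves (see `docs/methods.md`).

From the fitted model the package derives:

* **PAO** — percent area occupied per species and landuse, via Bernoulli
  draws on per-cell predicted occupancy for every 20th posterior sample;
* **per-cell species richness** maps and landuse averages;
* the occupancy-based **defaunation index**
  `D = Σ(ref_i − foc_i) / Σ(ref_i + foc_i)` (NFM as reference; −1…1);
* **Hill-number diversity profiles** `D_q` over orders q = 0…4 (richness,
  exponential Shannon, inverse Simpson at q = 0, 1, 2), with a separate set
  of metrics for threatened/endemic species.

A synthetic-survey generator (`occomm.synthetic`) is the model's exact
probabilistic inverse and ships first-class: every downstream stage is
testable against known truth without any field data.

## Worked example

```python
from occomm import *

truth  = simulate_truth(default_hyper(), n_species=25, seed=1)
design = default_design(seed=1)           # 142 stations, 2 sites, 12 occasions
sim    = simulate_survey(truth, design, seed=1)

spec = ModelSpec(
    landuse=design.stations["landuse"].to_numpy(),
    fmu=design.stations["fmu"].to_numpy(),
    road=design.stations["road"].to_numpy(),
    covariates=design.stations[list(design.covariate_names)],
)
draws = fit(spec, sim.detections, sim.effort, MCMCConfig.desk_profile(seed=1))
print(summarize(draws, parameters=["alpha_eff", "mu_alpha0"]))
```

which prints (posterior mean, SD, 95% and 75% credible intervals, support):

```
        parameter   mean    sd   q2.5  q97.5  q12.5  q87.5 support sign
        alpha_eff  0.196 0.015  0.166  0.225  0.178  0.214  strong    +
 mu_alpha0[Pasin] -5.773 0.222 -6.212 -5.345 -6.024 -5.518  strong    -
mu_alpha0[Raplex] -4.565 0.257 -5.056 -4.052 -4.858 -4.275  strong    -
```

The effort coefficient (0.196 per camera-day) sits on the generator's true
value of 0.20; the community detection intercepts (−5.8/−4.6 logits at
effort 0, i.e. per-occasion detection probability around 0.05 at full
effort) scatter around the hypermean truth (−5.21, −4.93) as expected for
one 25-species realization. The `examples/` directory walks through each
capability — simulation, ingestion, covariate screening, fitting,
prediction, metrics, full pipeline — as short narrative scripts.

An end-to-end run is one command:

```bash
occomm run --seed 1 --outdir my_run            # or: python -m occomm.cli ...
occomm run --seed 1 --outdir my_run --stages simulate,ingest,fit
```

Each run writes a manifest (config, versions, seeds), a JSON-lines log
(retained species, dropped records, screening report), posterior and
summary tables, richness/PAO/defaunation/diversity outputs and report
plots. Identical configs reproduce identical artifacts.

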