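"""End-to-end pipeline: simulate | ingest | covariates | fit | predict | metrics | report.

Each stage reads only files written by earlier stages (or, for ``simulate``,
nothing), writes its artifacts under ``outdir``, and appends a structured
JSON-lines log entry.  A manifest capturing the full configuration, seeds
and package versions is written on every run, and all randomness flows from
the single config seed through named substreams.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from pydantic import BaseModel, Field, field_validator

import occomm
from occomm import covariates as cov
from occomm import metrics as met
from occomm import model as mod
from occomm import predict as pred
from occomm import survey as surv
from occomm import synthetic as syn

log = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "covariates", "fit", "predict", "metrics", "report")


class RunConfig(BaseModel):
    """Validated configuration for a pipeline run."""

    seed: int = 0
    outdir: str = "occomm_run"
    # survey design
    n_species: int = Field(25, ge=1)
    n_stations: int = Field(142, ge=2)
    n_occasions: int = Field(12, ge=1)
    occasion_length: int = Field(5, ge=1)
    failure_prob: float = Field(0.05, ge=0.0, le=1.0)
    covariates: list[str] = list(syn.DEFAULT_COVARIATES)
    # species filter
    min_detections: int = Field(5, ge=0)
    exclusion_list: list[str] = []
    independence_minutes: float = Field(30.0, ge=0.0)
    # model
    profile: str = "desk"
    chains: int | None = None
    iterations: int | None = None
    burn_in: int | None = None
    thin: int | None = None
    hypermean_sd: float = Field(1.5, gt=0)
    hypersd_scale: float = Field(1.0, gt=0)
    effort_sd: float = Field(1.5, gt=0)
    # prediction
    n_cells: int = Field(20000, ge=1)
    sample_stride: int = Field(20, ge=1)
    q_max: float = Field(4.0, gt=0)
    q_step: float = Field(0.1, gt=0)

    @field_validator("profile")
    @classmethod
    def _known_profile(cls, v):
        if v not in ("desk", "full"):
            raise ValueError("profile must be 'desk' or 'full'")
        return v

    def mcmc_config(self) -> mod.MCMCConfig:
        base = (
            mod.MCMCConfig.full_profile(self.seed)
            if self.profile == "full"
            else mod.MCMCConfig.desk_profile(self.seed)
        )
        for attr in ("chains", "iterations", "burn_in", "thin"):
            v = getattr(self, attr)
            if v is not None:
                setattr(base, attr, v)
        base.validate()
        return base

    def priors(self) -> mod.Priors:
        return mod.Priors(self.hypermean_sd, self.hypersd_scale, self.effort_sd)

    def q_grid(self) -> np.ndarray:
        return np.round(np.arange(0.0, self.q_max + 1e-9, self.q_step), 10)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _log_event(outdir: Path, stage: str, **fields):
    entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **fields}
    with (outdir / "run_log.jsonl").open("a") as fh:
        fh.write(json.dumps(entry) + "\n")
    log.info("stage %s: %s", stage, fields)


def _require(path: Path, producing_stage: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}; run the '{producing_stage}' stage first"
        )
    return path


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (all, by default) and return the output dir."""
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_manifest(config, out)
    runners = {
        "simulate": stage_simulate,
        "ingest": stage_ingest,
        "covariates": stage_covariates,
        "fit": stage_fit,
        "predict": stage_predict,
        "metrics": stage_metrics,
        "report": stage_report,
    }
    for s in stages:
        runners[s](config, out)
    return out


def _write_manifest(config: RunConfig, out: Path):
    manifest = {
        "config": config.model_dump(),
        "versions": {"occomm": occomm.__version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "xarray": xr.__version__},
        "mcmc": vars(config.mcmc_config()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def stage_simulate(config: RunConfig, out: Path):
    truth = syn.simulate_truth(syn.default_hyper(), config.n_species, config.seed)
    design = syn.default_design(
        n_stations=config.n_stations,
        n_occasions=config.n_occasions,
        occasion_length=config.occasion_length,
        failure_prob=config.failure_prob,
        covariate_names=tuple(config.covariates),
        seed=config.seed,
    )
    sim = syn.simulate_survey(truth, design, config.seed)
    simdir = out / "sim"
    syn.write_survey_csvs(sim, simdir)
    _log_event(
        out, "simulate",
        n_species=truth.n_species, n_stations=len(design.stations),
        n_records=len(sim.records),
    )


def stage_ingest(config: RunConfig, out: Path):
    simdir = out / "sim"
    records = pd.read_csv(_require(simdir / "records.csv", "simulate"))
    stations = pd.read_csv(_require(simdir / "stations.csv", "simulate"))
    functionality = pd.read_csv(_require(simdir / "functionality.csv", "simulate"))

    filtered, report = surv.filter_species(
        records,
        min_detections=config.min_detections,
        exclusion_list=tuple(config.exclusion_list),
        independence_minutes=config.independence_minutes,
    )
    effort = surv.build_effort(functionality, stations, config.occasion_length)
    detections = surv.build_detection_history(
        filtered, stations, effort, config.occasion_length
    )
    ingdir = out / "ingest"
    ingdir.mkdir(exist_ok=True)
    report.to_csv(ingdir / "species_filter_report.csv", index=False)
    effort.to_dataset(name="effort").to_netcdf(ingdir / "effort.nc", engine="scipy")
    detections.to_dataset(name="detections").to_netcdf(
        ingdir / "detections.nc", engine="scipy"
    )
    # Wide CSV: one block of occasion columns per species.
    wide = detections.to_dataframe().reset_index().pivot_table(
        index=["species", "station"], columns="occasion", values="detections",
        dropna=False,
    )
    wide.to_csv(ingdir / "detections_wide.csv")
    _log_event(
        out, "ingest",
        retained_species=report.loc[report["retained"], "species"].tolist(),
        n_dropped_records=int(detections.attrs.get("n_dropped_records", 0)),
        total_effort=int(effort.values.sum()),
    )


def stage_covariates(config: RunConfig, out: Path):
    stations = pd.read_csv(_require(out / "sim" / "stations.csv", "simulate"))
    scaler = cov.Scaler.fit(stations, config.covariates)
    scaled = scaler.transform(stations)
    flagged = cov.spearman_screen(stations[config.covariates])
    covdir = out / "covariates"
    covdir.mkdir(exist_ok=True)
    scaler.to_json(covdir / "scaler.json")
    scaled.to_csv(covdir / "stations_scaled.csv", index=False)
    pd.DataFrame(flagged, columns=["covariate_a", "covariate_b", "rho"]).to_csv(
        covdir / "correlated_pairs.csv", index=False
    )
    _log_event(out, "covariates", n_correlated_pairs=len(flagged))


def stage_fit(config: RunConfig, out: Path):
    stations = pd.read_csv(
        _require(out / "covariates" / "stations_scaled.csv", "covariates")
    )
    scaler = cov.Scaler.from_json(out / "covariates" / "scaler.json")
    detections = xr.open_dataset(
        _require(out / "ingest" / "detections.nc", "ingest"), engine="scipy"
    )["detections"]
    effort = xr.open_dataset(out / "ingest" / "effort.nc", engine="scipy")["effort"]
    spec = mod.ModelSpec(
        landuse=stations["landuse"].to_numpy(),
        fmu=stations["fmu"].to_numpy(),
        road=stations["road"].to_numpy(),
        covariates=stations[config.covariates],
        priors=config.priors(),
        scaler_signature=scaler.signature(),
    )
    draws = mod.fit(spec, detections, effort, config.mcmc_config())
    draws.attrs["scaler_signature"] = scaler.signature()
    fitdir = out / "fit"
    fitdir.mkdir(exist_ok=True)
    enc = {v: {"dtype": "int8"} for v in ["z"]}
    draws_to_disk = draws.copy()
    draws_to_disk.attrs = {
        k: v for k, v in draws.attrs.items() if isinstance(v, (int, float, str))
    }
    draws_to_disk.to_netcdf(fitdir / "posterior.nc", engine="scipy", encoding=enc)
    mod.summarize(draws).to_csv(fitdir / "summary.csv", index=False)
    conv = mod.convergence_report(draws)
    conv.to_csv(fitdir / "convergence.csv", index=False)
    _log_event(
        out, "fit",
        max_rhat=float(np.nanmax(conv["rhat"])),
        n_flagged=int(conv["flagged"].sum()),
    )


def _load_fit(out: Path):
    draws = xr.open_dataset(_require(out / "fit" / "posterior.nc", "fit"), engine="scipy")
    scaler = cov.Scaler.from_json(_require(out / "covariates" / "scaler.json", "covariates"))
    return draws, scaler


def _make_grid(config: RunConfig, scaler: cov.Scaler) -> pred.PredictionGrid:
    # Grid covariates are simulated on the raw station scale by reusing the
    # station generator's population, then scaled with the training scaler.
    raw = syn.simulate_prediction_grid(
        n_cells=config.n_cells,
        covariate_names=tuple(config.covariates),
        seed=config.seed,
    )
    unscaled = raw.copy()
    for c in config.covariates:
        unscaled[c] = raw[c] * scaler.sds[c] + scaler.means[c]
    scaled = scaler.transform(unscaled)
    return pred.PredictionGrid(
        cells=scaled,
        covariate_names=list(config.covariates),
        scaler_signature=scaler.signature(),
    )


def stage_predict(config: RunConfig, out: Path):
    draws, scaler = _load_fit(out)
    grid = _make_grid(config, scaler)
    pdir = out / "predict"
    pdir.mkdir(exist_ok=True)
    grid.cells.to_csv(pdir / "grid.csv", index=False)
    pao_tab = pred.pao(draws, grid, config.sample_stride, config.seed)
    pao_tab.to_csv(pdir / "pao.csv", index=False)
    rich = pred.richness(draws, grid, config.sample_stride, config.seed)
    rich.to_netcdf(pdir / "richness.nc", engine="scipy")
    rich[["landuse_mean", "landuse_sd"]].to_dataframe().to_csv(
        pdir / "richness_landuse.csv"
    )
    truth = syn.CommunityTruth.from_json(_require(out / "sim" / "truth.json", "simulate"))
    retained = list(draws.coords["species"].values)
    flags = {sp: bool(f) for sp, f in zip(truth.species, truth.flags)}
    subset = [sp for sp in retained if flags.get(sp, False)]
    if subset:
        rich_sub = pred.richness(
            draws, grid, config.sample_stride, config.seed, species_subset=subset
        )
        rich_sub[["landuse_mean", "landuse_sd"]].to_dataframe().to_csv(
            pdir / "richness_landuse_subset.csv"
        )
    _log_event(
        out, "predict",
        n_cells=grid.n_cells,
        richness_nfm=float(rich["landuse_mean"].sel(landuse="NFM")),
        richness_lpf=float(rich["landuse_mean"].sel(landuse="LPF")),
    )


def stage_metrics(config: RunConfig, out: Path):
    draws, scaler = _load_fit(out)
    grid = _make_grid(config, scaler)
    # stream psi samples: only the per-landuse cell means are kept
    lu_idx = grid.landuse_idx
    masks = {lu: lu_idx == l for l, lu in enumerate(("NFM", "LPF"))}
    occ_rows = {lu: [] for lu in masks}
    for _, psi in pred.psi_sample_iter(draws, grid, config.sample_stride):
        for lu, m in masks.items():
            occ_rows[lu].append(psi[:, m].mean(axis=1))
    occ = {lu: np.array(rows) for lu, rows in occ_rows.items()}
    truth = syn.CommunityTruth.from_json(_require(out / "sim" / "truth.json", "simulate"))
    retained = list(draws.coords["species"].values)
    flag_map = {sp: bool(f) for sp, f in zip(truth.species, truth.flags)}
    flags = np.array([flag_map.get(sp, False) for sp in retained])

    q_grid = config.q_grid()
    mdir = out / "metrics"
    mdir.mkdir(exist_ok=True)
    defa = met.defaunation_posterior(occ["NFM"], occ["LPF"])
    rows = [("full", defa.mean, defa.sd, defa.q2_5, defa.q97_5)]
    np.savetxt(mdir / "defaunation_samples_full.csv", defa.samples, header="index")
    profiles = {}
    for lu in ("NFM", "LPF"):
        profiles[f"full_{lu}"] = met.diversity_profile(occ[lu], q_grid)
    if flags.any():
        defa_sub, prof_sub_lpf = met.subset_metrics(occ["NFM"], occ["LPF"], flags, q_grid)
        rows.append(("threatened_endemic", defa_sub.mean, defa_sub.sd,
                     defa_sub.q2_5, defa_sub.q97_5))
        np.savetxt(mdir / "defaunation_samples_subset.csv", defa_sub.samples,
                   header="index")
        profiles["subset_LPF"] = prof_sub_lpf
        profiles["subset_NFM"] = met.diversity_profile(occ["NFM"][:, flags], q_grid)
    pd.DataFrame(
        rows, columns=["community", "mean", "sd", "q2.5", "q97.5"]
    ).to_csv(mdir / "defaunation.csv", index=False)
    for name, prof in profiles.items():
        prof.to_csv(mdir / f"diversity_profile_{name}.csv", index=False)
    _log_event(out, "metrics", defaunation_full=rows[0][1],
               defaunation_subset=rows[-1][1] if len(rows) > 1 else None)


def stage_report(config: RunConfig, out: Path):
    from occomm import plots

    mdir = _require(out / "metrics" / "defaunation.csv", "metrics").parent
    rdir = out / "report"
    rdir.mkdir(exist_ok=True)
    defa = pd.read_csv(mdir / "defaunation.csv")
    summary = {"defaunation": defa.to_dict(orient="records")}
    samples = np.loadtxt(mdir / "defaunation_samples_full.csv", skiprows=1)
    plots.plot_defaunation(
        samples, float(defa.loc[0, "mean"]),
        (float(defa.loc[0, "q2.5"]), float(defa.loc[0, "q97.5"])),
        rdir / "defaunation_full.png",
    )
    prof_paths = sorted(mdir.glob("diversity_profile_full_*.csv"))
    profs = {p.stem.split("_")[-1]: pd.read_csv(p) for p in prof_paths}
    if profs:
        plots.plot_diversity_profiles(profs, rdir / "diversity_profiles.png")
        summary["diversity_q012"] = {
            lu: {
                f"q{int(q)}": float(df.loc[np.isclose(df["q"], q), "mean"].iloc[0])
                for q in (0, 1, 2)
            }
            for lu, df in profs.items()
        }
    rich_path = out / "predict" / "richness_landuse.csv"
    if rich_path.exists():
        rich = pd.read_csv(rich_path).set_index("landuse")
        summary["richness_per_cell"] = {
            lu: {"mean": float(rich.loc[lu, "landuse_mean"]),
                 "sd": float(rich.loc[lu, "landuse_sd"])}
            for lu in rich.index
        }
    (rdir / "summary.json").write_text(json.dumps(summary, indent=1))
    _log_event(out, "report", artifacts=[p.name for p in rdir.iterdir()])
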