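"""Synthetic two-site camera-trap surveys with known community truth.

The generator is the exact probabilistic inverse of the community occupancy
model in :mod:`occomm.model`: species-level parameters are drawn from
community hyperdistributions, latent occupancy states ``z`` from the
logit-linear occupancy model, and occasion-level detections from the
logit-linear detection model with effort (functional camera-days, 0-10) and
road-placement terms.  Camera failures are per-camera per-day Bernoulli
events; occasions in which neither camera functioned yield zero effort and a
*missing* (not zero) detection cell.

Defaults emulate the study conditions the package targets: two forest
management units (Pasin, surveyed first; Raplex), 142 stations split between
natural forest management (NFM) and licensed planted forest (LPF), 25
species of which 15 are flagged threatened/endemic, 5-day occasions with two
cameras per station.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from occomm.core import FMUS, LANDUSES, inv_logit, substream

DEFAULT_COVARIATES = ("SCI", "access", "elevation", "TRI3")


@dataclass
class CommunityHyper:
    """Community-level hyperparameters (all on the logit scale).

    ``occ`` and ``det`` map landuse / survey-site labels to ``(mean, sd)`` of
    the species-level random intercepts; ``slopes`` maps covariate names to
    ``(mean, sd)`` of the species-level slopes.  ``effort_coef`` is a single
    fixed effect shared by all species (logit units per functional
    camera-day); ``road`` is the community distribution of the species-level
    on-road detection effect.
    """

    occ: dict[str, tuple[float, float]] = field(
        # Means solve E[inv_logit(mu + sigma Z)] = mean occupancy of ~0.727
        # (NFM) / 0.674 (LPF) — the study's per-cell richness out of 25
        # species — with sigma^2 the total linear-predictor variance.
        default_factory=lambda: {"NFM": (1.257, 1.0), "LPF": (0.936, 1.0)}
    )
    slopes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "SCI": (0.25, 0.40),
            "access": (0.0, 0.30),
            "elevation": (0.0, 0.30),
            "TRI3": (0.0, 0.30),
        }
    )
    det: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Pasin": (-5.21, 1.0), "Raplex": (-4.93, 1.0)}
    )
    effort_coef: float = 0.20
    road: tuple[float, float] = (0.2, 0.5)
    flag_fraction: float = 0.6  # threatened/endemic species share (15 of 25)

    def validate(self) -> None:
        # SD = 0 is accepted as the degenerate all-species-identical limit;
        # negative SDs are invalid.
        for name, d in (("occ", self.occ), ("slopes", self.slopes), ("det", self.det)):
            for key, (_, sd) in d.items():
                if sd < 0:
                    raise ValueError(f"hyper SD for {name}[{key}] must be >= 0, got {sd}")
        if self.road[1] < 0:
            raise ValueError(f"road hyper SD must be >= 0, got {self.road[1]}")
        if set(self.occ) != set(LANDUSES):
            raise ValueError(f"occ hyperparameters must cover landuses {LANDUSES}")
        if set(self.det) != set(FMUS):
            raise ValueError(f"det hyperparameters must cover survey sites {FMUS}")


@dataclass
class CommunityTruth:
    """Realized community: hyperparameters plus per-species parameters."""

    hyper: CommunityHyper
    species: list[str]
    beta0: np.ndarray       # (S, n_landuse) occupancy intercepts
    slopes: np.ndarray      # (S, n_cov) occupancy slopes
    alpha0: np.ndarray      # (S, n_fmu) detection intercepts
    road: np.ndarray        # (S,) on-road detection effects
    flags: np.ndarray       # (S,) bool, threatened/endemic

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.hyper.slopes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "landuses": list(LANDUSES),
            "fmus": list(FMUS),
            "covariates": list(self.covariate_names),
            "hyper": {
                "occ": {k: list(v) for k, v in self.hyper.occ.items()},
                "slopes": {k: list(v) for k, v in self.hyper.slopes.items()},
                "det": {k: list(v) for k, v in self.hyper.det.items()},
                "effort_coef": self.hyper.effort_coef,
                "road": list(self.hyper.road),
                "flag_fraction": self.hyper.flag_fraction,
            },
            "beta0": self.beta0.tolist(),
            "slopes_values": self.slopes.tolist(),
            "alpha0": self.alpha0.tolist(),
            "road": self.road.tolist(),
            "flags": self.flags.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CommunityTruth":
        d = json.loads(Path(path).read_text())
        hyper = CommunityHyper(
            occ={k: tuple(v) for k, v in d["hyper"]["occ"].items()},
            slopes={k: tuple(v) for k, v in d["hyper"]["slopes"].items()},
            det={k: tuple(v) for k, v in d["hyper"]["det"].items()},
            effort_coef=d["hyper"]["effort_coef"],
            road=tuple(d["hyper"]["road"]),
            flag_fraction=d["hyper"]["flag_fraction"],
        )
        return cls(
            hyper=hyper,
            species=d["species"],
            beta0=np.array(d["beta0"]),
            slopes=np.array(d["slopes_values"]),
            alpha0=np.array(d["alpha0"]),
            road=np.array(d["road"]),
            flags=np.array(d["flags"], dtype=bool),
        )


@dataclass
class SurveyDesign:
    """Station layout and observation design for a simulated survey.

    ``stations`` carries one row per station: ``station_id``, ``fmu``,
    ``landuse``, ``road`` (0/1 on-road placement), ``deploy_start`` and one
    column per habitat covariate (already on the scaled/analysis scale).
    Every station runs exactly two cameras.
    """

    stations: pd.DataFrame
    n_occasions: int = 12
    occasion_length: int = 5
    failure_prob: float = 0.02   # transient per-camera per-day failure
    death_prob: float = 0.01     # per-day hazard of permanent camera failure
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES

    def validate(self) -> None:
        required = {"station_id", "fmu", "landuse", "road", "deploy_start"}
        missing = required - set(self.stations.columns)
        if missing:
            raise ValueError(f"stations table missing columns: {sorted(missing)}")
        for c in self.covariate_names:
            if c not in self.stations.columns:
                raise ValueError(f"stations table missing covariate column {c!r}")
            if not np.isfinite(self.stations[c].to_numpy(dtype=float)).all():
                raise ValueError(f"covariate {c!r} contains non-finite values")
        for name in ("failure_prob", "death_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_occasions < 1 or self.occasion_length < 1:
            raise ValueError("n_occasions and occasion_length must be >= 1")


@dataclass
class SimulatedSurvey:
    """Everything a simulated survey produces, including the latent truth."""

    detections: xr.DataArray    # (species, station, occasion); 0/1, NaN where effort 0
    effort: xr.DataArray        # (station, occasion); functional camera-days 0-10
    stations: pd.DataFrame
    records: pd.DataFrame       # station_id, species, timestamp, camera_id
    functionality: pd.DataFrame  # station_id, camera_id, date, functional
    z: np.ndarray               # (S, J) latent occupancy states
    psi: np.ndarray             # (S, J) occupancy probabilities
    truth: CommunityTruth


def default_design(
    n_stations: int = 142,
    n_occasions: int = 12,
    occasion_length: int = 5,
    failure_prob: float = 0.05,
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
    road_fraction: float = 0.5,
    seed: int = 0,
) -> SurveyDesign:
    """Two-site station layout mirroring the target study's design.

    Stations are split Pasin/Raplex roughly 79/63 and NFM/LPF roughly 99/43
    (scaled proportionally for other ``n_stations``); covariates are drawn
    standard-normal, i.e. already on the scaled analysis scale.
    """
    rng = substream(seed, "design")
    n_pasin = int(round(n_stations * 79 / 142))
    fmu = np.array(["Pasin"] * n_pasin + ["Raplex"] * (n_stations - n_pasin))
    landuse = np.empty(n_stations, dtype=object)
    for site, start in (("Pasin", "2018-01-15"), ("Raplex", "2019-04-15")):
        idx = np.flatnonzero(fmu == site)
        n_lpf = int(round(len(idx) * 43 / 142))
        lab = np.array(["NFM"] * (len(idx) - n_lpf) + ["LPF"] * n_lpf)
        rng.shuffle(lab)
        landuse[idx] = lab
    road = (rng.random(n_stations) < road_fraction).astype(int)
    start_dates = np.where(
        fmu == "Pasin", np.datetime64("2018-01-15"), np.datetime64("2019-04-15")
    )
    stations = pd.DataFrame(
        {
            "station_id": [f"st{i + 1:03d}" for i in range(n_stations)],
            "fmu": fmu,
            "landuse": landuse,
            "road": road,
            "deploy_start": pd.to_datetime(start_dates),
        }
    )
    for c in covariate_names:
        stations[c] = rng.standard_normal(n_stations)
    return SurveyDesign(
        stations=stations,
        n_occasions=n_occasions,
        occasion_length=occasion_length,
        failure_prob=failure_prob,
        covariate_names=tuple(covariate_names),
    )


def default_hyper() -> CommunityHyper:
    return CommunityHyper()


def simulate_truth(
    hyper: CommunityHyper, n_species: int = 25, seed: int = 0
) -> CommunityTruth:
    """Draw per-species parameters from the community hyperdistributions."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    hyper.validate()
    rng = substream(seed, "truth")
    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    beta0 = np.column_stack(
        [rng.normal(*hyper.occ[lu], size=n_species) for lu in LANDUSES]
    )
    slopes = np.column_stack(
        [rng.normal(*hyper.slopes[c], size=n_species) for c in hyper.slopes]
    )
    alpha0 = np.column_stack(
        [rng.normal(*hyper.det[f], size=n_species) for f in FMUS]
    )
    road = rng.normal(*hyper.road, size=n_species)
    n_flag = int(round(hyper.flag_fraction * n_species))
    flags = np.zeros(n_species, dtype=bool)
    flags[rng.choice(n_species, size=n_flag, replace=False)] = True
    return CommunityTruth(
        hyper=hyper, species=species, beta0=beta0, slopes=slopes,
        alpha0=alpha0, road=road, flags=flags,
    )


def simulate_survey(
    truth: CommunityTruth, design: SurveyDesign, seed: int = 0
) -> SimulatedSurvey:
    """Simulate camera functionality, latent occupancy and detections.

    Returns occasion-level arrays plus the record/deployment tables in the
    same CSV schemas that :mod:`occomm.survey` ingests, enabling bitwise
    round-trip checks of the ingestion code.
    """
    design.validate()
    if tuple(truth.covariate_names) != tuple(design.covariate_names):
        raise ValueError(
            f"truth covariates {truth.covariate_names} do not match design "
            f"covariates {design.covariate_names}"
        )
    st = design.stations
    S, J, K = truth.n_species, len(st), design.n_occasions
    L = design.occasion_length
    rng_fail = substream(seed, "camera-failure")
    rng_occ = substream(seed, "occupancy")
    rng_det = substream(seed, "detection")

    # Per-camera per-day functionality: transient failures (battery/trigger
    # glitches) plus a permanent-death hazard (theft, damage, dead battery) — the
    # latter is what produces whole occasions with zero effort, as camera
    # failures do in the field.
    n_days = K * L
    dead = np.cumsum(
        rng_fail.random((J, 2, n_days)) < design.death_prob, axis=2
    ) > 0
    functional = (rng_fail.random((J, 2, n_days)) >= design.failure_prob) & ~dead
    # Effort: functional camera-days summed within each 5-day occasion.
    effort_np = functional.sum(axis=1).reshape(J, K, L).sum(axis=2).astype(int)

    lu_idx = np.array([LANDUSES.index(v) for v in st["landuse"]])
    fmu_idx = np.array([FMUS.index(v) for v in st["fmu"]])
    road_j = st["road"].to_numpy(dtype=float)
    X = st[list(design.covariate_names)].to_numpy(dtype=float)

    lpsi = truth.beta0[:, lu_idx] + truth.slopes @ X.T  # (S, J)
    psi = inv_logit(lpsi)
    z = (rng_occ.random((S, J)) < psi).astype(int)

    lp = (
        truth.alpha0[:, fmu_idx][:, :, None]
        + truth.hyper.effort_coef * effort_np[None, :, :]
        + (truth.road[:, None] * road_j[None, :])[:, :, None]
    )  # (S, J, K)
    p = inv_logit(lp)
    y = (rng_det.random((S, J, K)) < p * z[:, :, None]).astype(float)
    y[:, effort_np == 0] = np.nan

    occ_coord = np.arange(1, K + 1)
    detections = xr.DataArray(
        y,
        dims=("species", "station", "occasion"),
        coords={
            "species": truth.species,
            "station": st["station_id"].to_list(),
            "occasion": occ_coord,
        },
        name="detections",
    )
    effort = xr.DataArray(
        effort_np,
        dims=("station", "occasion"),
        coords={"station": st["station_id"].to_list(), "occasion": occ_coord},
        name="effort",
    )

    records = _records_from_detections(y, functional, st, L, truth.species)
    functionality = _functionality_table(functional, st)
    stations_out = st.copy()
    stations_out["deploy_end"] = stations_out["deploy_start"] + pd.Timedelta(
        days=n_days - 1
    )
    return SimulatedSurvey(
        detections=detections, effort=effort, stations=stations_out,
        records=records, functionality=functionality, z=z, psi=psi, truth=truth,
    )


def _records_from_detections(y, functional, stations, occ_len, species):
    """One record per detected species x station x occasion.

    The record is timestamped at noon of the first day of the occasion on
    which at least one camera functioned, attributed to the first functional
    camera — sufficient for the ingestion round trip, which only needs the
    occasion each record falls in.
    """
    rows = []
    starts = stations["deploy_start"].to_numpy()
    ids = stations["station_id"].to_list()
    any_cam = functional.any(axis=1)  # (J, day)
    s_idx, j_idx, k_idx = np.nonzero(np.nan_to_num(y) == 1)
    for s, j, k in zip(s_idx, j_idx, k_idx):
        days = np.flatnonzero(any_cam[j, k * occ_len : (k + 1) * occ_len])
        day = k * occ_len + int(days[0])
        cam = 1 if functional[j, 0, day] else 2
        ts = pd.Timestamp(starts[j]) + pd.Timedelta(days=day, hours=12)
        rows.append((ids[j], species[s], ts, f"{ids[j]}-c{cam}"))
    return pd.DataFrame(
        rows, columns=["station_id", "species", "timestamp", "camera_id"]
    ).sort_values(["station_id", "timestamp", "species"], ignore_index=True)


def _functionality_table(functional, stations):
    J, _, n_days = functional.shape
    starts = stations["deploy_start"].to_numpy()
    ids = stations["station_id"].to_numpy()
    frames = []
    for cam in (0, 1):
        df = pd.DataFrame(
            {
                "station_id": np.repeat(ids, n_days),
                "camera_id": np.repeat(
                    [f"{i}-c{cam + 1}" for i in ids], n_days
                ),
                "date": np.concatenate(
                    [
                        pd.date_range(pd.Timestamp(s), periods=n_days, freq="D")
                        for s in starts
                    ]
                ),
                "functional": functional[:, cam, :].reshape(-1).astype(int),
            }
        )
        frames.append(df)
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["station_id", "camera_id", "date"], ignore_index=True)
    )


def simulate_prediction_grid(
    n_cells: int = 20000,
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
    nfm_fraction: float = 0.846,
    seed: int = 0,
) -> pd.DataFrame:
    """Landscape grid of cells with scaled covariates and landuse labels.

    The NFM share defaults to the target landscape's proportion (~84.6% of
    cells inside natural-forest-management boundaries).
    """
    rng = substream(seed, "prediction-grid")
    n_nfm = int(round(n_cells * nfm_fraction))
    landuse = np.array(["NFM"] * n_nfm + ["LPF"] * (n_cells - n_nfm))
    grid = pd.DataFrame({"cell_id": np.arange(n_cells), "landuse": landuse})
    for c in covariate_names:
        grid[c] = rng.standard_normal(n_cells)
    return grid


def write_survey_csvs(sim: SimulatedSurvey, outdir: str | Path) -> dict[str, Path]:
    """Write records/stations/functionality CSVs plus the truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "stations": out / "stations.csv",
        "functionality": out / "functionality.csv",
        "truth": out / "truth.json",
    }
    sim.records.to_csv(paths["records"], index=False)
    sim.stations.to_csv(paths["stations"], index=False)
    sim.functionality.to_csv(paths["functionality"], index=False)
    sim.truth.to_json(paths["truth"])
    return paths
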