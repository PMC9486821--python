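"""Ingestion: raw record and deployment tables -> model-ready arrays.

Raw inputs are three flat tables (CSV on disk, DataFrame in memory):

``records``
    one row per independent camera record: ``station_id``, ``species``,
    ``timestamp`` (ISO-8601), ``camera_id``.
``stations``
    one row per station: ``station_id``, ``fmu``, ``landuse``, ``road``,
    ``deploy_start``, ``deploy_end`` plus covariate columns.
``functionality``
    one row per camera per deployment day: ``station_id``, ``camera_id``,
    ``date``, ``functional`` (0/1).

Days are condensed into fixed-length occasions (default 5 days) anchored at
each station's own deployment start; a trailing partial occasion is retained
with its reduced effort.  Detection cells where no camera functioned are
missing (NaN), never zero.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import xarray as xr

log = logging.getLogger(__name__)


def _deployment_days(stations: pd.DataFrame) -> np.ndarray:
    start = pd.to_datetime(stations["deploy_start"])
    end = pd.to_datetime(stations["deploy_end"])
    days = (end - start).dt.days.to_numpy() + 1
    if (days < 1).any():
        raise ValueError("deploy_end before deploy_start for some station")
    return days


def n_occasions_per_station(stations: pd.DataFrame, occasion_length: int) -> np.ndarray:
    """ceil(deployment days / occasion length), per station."""
    return -(-_deployment_days(stations) // occasion_length)


def build_effort(
    functionality: pd.DataFrame,
    stations: pd.DataFrame,
    occasion_length: int = 5,
) -> xr.DataArray:
    """Functional camera-days per station x occasion.

    Effort is the sum over the station's two cameras of days marked
    functional within each occasion (maximum ``2 * occasion_length``).
    Occasions after camera retrieval, and days absent from the functionality
    log, count as zero effort.
    """
    if occasion_length < 1:
        raise ValueError("occasion_length must be >= 1")
    st = stations.reset_index(drop=True)
    ids = st["station_id"].to_list()
    n_occ = n_occasions_per_station(st, occasion_length)
    K = int(n_occ.max())
    effort = np.zeros((len(ids), K), dtype=int)

    fn = functionality.copy()
    fn["date"] = pd.to_datetime(fn["date"])
    start_by_station = dict(zip(ids, pd.to_datetime(st["deploy_start"])))
    end_by_station = dict(zip(ids, pd.to_datetime(st["deploy_end"])))
    pos = {sid: i for i, sid in enumerate(ids)}

    for sid, grp in fn.groupby("station_id", sort=False):
        if sid not in pos:
            raise KeyError(f"functionality log references unknown station {sid!r}")
        cams = grp["camera_id"].unique()
        if len(cams) > 2:
            raise ValueError(
                f"station {sid!r} has {len(cams)} cameras in the functionality "
                "log; the design allows exactly 2"
            )
        j = pos[sid]
        inside = (grp["date"] >= start_by_station[sid]) & (
            grp["date"] <= end_by_station[sid]
        )
        g = grp[inside & (grp["functional"].astype(int) == 1)]
        day = (g["date"] - start_by_station[sid]).dt.days.to_numpy()
        occ = day // occasion_length
        np.add.at(effort[j], occ, 1)

    if (effort > 2 * occasion_length).any():
        raise ValueError("effort exceeds 2 cameras x occasion length; duplicate log rows?")
    return xr.DataArray(
        effort,
        dims=("station", "occasion"),
        coords={"station": ids, "occasion": np.arange(1, K + 1)},
        name="effort",
    )


def build_detection_history(
    records: pd.DataFrame,
    stations: pd.DataFrame,
    effort: xr.DataArray,
    occasion_length: int = 5,
    species: list[str] | None = None,
) -> xr.DataArray:
    """Species x station x occasion binary detection history.

    A cell is 1 iff at least one record of the species (either camera; both
    cameras at a station are pooled) falls inside that occasion, 0 if the
    station was surveyed (effort > 0) without a record, and missing (NaN)
    where effort is 0.  Occasions count from each station's deployment start.

    Records timestamped outside the station's deployment window are dropped
    with a warning; records at unknown stations raise ``KeyError``.
    """
    st = stations.reset_index(drop=True)
    ids = st["station_id"].to_list()
    pos = {sid: i for i, sid in enumerate(ids)}
    if species is None:
        species = sorted(records["species"].unique())
    sp_pos = {sp: i for i, sp in enumerate(species)}
    K = effort.sizes["occasion"]
    y = np.zeros((len(species), len(ids), K))

    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    unknown = set(rec["station_id"]) - set(ids)
    if unknown:
        raise KeyError(f"records reference unknown stations: {sorted(unknown)}")

    start = pd.to_datetime(st["deploy_start"]).to_numpy()[
        rec["station_id"].map(pos).to_numpy()
    ]
    end = pd.to_datetime(st["deploy_end"]).to_numpy()[
        rec["station_id"].map(pos).to_numpy()
    ] + np.timedelta64(1, "D")
    ts = rec["timestamp"].to_numpy()
    inside = (ts >= start) & (ts < end)
    n_dropped = int((~inside).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} record(s) outside the deployment window",
            stacklevel=2,
        )
        log.info("dropped %d out-of-window records", n_dropped)

    day = ((ts - start) / np.timedelta64(1, "D")).astype(int)
    occ = day // occasion_length
    for keep, sid, sp, k in zip(
        inside, rec["station_id"], rec["species"], occ
    ):
        if keep and sp in sp_pos:
            y[sp_pos[sp], pos[sid], k] = 1.0

    y[:, effort.to_numpy() == 0] = np.nan
    out = xr.DataArray(
        y,
        dims=("species", "station", "occasion"),
        coords={
            "species": species,
            "station": ids,
            "occasion": np.arange(1, K + 1),
        },
        name="detections",
    )
    out.attrs["n_dropped_records"] = n_dropped
    return out


def independent_records(
    records: pd.DataFrame, independence_minutes: float = 30.0
) -> pd.DataFrame:
    """Collapse records of one species at one station closer than the
    independence interval into single events (first record kept)."""
    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    rec = rec.sort_values(["station_id", "species", "timestamp"])
    gap = rec.groupby(["station_id", "species"])["timestamp"].diff()
    new_event = gap.isna() | (gap >= pd.Timedelta(minutes=independence_minutes))
    return rec[new_event].reset_index(drop=True)


def filter_species(
    records: pd.DataFrame,
    min_detections: int = 5,
    exclusion_list: tuple[str, ...] = (),
    independence_minutes: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the analysis species filter to a record table.

    Species are retained if they have at least ``min_detections`` independent
    records (events separated by the independence interval) and are not on
    the exclusion list (arboreal / reptile / small-mammal / wide-ranging taxa
    unsuited to terrestrial camera stations).

    Returns the filtered record table (all raw records of retained species)
    and a per-species report with columns ``species``, ``n_records``,
    ``n_independent``, ``retained``, ``reason``.
    """
    events = independent_records(records, independence_minutes)
    n_ind = events.groupby("species").size()
    n_raw = records.groupby("species").size()
    report_rows = []
    retained = []
    for sp in sorted(n_raw.index):
        ni = int(n_ind.get(sp, 0))
        if sp in exclusion_list:
            reason = "excluded taxon"
            keep = False
        elif ni < min_detections:
            reason = f"<{min_detections} independent records"
            keep = False
        else:
            reason = ""
            keep = True
        if keep:
            retained.append(sp)
        report_rows.append((sp, int(n_raw[sp]), ni, keep, reason))
    report = pd.DataFrame(
        report_rows,
        columns=["species", "n_records", "n_independent", "retained", "reason"],
    )
    if not retained:
        counts = ", ".join(f"{r[0]}={r[2]}" for r in report_rows)
        raise ValueError(
            "no species passed the detection filter "
            f"(independent record counts: {counts})"
        )
    filtered = records[records["species"].isin(retained)].reset_index(drop=True)
    log.info("retained %d of %d species", len(retained), len(n_raw))
    return filtered, report
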