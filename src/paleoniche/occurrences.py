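"""Occurrence ingestion, filtering, collapse, and model-table assembly.

The analysis window is the closed interval [7500, 47000] cal BP: younger
records risk confusion with domesticated forms, older ones are too sparse
to model. Within the window, observations are collapsed to one record per
(species, grid cell, time slice) — presence/background models need
presences, not frequencies, and repeated dates from one site and slice
mostly encode sampling effort. The retained duplicate is the one with the
smallest age_error (ties broken by file order); which duplicate survives
is immaterial for modelling, since all share a cell and hence an
environment, but a fixed rule keeps the pipeline deterministic.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .climate import VARIABLES, ClimateCube, extract_env, nearest_slice

REQUIRED_COLUMNS = ("species", "longitude", "latitude", "age_calBP")

DEFAULT_WINDOW = (7_500.0, 47_000.0)


def read_occurrences(path, window=DEFAULT_WINDOW, report: dict | None = None) -> pd.DataFrame:
    """Load an occurrence CSV, normalize longitudes to [-180, 180), drop
    records outside the (closed) time window or with invalid coordinates.

    ``report``, if given, collects exclusion counts by reason and the row
    numbers of rejected records.
    """
    df = pd.read_csv(path)
    return filter_occurrences(df, window=window, report=report)


def filter_occurrences(df: pd.DataFrame, window=DEFAULT_WINDOW, report: dict | None = None) -> pd.DataFrame:
    young, old = window
    if young >= old:
        raise ValueError("window must satisfy young < old")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"required column {col} missing")
    df = df.copy()
    if "age_error" not in df.columns:
        df["age_error"] = np.nan

    lon = df["longitude"].to_numpy(dtype=float)
    lon = np.where(lon >= 180.0, lon - 360.0, lon)
    df["longitude"] = lon

    bad_coord = (
        (np.abs(df["latitude"].to_numpy(dtype=float)) > 90)
        | (lon < -180)
        | (lon >= 180)
        | ~np.isfinite(lon)
        | ~np.isfinite(df["latitude"].to_numpy(dtype=float))
    )
    age = df["age_calBP"].to_numpy(dtype=float)
    bad_age = ~np.isfinite(age) | (age < 0)
    outside = ~bad_age & ((age < young) | (age > old))
    keep = ~(bad_coord | bad_age | outside)

    if report is not None:
        report["n_input"] = int(len(df))
        report["invalid_coordinates"] = [int(i) for i in np.flatnonzero(bad_coord)]
        report["invalid_age"] = [int(i) for i in np.flatnonzero(bad_age & ~bad_coord)]
        report["outside_window"] = int(outside.sum())
        report["n_retained"] = int(keep.sum())
    return df.loc[keep].reset_index(drop=True)


def collapse_occurrences(table: pd.DataFrame, cube: ClimateCube) -> pd.DataFrame:
    """One record per (species, cell, slice): smallest age_error wins,
    ties broken by original row order. Output is sorted by species, slice,
    then cell (row-major), so any input ordering yields the same result."""
    if table.empty:
        return table.copy()
    df = table.reset_index(drop=True).copy()
    row, col = cube.grid.cell_index(df["longitude"], df["latitude"])
    df["_cell"] = row * cube.grid.n_lon + col
    df["_slice"] = nearest_slice(df["age_calBP"].to_numpy(dtype=float), cube.ages)
    df["_order"] = np.arange(len(df))
    df["_err"] = df["age_error"].fillna(np.inf)
    df = df.sort_values(["species", "_slice", "_cell", "_err", "_order"], kind="stable")
    out = df.groupby(["species", "_slice", "_cell"], as_index=False, sort=True).first()
    out = out.sort_values(["species", "_slice", "_cell"], kind="stable").reset_index(drop=True)
    out["slice_calBP"] = out["_slice"]
    return out.drop(columns=["_cell", "_slice", "_order", "_err"])


def build_model_table(
    presences: pd.DataFrame,
    backgrounds: "RepetitionSet",
    cube: ClimateCube,
    report: dict | None = None,
) -> pd.DataFrame:
    """Join collapsed presences and per-repetition backgrounds to their
    cell environments, yielding the GAM design input.

    One long table with columns response (1/0), repetition, time (slice
    age), lon, lat and the five variables. Presence rows are identical
    across repetitions; rows flagged sea/ice by extraction are removed
    with a logged count.
    """
    from .background import RepetitionSet  # local to avoid cycle

    assert isinstance(backgrounds, RepetitionSet)
    pres_pts = pd.DataFrame(
        {
            "lon": presences["longitude"].to_numpy(dtype=float),
            "lat": presences["latitude"].to_numpy(dtype=float),
            "age_calBP": presences["age_calBP"].to_numpy(dtype=float),
        }
    )
    pres_env = extract_env(cube, pres_pts)
    dropped = int((pres_env["status"] != "ok").sum())
    pres_env = pres_env[pres_env["status"] == "ok"]
    if report is not None:
        report["presences_dropped_sea_or_ice"] = dropped
        report["presences_retained"] = int(len(pres_env))

    frames = []
    for rep_id, rep_table in backgrounds.tables.items():
        if rep_table.empty:
            raise ValueError(f"repetition {rep_id} has zero background points")
        p = pres_env[["lon", "lat", "time"] + list(VARIABLES)].copy()
        p["response"] = 1
        p["repetition"] = rep_id
        bg_env = extract_env(
            cube,
            pd.DataFrame(
                {
                    "lon": rep_table["lon"].to_numpy(dtype=float),
                    "lat": rep_table["lat"].to_numpy(dtype=float),
                    "age_calBP": rep_table["slice_calBP"].to_numpy(dtype=float),
                }
            ),
        )
        bad_bg = int((bg_env["status"] != "ok").sum())
        if bad_bg:  # background is drawn from available cells, so this
            raise ValueError(f"repetition {rep_id}: {bad_bg} background points off land")
        b = bg_env[["lon", "lat", "time"] + list(VARIABLES)].copy()
        b["response"] = 0
        b["repetition"] = rep_id
        frames.append(pd.concat([p, b], ignore_index=True))
    out = pd.concat(frames, ignore_index=True)
    cols = ["response", "repetition", "time", "lon", "lat"] + list(VARIABLES)
    return out[cols]


def write_exclusion_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
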