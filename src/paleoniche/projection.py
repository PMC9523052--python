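"""Geographic projection of the best ensemble.

The ensemble is evaluated on every land, ice-free cell of each time slice
(ice is masked before thresholding — treated as non-habitat throughout),
giving per-slice suitability maps. A single species-level threshold — the
minimum-predicted-area (MPA) threshold, the largest suitability value that
still covers a target fraction (default 99%) of the training presences —
turns suitability into binary range maps, which are then averaged within
the four major climatic periods: pre-LGM (47-27 kya), LGM (27-18 kya),
Late Glacial (18-11.7 kya) and Holocene (11.7-7.5 kya). Period means are
computed over cells that are land in every member slice; the union ice
mask is carried alongside for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .climate import ClimateCube
from .evaluation import EnsemblePrediction

#: (name, old edge, young edge); boundary slices belong to the OLDER period
PERIODS = (
    ("pre-LGM", 47_000.0, 27_000.0),
    ("LGM", 27_000.0, 18_000.0),
    ("Late Glacial", 18_000.0, 11_700.0),
    ("Holocene", 11_700.0, 7_500.0),
)


def assign_period(age: float, periods=PERIODS) -> str:
    """Climatic period of a slice; a slice on a shared boundary goes to
    the older period (e.g. 18 kya is LGM, not Late Glacial)."""
    if age == periods[0][1]:  # oldest edge belongs to the oldest period
        return periods[0][0]
    for name, old, young in periods:
        if young <= age < old:
            return name
    raise ValueError(f"age {age} outside all periods")


@dataclass
class SuitabilityMap:
    age: float
    values: np.ndarray  # (n_lat, n_lon); NaN off the available mask


def project_slice(ensemble: EnsemblePrediction, cube: ClimateCube, age: float) -> SuitabilityMap:
    """Ensemble suitability on every available cell of one slice."""
    env = cube.env_at(age)  # raises KeyError if the slice is absent
    probs = ensemble.predict(env)
    grid = np.full((cube.grid.n_lat, cube.grid.n_lon), np.nan)
    row, col = cube.grid.cell_index(env["lon"], env["lat"])
    grid[row, col] = probs
    return SuitabilityMap(age=age, values=grid)


def project_all(ensemble: EnsemblePrediction, cube: ClimateCube) -> list:
    return [project_slice(ensemble, cube, age) for age in cube.ages]


def mpa_threshold(pred_presence, coverage: float = 0.99) -> float:
    """Minimum-predicted-area threshold: the largest t such that at least
    ``coverage`` of the presence predictions are >= t.

    With n all-distinct predictions and coverage 0.99 this is the
    ceil(n*(1-coverage))+... -th smallest value; monotone non-increasing
    in coverage.
    """
    p = np.sort(np.asarray(pred_presence, dtype=float))
    n = len(p)
    if n == 0:
        raise ValueError("no presence predictions")
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    # largest index i with (n - i)/n >= coverage  ->  i = floor(n*(1-coverage))
    i = int(np.floor(n * (1 - coverage) + 1e-12))
    i = min(i, n - 1)
    return float(p[i])


@dataclass
class BinaryMaps:
    threshold: float
    ages: np.ndarray
    maps: list  # per slice: (n_lat, n_lon) float arrays of {0,1,NaN}


def binarize_maps(maps: list, threshold: float) -> BinaryMaps:
    """Cell = 1 iff suitability >= threshold; missing cells stay NaN."""
    ages = np.array([m.age for m in maps])
    out = []
    for m in maps:
        b = np.where(np.isnan(m.values), np.nan, (m.values >= threshold).astype(float))
        out.append(b)
    return BinaryMaps(threshold=threshold, ages=ages, maps=out)


@dataclass
class PeriodSummary:
    threshold: float
    periods: dict  # name -> dict(mean=..., land_all=..., ice_union=..., ages=[...])

    def to_dataset(self, cube: ClimateCube) -> xr.Dataset:
        names = list(self.periods)
        data = np.stack([self.periods[n]["mean"] for n in names])
        ice = np.stack([self.periods[n]["ice_union"] for n in names])
        return xr.Dataset(
            {
                "range_mean": (("period", "lat", "lon"), data),
                "ice_union": (("period", "lat", "lon"), ice.astype(np.uint8)),
            },
            coords={"period": names, "lat": cube.grid.lats, "lon": cube.grid.lons},
            attrs={"threshold": self.threshold},
        )


def period_average(binary: BinaryMaps, cube: ClimateCube, periods=PERIODS) -> PeriodSummary:
    """Mean binary range per climatic period over cells that are land in
    every member slice; union ice mask carried for display. Empty periods
    are skipped with a warning."""
    import warnings

    groups: dict = {}
    for i, age in enumerate(binary.ages):
        groups.setdefault(assign_period(age, periods), []).append(i)
    out = {}
    for name, *_ in periods:
        idx = groups.get(name, [])
        if not idx:
            warnings.warn(f"period {name}: no member slices, skipped")
            continue
        t_idx = [cube.slice_index(a) for a in binary.ages[idx]]
        land_all = np.all(cube.land[t_idx] > 0, axis=0)
        ice_union = np.any(cube.ice[t_idx] > 0, axis=0)
        stack = np.stack([binary.maps[i] for i in idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
        mean = np.where(land_all, mean, np.nan)
        out[name] = {
            "mean": mean,
            "land_all": land_all,
            "ice_union": ice_union,
            "ages": [float(a) for a in binary.ages[idx]],
        }
    return PeriodSummary(threshold=binary.threshold, periods=out)


@dataclass
class InteractionBundle:
    """Everything needed to re-render the niche-change figures for one
    variable: the mean effect surface, the presence points in (time,
    value) space, and the availability density matrix. A shared colour
    scale (global max |effect|) keeps panels comparable."""

    surfaces: dict  # variable -> InteractionSurface
    presence_points: dict  # variable -> DataFrame(age_calBP, value)
    densities: dict  # variable -> DensityMatrix
    effect_scale: float

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for var, surf in self.surfaces.items():
            surf.to_frame().to_csv(outdir / f"surface_{var}.csv")
            self.presence_points[var].to_csv(outdir / f"presences_{var}.csv", index=False)
            self.densities[var].to_frame().to_csv(outdir / f"availability_{var}.csv")


def interaction_bundle(surfaces: dict, presences_env: pd.DataFrame, densities: dict) -> InteractionBundle:
    """Assemble surfaces + presence dots + availability densities with a
    shared effect colour scale."""
    points = {}
    for var in surfaces:
        points[var] = pd.DataFrame(
            {
                "age_calBP": presences_env["time"].to_numpy(dtype=float),
                "value": presences_env[var].to_numpy(dtype=float),
            }
        )
    scale = max(
        float(np.max(np.abs(np.where(s.included, s.effect, 0.0)))) for s in surfaces.values()
    )
    return InteractionBundle(
        surfaces=surfaces, presence_points=points, densities=densities, effect_scale=scale
    )
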