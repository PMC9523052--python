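"""Synthetic paleoclimate and occurrence scenarios.

This module generates the study conditions the pipeline assumes: a
multi-variable climate cube on a regular grid with a glacial-cycle signal
and a shrinking ice sheet, a known (optionally time-varying) niche, and
presence records sampled from that niche with geographically biased effort
and radiocarbon-style age scatter. Because the truth is known, every
downstream stage — collapse, background sampling, GAM fitting, model
selection, evaluation, projection — is testable without any external data.

The generating model is deliberately simple, not a climate emulation:

* each variable is ``baseline + spatial gradients + smooth seeded noise
  field + trend_amplitude * g(t)``, where the glacial index ``g(t)`` ramps
  linearly from 0 at 10 kya to 1 at 20 kya and stays 1 before that;
* the true niche is a product of per-variable Gaussian response curves,
  optionally switching curve sets at a change-point time (ages are years
  BP, so "before the change" means t >= change_time);
* sampling effort is an east-west logistic ramp, mimicking uneven
  archaeological sampling.

Default parameters keep all pairwise variable correlations below the 0.7
collinearity screen; ``collinear_scenario`` deliberately violates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .climate import VARIABLES, ClimateCube, GridSpec, time_axis


def glacial_index(age_calBP) -> np.ndarray:
    """0 in the Holocene, 1 at full glacial, linear ramp 10-20 kya."""
    t = np.asarray(age_calBP, dtype=float)
    return np.clip((t - 10_000.0) / 10_000.0, 0.0, 1.0)


@dataclass
class VariableSpec:
    """Spatial/temporal structure of one synthetic variable."""

    baseline: float
    lat_gradient: float = 0.0  # units per degree north of the grid's south edge
    lon_gradient: float = 0.0  # units per degree east of the grid's west edge
    noise_sd: float = 0.0  # sd of the static smooth noise field
    noise_smoothness: float = 2.0  # gaussian-filter sigma, in cells
    trend_amplitude: float = 0.0  # added at full glacial (g=1)


@dataclass
class IceSchedule:
    """Southern ice-sheet limit as a function of the glacial index."""

    lat_full: float = 54.0  # southern limit at g=1
    lat_modern: float = 70.0  # southern limit at g=0 (off-grid -> no ice)

    def southern_limit(self, age_calBP) -> np.ndarray:
        g = glacial_index(age_calBP)
        return self.lat_modern + (self.lat_full - self.lat_modern) * g


@dataclass
class ResponseCurve:
    """Gaussian suitability curve; width=inf gives a flat (uninformative)
    response. Values are always in [0, 1]."""

    optimum: float
    width: float

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if not np.isfinite(self.width):
            return np.ones_like(x)
        return np.exp(-(((x - self.optimum) / self.width) ** 2))


@dataclass
class NicheSpec:
    """Product-form niche; optionally a different curve set after a
    change-point (time in years BP: t >= change_time uses `curves`)."""

    curves: dict
    change_time: float | None = None
    post_curves: dict | None = None


class NicheFunction:
    """Callable mapping (environment, time) -> suitability in [0, 1].

    Suitability is the product of per-variable response curves, so it is
    bounded above by the smallest marginal curve value. With no declared
    change point the function is time-invariant.
    """

    def __init__(self, spec: NicheSpec):
        if spec.change_time is not None and spec.post_curves is None:
            raise ValueError("change-point niche needs post_curves")
        self.spec = spec

    @property
    def variables(self) -> tuple:
        return tuple(self.spec.curves)

    def _curves(self, age_calBP: float) -> dict:
        if self.spec.change_time is not None and age_calBP < self.spec.change_time:
            return self.spec.post_curves
        return self.spec.curves

    def __call__(self, env, age_calBP: float) -> np.ndarray:
        curves = self._curves(age_calBP)
        out = None
        for name, curve in curves.items():
            vals = np.asarray(env[name], dtype=float)
            s = np.asarray(curve(vals), dtype=float)
            if np.any((s < -1e-12) | (s > 1 + 1e-12)):
                raise ValueError(f"response curve for {name} left [0, 1]")
            out = s if out is None else out * s
        return np.clip(out, 0.0, 1.0)


def define_niche(spec: NicheSpec) -> NicheFunction:
    """Validate a niche spec and return the callable suitability function."""
    fn = NicheFunction(spec)
    probe = np.linspace(-1e4, 1e4, 101)
    for curves in (spec.curves, spec.post_curves or {}):
        for name, curve in curves.items():
            s = np.asarray(curve(probe), dtype=float)
            if np.any((s < -1e-12) | (s > 1 + 1e-12)) or not np.all(np.isfinite(s)):
                raise ValueError(f"response curve for {name} yields values outside [0, 1]")
    return fn


@dataclass
class SamplingSpec:
    """Presence sampling: per-slice effort and spatial bias.

    The default effort (25 records per slice, ~650 collapsed presences
    over the 27 default slices) emulates the scale of well-sampled
    late-Quaternary megafauna datasets, whose collapsed species counts
    run to several hundred records.
    """

    n_per_slice: int = 25
    bias_strength: float = 1.0  # 0 disables the bias ramp
    bias_center_lon: float = 10.0
    bias_scale: float = 8.0  # logistic scale, degrees
    species: str = "Equus syntheticus"

    def bias(self, lon) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        if self.bias_strength == 0:
            return np.ones_like(lon)
        ramp = 1.0 / (1.0 + np.exp((lon - self.bias_center_lon) / self.bias_scale))
        return 1.0 + self.bias_strength * ramp


def _default_variables() -> dict:
    return {
        "BIO5": VariableSpec(28.0, lat_gradient=-0.35, noise_sd=4.0, trend_amplitude=-6.0),
        "BIO6": VariableSpec(2.0, lat_gradient=-0.5, noise_sd=5.0, trend_amplitude=-10.0),
        "BIO12": VariableSpec(1000.0, lon_gradient=-8.0, noise_sd=150.0, trend_amplitude=-250.0),
        "NPP": VariableSpec(850.0, noise_sd=180.0, noise_smoothness=3.0, trend_amplitude=-150.0),
        "rugosity": VariableSpec(2.0, noise_sd=0.8, noise_smoothness=1.5),
    }


def _default_niche(change: bool) -> NicheSpec:
    pre = {
        "BIO5": ResponseCurve(20.0, 6.0),
        "BIO6": ResponseCurve(-12.0, 5.0),
        "BIO12": ResponseCurve(800.0, 350.0),
        "NPP": ResponseCurve(800.0, 500.0),
        "rugosity": ResponseCurve(2.0, 2.5),
    }
    if not change:
        return NicheSpec(curves=pre)
    post = dict(pre)
    post["BIO6"] = ResponseCurve(-2.0, 5.0)
    return NicheSpec(curves=pre, change_time=16_000.0, post_curves=post)


@dataclass
class ScenarioConfig:
    """Everything needed to generate one synthetic study."""

    lon_min: float = -10.0
    lon_max: float = 30.0
    lat_min: float = 35.0
    lat_max: float = 60.0
    resolution: float = 1.0
    window: tuple = (7_500.0, 47_000.0)
    variables: dict = field(default_factory=_default_variables)
    ice: IceSchedule = field(default_factory=IceSchedule)
    niche: NicheSpec = field(default_factory=lambda: _default_niche(change=True))
    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    sea_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.window[0] >= self.window[1]:
            raise ValueError("time window must satisfy young < old")
        if self.sampling.n_per_slice < 0:
            raise ValueError("presences per slice must be >= 0")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            lon_min=self.lon_min,
            lat_min=self.lat_min,
            resolution=self.resolution,
            n_lon=int(round((self.lon_max - self.lon_min) / self.resolution)),
            n_lat=int(round((self.lat_max - self.lat_min) / self.resolution)),
        )


def default_scenario(seed: int = 0, change: bool = True, **kw) -> ScenarioConfig:
    return ScenarioConfig(seed=seed, niche=_default_niche(change=change), **kw)


def constant_scenario(seed: int = 0, **kw) -> ScenarioConfig:
    """Constant-niche null scenario.

    Sampling is unbiased here: a spatial effort bias under a drifting
    climate changes the environmental profile of the sampled region
    through time, i.e. it induces a *genuine* change in the realized,
    sampled niche — which would contradict this scenario's role as the
    no-change condition for selection calibration. The change-point
    scenario keeps the bias (robustness is part of what it tests).
    """
    cfg = default_scenario(seed=seed, change=False, **kw)
    cfg.sampling.bias_strength = 0.0
    return cfg


def collinear_scenario(seed: int = 0) -> ScenarioConfig:
    """NPP made a near-affine copy of BIO12 (same gradients and trend,
    little independent noise on either) so the correlation screen fails
    by construction (exercises the screen's failure path)."""
    cfg = default_scenario(seed=seed)
    cfg.variables["BIO12"] = VariableSpec(
        1000.0, lon_gradient=-8.0, noise_sd=60.0, trend_amplitude=-250.0
    )
    cfg.variables["NPP"] = VariableSpec(
        850.0, lon_gradient=-8.0, noise_sd=0.0, trend_amplitude=-250.0
    )
    return cfg


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance smooth random field (gaussian-filtered white noise)."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_climate_cube(config: ScenarioConfig) -> ClimateCube:
    """Build the scenario's climate cube (deterministic given the seed)."""
    grid = config.grid
    ages = time_axis(*config.window)
    lons, lats = grid.lons, grid.lats
    lon2d, lat2d = np.meshgrid(lons, lats)
    n_t = len(ages)
    shape2d = (grid.n_lat, grid.n_lon)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    # static land/sea split from a smooth seeded field
    sea_field = _smooth_field(rng, shape2d, sigma=3.0)
    thresh = np.quantile(sea_field, config.sea_fraction)
    land2d = (sea_field >= thresh).astype(np.uint8)

    g = glacial_index(ages)
    ice = np.zeros((n_t,) + shape2d, dtype=np.uint8)
    limits = config.ice.southern_limit(ages)
    for i in range(n_t):
        ice[i] = (lat2d >= limits[i]).astype(np.uint8) & land2d

    land = np.broadcast_to(land2d, (n_t,) + shape2d).copy()

    variables = {}
    for name in VARIABLES:
        spec = config.variables[name]
        base = (
            spec.baseline
            + spec.lat_gradient * (lat2d - config.lat_min)
            + spec.lon_gradient * (lon2d - config.lon_min)
        )
        if spec.noise_sd > 0:
            base = base + spec.noise_sd * _smooth_field(rng, shape2d, spec.noise_smoothness)
        cube = base[None, :, :] + spec.trend_amplitude * g[:, None, None]
        cube = np.where(land2d[None, :, :] > 0, cube, np.nan)
        variables[name] = cube

    return ClimateCube(
        grid=grid,
        ages=ages,
        variables=variables,
        land=land,
        ice=ice,
        attrs={"scenario_seed": config.seed},
    )


def sample_occurrences(
    cube: ClimateCube,
    niche: NicheFunction,
    sampling: SamplingSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw presence records per slice with probability proportional to
    suitability x sampling bias over land, ice-free cells.

    Records get cell-center coordinates, an age jittered uniformly within
    just under half the slice's minimum neighbour gap (so nearest-slice
    assignment round-trips to the generating slice), and a small positive
    age_error used only by the collapse tie rule. Extra truth columns
    (slice_true, suitability_true) support testing; the CSV writer keeps
    only the occurrence schema.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    ages = cube.ages
    gaps = np.diff(ages)
    records = []
    for i, age in enumerate(ages):
        ok = cube.available(age)
        if not ok.any():
            raise ValueError(f"slice {age:.0f}: no ice-free land to sample from")
        if sampling.n_per_slice == 0:
            continue
        rows, cols = np.nonzero(ok)
        env = {name: cube.variables[name][i][rows, cols] for name in VARIABLES}
        suit = niche(env, age)
        lon = cube.grid.lons[cols]
        lat = cube.grid.lats[rows]
        w = suit * sampling.bias(lon)
        total = w.sum()
        if total <= 0:
            raise ValueError(f"slice {age:.0f}: suitability is zero everywhere")
        p = w / total
        picks = rng.choice(len(p), size=sampling.n_per_slice, p=p)
        half = min(
            gaps[i - 1] if i > 0 else np.inf,
            gaps[i] if i < len(gaps) else np.inf,
        ) / 2.0
        jitter = rng.uniform(-0.998 * half, 0.998 * half, size=sampling.n_per_slice)
        err = rng.uniform(50.0, 300.0, size=sampling.n_per_slice)
        records.append(
            pd.DataFrame(
                {
                    "species": sampling.species,
                    "longitude": lon[picks],
                    "latitude": lat[picks],
                    "age_calBP": age + jitter,
                    "age_error": err,
                    "slice_true": age,
                    "suitability_true": suit[picks],
                }
            )
        )
    if not records:
        return pd.DataFrame(
            columns=[
                "species", "longitude", "latitude", "age_calBP", "age_error",
                "slice_true", "suitability_true",
            ]
        )
    return pd.concat(records, ignore_index=True)


OCCURRENCE_COLUMNS = ["species", "longitude", "latitude", "age_calBP", "age_error"]


def write_occurrences(table: pd.DataFrame, path) -> None:
    table[OCCURRENCE_COLUMNS].to_csv(path, index=False)


def generate_scenario(config: ScenarioConfig):
    """Cube, niche and occurrences for one scenario (the usual entry point)."""
    cube = generate_climate_cube(config)
    niche = define_niche(config.niche)
    occ = sample_occurrences(cube, niche, config.sampling, seed=config.seed)
    return cube, niche, occ
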