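"""End-to-end orchestration: simulate/load -> collapse -> background ->
fit -> diagnose -> select -> ensemble -> project, with a reproducible
run manifest.

The pipeline is deterministic given the config and master seed: every
random stage (scenario generation, background repetitions, residual
simulations) draws from seeds derived from the master seed, and the
manifest records per-stage output hashes so two identical runs can be
compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .background import sample_background_repetitions
from .climate import VARIABLES, availability_density, extract_env, read_climate_cube, write_climate_cube
from .diagnostics import concurvity, correlation_screen
from .evaluation import build_ensemble, select_model, variable_importance
from .gam import (
    CHANGING_NICHE,
    CONSTANT_NICHE,
    fit_gam,
    make_formula,
    smooth_surface,
)
from .occurrences import (
    DEFAULT_WINDOW,
    build_model_table,
    collapse_occurrences,
    filter_occurrences,
    read_occurrences,
)
from .projection import (
    binarize_maps,
    interaction_bundle,
    mpa_threshold,
    period_average,
    project_all,
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs. Either ``scenario`` (synthetic)
    or both ``climate_path`` and ``occurrence_path`` must be set."""

    output_dir: str
    seed: int
    scenario: str | None = "default"  # default | constant | collinear | None
    climate_path: str | None = None
    occurrence_path: str | None = None
    species: list = field(default_factory=list)
    region: tuple | None = None
    window: tuple = DEFAULT_WINDOW
    n_repetitions: int = 25
    ratio: int = 50
    gamma: float = 1.4
    k: dict = field(default_factory=dict)
    k_time: int = 5
    bci_threshold: float = 0.8
    mpa_coverage: float = 0.99
    correlation_threshold: float = 0.7
    concurvity_threshold: float = 0.8
    importance: bool = False
    importance_repetitions: int = 3
    n_value_grid: int = 40

    def validate(self) -> None:
        errors = []
        if self.seed is None:
            errors.append("seed is mandatory")
        if self.scenario is None and not (self.climate_path and self.occurrence_path):
            errors.append("need a scenario or climate_path + occurrence_path")
        if not (0 < self.mpa_coverage <= 1):
            errors.append("mpa_coverage must be in (0, 1]")
        if not (-1 <= self.bci_threshold <= 1):
            errors.append("bci_threshold must be in [-1, 1]")
        for name in ("correlation_threshold", "concurvity_threshold"):
            if not (0 < getattr(self, name) <= 1):
                errors.append(f"{name} must be in (0, 1]")
        if self.n_repetitions < 1 or self.ratio < 1:
            errors.append("n_repetitions and ratio must be positive")
        if self.gamma < 1:
            errors.append("gamma must be >= 1")
        if self.window[0] >= self.window[1]:
            errors.append("window must satisfy young < old")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _scenario_config(cfg: RunConfig) -> synthetic.ScenarioConfig:
    if cfg.scenario == "default":
        return synthetic.default_scenario(seed=cfg.seed)
    if cfg.scenario == "constant":
        return synthetic.constant_scenario(seed=cfg.seed)
    if cfg.scenario == "collinear":
        return synthetic.collinear_scenario(seed=cfg.seed)
    raise ValueError(f"unknown scenario {cfg.scenario}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the whole analysis; returns the manifest (also written to
    output_dir/manifest.json). Any stage failure aborts with the stage
    name while preserving partial outputs."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(cfg).items()},
                      "stages": {}, "hashes": {}}
    t_all = _time.perf_counter()
    stage = "init"

    def done(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"seconds": round(_time.perf_counter() - t0, 3), **info}

    try:
        # ---- data ------------------------------------------------------
        stage = "data"
        t0 = _time.perf_counter()
        if cfg.scenario is not None:
            scen = _scenario_config(cfg)
            cube, niche, occ_raw = synthetic.generate_scenario(scen)
            write_climate_cube(cube, out / "climate.nc")
            synthetic.write_occurrences(occ_raw, out / "occurrences.csv")
            occ = filter_occurrences(occ_raw, window=cfg.window)
        else:
            cube = read_climate_cube(cfg.climate_path)
            occ = read_occurrences(cfg.occurrence_path, window=cfg.window)
        if cfg.species:
            occ = occ[occ["species"].isin(cfg.species)].reset_index(drop=True)
        done("data", t0, n_occurrences=int(len(occ)), n_slices=int(len(cube.ages)))

        # ---- collapse --------------------------------------------------
        stage = "collapse"
        t0 = _time.perf_counter()
        collapsed = collapse_occurrences(occ, cube)
        collapsed.to_csv(out / "collapsed.csv", index=False)
        done("collapse", t0, n_before=int(len(occ)), n_after=int(len(collapsed)))

        # ---- background ------------------------------------------------
        stage = "background"
        t0 = _time.perf_counter()
        reps = sample_background_repetitions(
            collapsed,
            cube,
            n_repetitions=cfg.n_repetitions,
            ratio=cfg.ratio,
            region=cfg.region,
            master_seed=cfg.seed,
        )
        reps.write(out / "background")
        done("background", t0, **reps.manifest())

        # ---- model tables + correlation screen -------------------------
        stage = "model_table"
        t0 = _time.perf_counter()
        table = build_model_table(collapsed, reps, cube)
        corr, corr_ok = correlation_screen(
            table[list(VARIABLES)], threshold=cfg.correlation_threshold
        )
        corr.to_csv(out / "correlation.csv")
        done("model_table", t0, n_rows=int(len(table)), correlation_ok=bool(corr_ok))

        # ---- fits ------------------------------------------------------
        stage = "fit"
        t0 = _time.perf_counter()
        env_vars = list(VARIABLES)
        f_const = make_formula(CONSTANT_NICHE, env_vars, k=cfg.k, k_time=cfg.k_time)
        f_chang = make_formula(CHANGING_NICHE, env_vars, k=cfg.k, k_time=cfg.k_time)
        fits_c, fits_g, conc_rows = {}, {}, []
        for rep in sorted(table["repetition"].unique()):
            sub = table[table["repetition"] == rep].reset_index(drop=True)
            fits_c[rep] = fit_gam(sub, f_const, gamma=cfg.gamma)
            fits_g[rep] = fit_gam(sub, f_chang, gamma=cfg.gamma)
            conc = concurvity(fits_g[rep])
            conc_rows.append({"repetition": rep, **conc.to_dict()})
            fits_c[rep].slim()
            fits_g[rep].X = None  # keep train_data for surfaces/BCI
        conc_df = pd.DataFrame(conc_rows).set_index("repetition")
        conc_df.to_csv(out / "concurvity.csv")
        done(
            "fit", t0,
            concurvity_ok=bool((conc_df.to_numpy() < cfg.concurvity_threshold).all()),
        )

        # ---- selection -------------------------------------------------
        stage = "select"
        t0 = _time.perf_counter()
        comparison = select_model(fits_c, fits_g)
        comparison.table.to_csv(out / "model_selection.csv")
        done("select", t0, **comparison.summary())

        # ---- evaluation + ensemble -------------------------------------
        stage = "ensemble"
        t0 = _time.perf_counter()
        pres_pts = pd.DataFrame(
            {
                "lon": collapsed["longitude"].to_numpy(dtype=float),
                "lat": collapsed["latitude"].to_numpy(dtype=float),
                "age_calBP": collapsed["age_calBP"].to_numpy(dtype=float),
            }
        )
        pres_env = extract_env(cube, pres_pts)
        pres_env = pres_env[pres_env["status"] == "ok"].reset_index(drop=True)
        avail_env = pd.concat([cube.env_at(a) for a in cube.ages], ignore_index=True)
        best, ensembles, per_fit_bci = build_ensemble(
            fits_g, pres_env, avail_env, bci_threshold=cfg.bci_threshold
        )
        pd.Series(per_fit_bci, name="bci").rename_axis("repetition").to_csv(out / "bci.csv")
        done(
            "ensemble", t0,
            method=best.method,
            bci={k: float(v.bci) for k, v in ensembles.items()},
            n_members=len(best.members),
            per_fit_bci={str(k): float(v) for k, v in per_fit_bci.items()},
        )

        # ---- variable importance (optional) ----------------------------
        if cfg.importance:
            stage = "importance"
            t0 = _time.perf_counter()
            accepted = [r for r, b in per_fit_bci.items() if b > cfg.bci_threshold]
            use = accepted[: cfg.importance_repetitions]
            imp = variable_importance(
                table[table["repetition"].isin(use)], f_chang, gamma=cfg.gamma
            )
            imp.table.to_csv(out / "importance.csv")
            done("importance", t0, repetitions=[int(u) for u in use])

        # ---- projection ------------------------------------------------
        stage = "project"
        t0 = _time.perf_counter()
        maps = project_all(best, cube)
        thr = mpa_threshold(best.predict(pres_env), coverage=cfg.mpa_coverage)
        binary = binarize_maps(maps, thr)
        summary = period_average(binary, cube)
        import xarray as xr

        suit = xr.Dataset(
            {"suitability": (("time", "lat", "lon"), np.stack([m.values for m in maps])),
             "binary": (("time", "lat", "lon"), np.stack(binary.maps))},
            coords={"time": cube.ages, "lat": cube.grid.lats, "lon": cube.grid.lons},
            attrs={"threshold": thr},
        )
        suit.to_netcdf(out / "projection.nc", engine="scipy")
        summary.to_dataset(cube).to_netcdf(out / "periods.nc", engine="scipy")
        done("project", t0, mpa_threshold=float(thr))

        # ---- interaction bundle ----------------------------------------
        stage = "surfaces"
        t0 = _time.perf_counter()
        members = best.members
        surfaces = {
            v: smooth_surface(members, v, times=cube.ages, n_value=cfg.n_value_grid)
            for v in env_vars
        }
        densities = {v: availability_density(cube, v) for v in env_vars}
        bundle = interaction_bundle(surfaces, pres_env, densities)
        bundle.write(out / "interaction")
        done("surfaces", t0, effect_scale=float(bundle.effect_scale))

    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    # ---- manifest ------------------------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["hashes"][str(path.relative_to(out))] = _hash_file(path)
    manifest["total_seconds"] = round(_time.perf_counter() - t_all, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    return manifest
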