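"""Time-matched random background sampling.

Presence/background niche models contrast the environments a species used
with the environments that were available; because availability itself
changed through the glacial cycle, background points must be matched in
time to the presences. For each presence, `ratio` (default 50) cells are
drawn uniformly, with replacement, from the land, ice-free cells of that
presence's time slice — so the background's empirical time distribution
equals the presences' exactly, scaled by the ratio. The draw is repeated
`n_repetitions` (default 25) times with independent seeds; the whole
analysis is repeated per draw and ensembled downstream. Presence cells are
not excluded: background represents availability, not absence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateCube


@dataclass
class RepetitionSet:
    """Per-repetition background tables (lon, lat, slice_calBP at cell
    centers) plus the seeds that produced them."""

    ratio: int
    seeds: dict = field(default_factory=dict)  # rep id -> integer seed
    tables: dict = field(default_factory=dict)  # rep id -> DataFrame

    @property
    def n_repetitions(self) -> int:
        return len(self.tables)

    def manifest(self) -> dict:
        return {
            "ratio": self.ratio,
            "n_repetitions": self.n_repetitions,
            "seeds": {str(k): int(v) for k, v in self.seeds.items()},
            "counts": {str(k): int(len(v)) for k, v in self.tables.items()},
        }

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rep_id, table in self.tables.items():
            table.to_csv(outdir / f"background_rep{rep_id:03d}.csv", index=False)
        with open(outdir / "background_manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)


def sample_background_repetitions(
    presences: pd.DataFrame,
    cube: ClimateCube,
    n_repetitions: int = 25,
    ratio: int = 50,
    region: tuple | None = None,
    master_seed: int = 0,
) -> RepetitionSet:
    """Draw `n_repetitions` independent background sets for a collapsed
    presence table.

    ``region`` is an optional (lon_min, lon_max, lat_min, lat_max) bounding
    box restricting eligible cells (default: full cube extent). Eligible
    cells of a slice are its land, ice-free cells; a slice with presences
    but no eligible cell raises, naming the slice. Reproducible from
    ``master_seed`` via spawned per-repetition seeds.
    """
    if n_repetitions < 1 or ratio < 1:
        raise ValueError("n_repetitions and ratio must be positive")
    if "slice_calBP" in presences.columns:
        slices = presences["slice_calBP"].to_numpy(dtype=float)
    else:
        from .climate import nearest_slice

        slices = np.atleast_1d(nearest_slice(presences["age_calBP"].to_numpy(dtype=float), cube.ages))
    counts = pd.Series(slices).value_counts().sort_index()

    lons, lats = cube.grid.lons, cube.grid.lats
    lon2d, lat2d = np.meshgrid(lons, lats)
    in_region = np.ones_like(lon2d, dtype=bool)
    if region is not None:
        lo, hi, blo, bhi = region
        in_region = (lon2d >= lo) & (lon2d <= hi) & (lat2d >= blo) & (lat2d <= bhi)

    eligible = {}
    for age in counts.index:
        ok = cube.available(age) & in_region
        if not ok.any():
            raise ValueError(f"slice {age:.0f}: no eligible background cells")
        rows, cols = np.nonzero(ok)
        eligible[age] = (lons[cols], lats[rows])

    child_seeds = np.random.SeedSequence(master_seed).generate_state(n_repetitions) % (2**31)
    seeds, tables = {}, {}
    for rep_id in range(n_repetitions):
        seed = int(child_seeds[rep_id])
        rng = np.random.default_rng(seed)
        parts = []
        for age, n_pres in counts.items():
            cell_lon, cell_lat = eligible[age]
            n_draw = ratio * int(n_pres)
            idx = rng.integers(0, len(cell_lon), size=n_draw)
            parts.append(
                pd.DataFrame(
                    {"lon": cell_lon[idx], "lat": cell_lat[idx], "slice_calBP": age}
                )
            )
        seeds[rep_id] = seed
        tables[rep_id] = pd.concat(parts, ignore_index=True)
    return RepetitionSet(ratio=ratio, seeds=seeds, tables=tables)
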