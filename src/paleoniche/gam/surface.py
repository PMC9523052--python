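"""Partial-effect surfaces of environment x time smooths.

The changing-niche story is read off heatmaps of a term's effect (link
scale, centered by the model's sum-to-zero constraint) on a grid of
(time, variable value): red regions are used more than availability would
suggest, blue less, and a sign flip along time at some value band marks a
niche change. For a constant-niche fit the surface is constant along the
time axis by construction. Grid nodes far from any training datum are
masked, since the smooth is unsupported there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import FittedGAM


@dataclass
class InteractionSurface:
    variable: str
    times: np.ndarray  # n_time, years BP ascending
    values: np.ndarray  # n_value, variable units
    effect: np.ndarray  # (n_value, n_time), link scale
    included: np.ndarray  # same shape, True where supported by data

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.where(self.included, self.effect, np.nan),
            index=pd.Index(self.values, name=self.variable),
            columns=pd.Index(self.times, name="age_calBP"),
        )
        return df


def _term_label(fit: FittedGAM, variable: str) -> str:
    for block in fit.blocks:
        if block.margins[0].var == variable:
            return block.label
    raise KeyError(f"variable {variable} not in model formula")


def smooth_surface(
    fits,
    variable: str,
    times=None,
    values=None,
    n_value: int = 40,
    time_tol: float = 2_500.0,
    value_tol_frac: float = 0.15,
) -> InteractionSurface:
    """Pointwise mean partial-effect surface across fits.

    All fits must share the formula kind. The grid defaults to the first
    fit's training ranges (times: unique training slice ages; values:
    ``n_value`` equally spaced points). A node is included if some
    training datum lies within ``time_tol`` years and ``value_tol_frac``
    of the value range of it.
    """
    if isinstance(fits, FittedGAM):
        fits = [fits]
    if not fits:
        raise ValueError("need at least one fit")
    kinds = {f.formula.kind for f in fits}
    if len(kinds) > 1:
        raise ValueError("fits mix model kinds")
    label = _term_label(fits[0], variable)

    ref = fits[0]
    tdat = ref.train_data
    if tdat is None:
        raise ValueError("reference fit has no stored training data (slimmed)")
    x_train = np.asarray(tdat[variable], dtype=float)
    t_train = np.asarray(tdat["time"], dtype=float) if "time" in tdat else np.zeros_like(x_train)
    if times is None:
        times = np.unique(t_train)
    times = np.asarray(times, dtype=float)
    if values is None:
        values = np.linspace(x_train.min(), x_train.max(), n_value)
    values = np.asarray(values, dtype=float)

    tt, vv = np.meshgrid(times, values)
    grid = pd.DataFrame({variable: vv.ravel(), "time": tt.ravel()})

    acc = np.zeros(vv.shape)
    for f in fits:
        eff = f.term_effect(_term_label(f, variable), grid).reshape(vv.shape)
        acc += eff
    acc /= len(fits)

    vtol = value_tol_frac * (x_train.max() - x_train.min())
    included = np.zeros(vv.shape, dtype=bool)
    # support check per time column against data near that time
    for j, t in enumerate(times):
        near = np.abs(t_train - t) <= time_tol
        if not near.any():
            continue
        xs = x_train[near]
        d = np.min(np.abs(values[:, None] - xs[None, :]), axis=1)
        included[:, j] = d <= vtol
    return InteractionSurface(
        variable=variable, times=times, values=values, effect=acc, included=included
    )
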