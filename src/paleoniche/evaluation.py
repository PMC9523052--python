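"""Model selection, the Continuous Boyce Index, variable importance and
ensembles.

Constant- vs changing-niche support is judged per background repetition by
AIC; the headline summary is the fraction of repetitions favouring the
changing-niche model. Predictive adequacy of each changing-niche fit is
scored with the Continuous Boyce Index (BCI): sliding suitability windows
over the available-environment predictions, the ratio F = P/E of the
presence share to the availability share per window should increase with
suitability, and BCI is the Spearman correlation of F with the window
midpoints. Fits with BCI above the acceptance threshold (default 0.8) are
combined into mean and median ensembles, and the higher-BCI ensemble is
carried forward.

Variable importance is deviance-partitioned: a variable's *total* deviance
explained comes from a model containing only that variable (with its time
tensor, so the comparison stays within the changing-niche family), its
*unique* contribution is the full-model deviance explained lost by
dropping it; the difference is deviance shared with other variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gam import FittedGAM, ModelFormula, fit_gam, make_formula


# -- model selection -----------------------------------------------------


@dataclass
class ModelComparison:
    table: pd.DataFrame  # per repetition: aic_constant, aic_changing, delta_aic, winner
    fraction_changing: float

    def summary(self) -> dict:
        return {
            "fraction_changing": self.fraction_changing,
            "n_repetitions": int(len(self.table)),
            "mean_delta_aic": float(self.table["delta_aic"].mean()),
        }


def select_model(fits_constant: dict, fits_changing: dict) -> ModelComparison:
    """Per-repetition AIC comparison of paired constant/changing fits.

    delta_aic = AIC(constant) - AIC(changing); the winner is the lower-AIC
    model, with exact ties reported as 'tie'. Support is only called
    decisive when |delta| > 2.
    """
    if set(fits_constant) != set(fits_changing):
        raise ValueError("unpaired repetition ids")
    rows = []
    for rep in sorted(fits_constant):
        fc, fg = fits_constant[rep], fits_changing[rep]
        delta = fc.aic - fg.aic
        winner = "tie" if delta == 0 else ("changing" if delta > 0 else "constant")
        rows.append(
            {
                "repetition": rep,
                "aic_constant": fc.aic,
                "aic_changing": fg.aic,
                "delta_aic": delta,
                "winner": winner,
                "decisive": abs(delta) > 2,
                "dev_explained_constant": fc.dev_explained,
                "dev_explained_changing": fg.dev_explained,
                "nagelkerke_constant": fc.nagelkerke,
                "nagelkerke_changing": fg.nagelkerke,
            }
        )
    table = pd.DataFrame(rows).set_index("repetition")
    frac = float((table["winner"] == "changing").mean())
    return ModelComparison(table=table, fraction_changing=frac)


# -- Continuous Boyce Index ----------------------------------------------


@dataclass
class BoyceResult:
    midpoints: np.ndarray
    f_ratio: np.ndarray
    bci: float
    threshold: float = 0.8

    @property
    def accepted(self) -> bool:
        return self.bci > self.threshold


def boyce_index(
    pred_presence,
    pred_available,
    n_windows: int = 101,
    window_fraction: float = 0.1,
    threshold: float = 0.8,
) -> BoyceResult:
    """Continuous Boyce Index of presence predictions against the
    available-environment prediction distribution.

    ``n_windows`` overlapping windows of width ``window_fraction`` x range
    slide over [min, max] of the available predictions; per window,
    F = (share of presences inside) / (share of available inside), and the
    BCI is the Spearman rank correlation of F with the window midpoints
    (windows with zero availability are dropped).
    """
    p = np.asarray(pred_presence, dtype=float)
    a = np.asarray(pred_available, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("prediction vectors must be non-empty")
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        raise ValueError("all available predictions identical; BCI undefined")
    width = window_fraction * (hi - lo)
    starts = lo + (hi - lo - width) * np.arange(n_windows) / (n_windows - 1)
    mids, fs = [], []
    for s in starts:
        e_share = np.mean((a >= s) & (a <= s + width))
        if e_share == 0:
            continue
        p_share = np.mean((p >= s) & (p <= s + width))
        mids.append(s + width / 2)
        fs.append(p_share / e_share)
    mids = np.asarray(mids)
    fs = np.asarray(fs)
    if len(fs) < 2 or np.all(fs == fs[0]):
        raise ValueError("degenerate P/E profile; BCI undefined")
    rho = stats.spearmanr(fs, mids).statistic
    return BoyceResult(midpoints=mids, f_ratio=fs, bci=float(rho), threshold=threshold)


def boyce_for_fit(
    fit: FittedGAM,
    presence_env: pd.DataFrame,
    available_env: pd.DataFrame,
    **kw,
) -> BoyceResult:
    return boyce_index(fit.predict(presence_env), fit.predict(available_env), **kw)


# -- variable importance -------------------------------------------------


@dataclass
class ImportanceTable:
    table: pd.DataFrame  # index: variable; columns: total, unique, shared


def variable_importance(
    data: pd.DataFrame,
    formula: ModelFormula,
    gamma: float = 1.4,
    criterion: str = "reml",
    repetitions=None,
) -> ImportanceTable:
    """Deviance-partition importance for one model table (optionally
    averaged over its ``repetition`` values).

    total(v) = deviance explained by the single-variable model;
    unique(v) = full-model deviance explained minus the drop-v model's;
    shared = total - unique. Mild penalization can push unique a hair
    negative; values are clipped at 0 and the slack is documented.
    """
    if repetitions is None:
        if "repetition" in data.columns:
            repetitions = sorted(data["repetition"].unique())
        else:
            repetitions = [None]
    variables = list(formula.env_variables)
    time_main = any(s.variables == ("time",) for s in formula.smooths)
    acc = {v: {"total": [], "unique": []} for v in variables}
    for rep in repetitions:
        sub = data if rep is None else data[data["repetition"] == rep]
        full = fit_gam(sub, formula, gamma=gamma, criterion=criterion, keep_design=False)
        for v in variables:
            single = make_formula(formula.kind, [v], k={v: _k_of(formula, v)},
                                  k_time=_ktime_of(formula), time_main=time_main)
            drop = make_formula(
                formula.kind,
                [u for u in variables if u != v],
                k={u: _k_of(formula, u) for u in variables if u != v},
                k_time=_ktime_of(formula),
                time_main=time_main,
            )
            f_single = fit_gam(sub, single, gamma=gamma, criterion=criterion, keep_design=False)
            f_drop = fit_gam(sub, drop, gamma=gamma, criterion=criterion, keep_design=False)
            acc[v]["total"].append(f_single.dev_explained)
            acc[v]["unique"].append(max(0.0, full.dev_explained - f_drop.dev_explained))
    rows = []
    for v in variables:
        total = float(np.mean(acc[v]["total"]))
        unique = float(np.mean(acc[v]["unique"]))
        rows.append({"variable": v, "total": total, "unique": unique, "shared": total - unique})
    return ImportanceTable(table=pd.DataFrame(rows).set_index("variable"))


def _k_of(formula: ModelFormula, var: str) -> int:
    for s in formula.smooths:
        if s.variables[0] == var:
            return s.k[0]
    raise KeyError(var)


def _ktime_of(formula: ModelFormula) -> int:
    for s in formula.smooths:
        if len(s.k) > 1:
            return s.k[1]
    return 5


# -- ensembles -----------------------------------------------------------


@dataclass
class EnsemblePrediction:
    """Aggregate of accepted member fits; callable like a fit."""

    method: str  # "mean" or "median"
    members: list = field(repr=False, default_factory=list)
    member_bci: list = field(default_factory=list)
    bci: float | None = None

    def predict(self, data) -> np.ndarray:
        preds = np.stack([m.predict(data) for m in self.members])
        agg = np.mean(preds, axis=0) if self.method == "mean" else np.median(preds, axis=0)
        return np.clip(agg, 1e-12, 1 - 1e-12)


def build_ensemble(
    fits: dict,
    presence_env: pd.DataFrame,
    available_env: pd.DataFrame,
    bci_threshold: float = 0.8,
    n_windows: int = 101,
    window_fraction: float = 0.1,
):
    """Score every fit by BCI, keep those above the threshold, build both
    mean and median ensembles and flag the higher-BCI one as best.

    Returns (best, {"mean": ..., "median": ...}, per_fit_bci). Raises if no
    fit is accepted, reporting each repetition's BCI.
    """
    per_fit = {}
    accepted = []
    for rep, fit in sorted(fits.items()):
        res = boyce_for_fit(
            fit, presence_env, available_env,
            n_windows=n_windows, window_fraction=window_fraction,
            threshold=bci_threshold,
        )
        per_fit[rep] = res.bci
        if res.accepted:
            accepted.append((rep, fit, res.bci))
    if not accepted:
        raise ValueError(f"no fit exceeded BCI {bci_threshold}; per-repetition BCI: {per_fit}")
    ensembles = {}
    for method in ("mean", "median"):
        ens = EnsemblePrediction(
            method=method,
            members=[f for _, f, _ in accepted],
            member_bci=[b for _, _, b in accepted],
        )
        res = boyce_index(
            ens.predict(presence_env),
            ens.predict(available_env),
            n_windows=n_windows,
            window_fraction=window_fraction,
            threshold=bci_threshold,
        )
        ens.bci = res.bci
        ensembles[method] = ens
    best = max(ensembles.values(), key=lambda e: e.bci)
    return best, ensembles, per_fit
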