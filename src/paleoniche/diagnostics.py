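"""Pre- and post-fit model checks.

Four families of checks guard the niche-change inference:

* a Pearson correlation screen on the environmental variables (fail at
  |r| >= 0.7, the usual collinearity rule of thumb for distribution
  models);
* concurvity — the smooth-model analogue of collinearity: the share of a
  fitted term's variance reproducible by projection onto the other terms'
  column space (pass below 0.8);
* simulation-based randomized-quantile residual tests (uniformity,
  dispersion, outliers), the standard scheme for binary GLM/GAM residuals
  where raw residuals are uninformative;
* Moran's I on residuals with inverse great-circle-distance weights
  within each time slice (zero across slices), with a permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gam import FittedGAM

EARTH_RADIUS_KM = 6371.0


# -- correlation screen --------------------------------------------------


def correlation_screen(env: pd.DataFrame, threshold: float = 0.7):
    """Pairwise Pearson correlations; verdict fails if any off-diagonal
    |r| >= threshold. Zero-variance variables give NaN pairs + warning."""
    if len(env) < 3:
        raise ValueError("need at least 3 rows")
    num = env.select_dtypes(include=[np.number])
    sd = num.std(ddof=1)
    if (sd == 0).any():
        warnings.warn(f"zero-variance variables: {list(sd.index[sd == 0])}")
    corr = num.corr()
    off = corr.where(~np.eye(len(corr), dtype=bool)).abs().to_numpy()
    finite = off[np.isfinite(off)]
    max_r = float(finite.max()) if finite.size else 0.0
    return corr, max_r < threshold


# -- concurvity ----------------------------------------------------------


def concurvity(fit: FittedGAM) -> pd.Series:
    """Per-term 'estimate' concurvity: R^2 of projecting the term's fitted
    component onto the span of the intercept and all other terms' columns.
    Values in [0, 1]; empty for single-term models."""
    if fit.X is None:
        raise ValueError("fit has no stored design matrix (slimmed)")
    if len(fit.blocks) < 2:
        return pd.Series(dtype=float)
    out = {}
    n = fit.X.shape[0]
    for block, sl in zip(fit.blocks, fit.slices):
        f = fit.X[:, sl] @ fit.beta[sl]
        others = [np.ones((n, 1))]
        for b2, sl2 in zip(fit.blocks, fit.slices):
            if b2 is not block:
                others.append(fit.X[:, sl2])
        Q = np.concatenate(others, axis=1)
        coef, *_ = np.linalg.lstsq(Q, f, rcond=None)
        g = Q @ coef
        denom = float(f @ f)
        out[block.label] = float(np.clip((g @ g) / denom, 0, 1)) if denom > 0 else 0.0
    return pd.Series(out, name="concurvity")


# -- randomized quantile residuals ---------------------------------------


@dataclass
class ResidualTests:
    residuals: np.ndarray  # PIT residuals, uniform under the model
    uniformity_p: float
    dispersion_ratio: float
    dispersion_p: float
    n_outliers: int
    outlier_p: float

    def passed(self, alpha: float = 0.05) -> bool:
        return min(self.uniformity_p, self.dispersion_p, self.outlier_p) >= alpha


def residual_checks(fit: FittedGAM, n_sim: int = 250, seed: int = 0) -> ResidualTests:
    """Simulation-based residual diagnostics for the binomial fit.

    ``n_sim`` response vectors are simulated from the fitted Bernoulli
    probabilities. Each observation's randomized (PIT) quantile residual
    is its observed value's rank among the simulations with uniform
    jitter over ties; under a well-specified model these are U(0,1)
    (Kolmogorov-Smirnov test). Dispersion compares the observed Pearson
    chi-square statistic with its simulated distribution (two-sided
    empirical p). Outliers are observations outside the simulated range;
    for a Bernoulli response the chance of that is (1-mu)^n_sim for a
    presence and mu^n_sim for an absence, so the observed count is tested
    two-sided against a Poisson with the summed per-row probabilities.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if fit.mu is None or fit.y is None:
        raise ValueError("fit has no stored training response (slimmed)")
    rng = np.random.default_rng(seed)
    mu = np.clip(fit.mu, 1e-10, 1 - 1e-10)
    y = fit.y
    n = len(y)
    sims = rng.random((n_sim, n)) < mu[None, :]  # simulated Bernoulli draws

    # PIT residual: P(sim < y) + U * P(sim == y)
    p_less = np.where(y == 1, (~sims).mean(axis=0), 0.0)
    p_equal = np.where(y == 1, sims.mean(axis=0), (~sims).mean(axis=0))
    resid = p_less + rng.random(n) * p_equal
    uniformity_p = float(stats.kstest(resid, "uniform").pvalue)

    denom = mu * (1 - mu)
    chi_obs = float(np.sum((y - mu) ** 2 / denom))
    chi_sim = np.sum((sims - mu[None, :]) ** 2 / denom[None, :], axis=1)
    ratio = chi_obs / float(np.mean(chi_sim))
    p_hi = (1 + np.sum(chi_sim >= chi_obs)) / (n_sim + 1)
    p_lo = (1 + np.sum(chi_sim <= chi_obs)) / (n_sim + 1)
    dispersion_p = float(min(1.0, 2 * min(p_hi, p_lo)))

    all_one = sims.all(axis=0)
    all_zero = (~sims).all(axis=0)
    outlier = ((y == 1) & all_zero) | ((y == 0) & all_one)
    n_out = int(outlier.sum())
    lam_out = float(np.sum(mu * (1 - mu) ** n_sim + (1 - mu) * mu**n_sim))
    p_out_hi = float(stats.poisson.sf(n_out - 1, lam_out))
    p_out_lo = float(stats.poisson.cdf(n_out, lam_out))
    outlier_p = min(1.0, 2 * min(p_out_hi, p_out_lo))

    return ResidualTests(
        residuals=resid,
        uniformity_p=uniformity_p,
        dispersion_ratio=ratio,
        dispersion_p=dispersion_p,
        n_outliers=n_out,
        outlier_p=outlier_p,
    )


# -- Moran's I -----------------------------------------------------------


def _great_circle_km(lon, lat) -> np.ndarray:
    """Pairwise haversine distances (km)."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def moran_weights(
    lon,
    lat,
    slices=None,
    max_distance_km: float | None = None,
    min_distance_km: float = 1.0,
) -> np.ndarray:
    """Row-standardized inverse-distance weights; pairs in different time
    slices get weight zero. Coincident points are floored at
    ``min_distance_km`` to avoid infinite weights."""
    d = _great_circle_km(lon, lat)
    np.fill_diagonal(d, np.inf)
    d = np.maximum(d, min_distance_km)
    w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if slices is not None:
        s = np.asarray(slices)
        w = w * (s[:, None] == s[None, :])
    if max_distance_km is not None:
        w = w * (d <= max_distance_km)
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return w / rs


@dataclass
class MoranResult:
    estimate: float
    p_value: float
    expected: float  # -1/(n-1)
    perm_values: np.ndarray = field(repr=False, default=None)


def morans_i(
    residuals,
    lon,
    lat,
    slices=None,
    n_perm: int = 999,
    seed: int = 0,
    max_distance_km: float | None = None,
) -> MoranResult:
    """Moran's I of residuals under within-slice inverse-distance weights,
    with a permutation p-value (two-sided on the permutation null)."""
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 points")
    if not np.all(np.isfinite(x)):
        raise ValueError("residuals must be finite")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.all(lon == lon[0]) and np.all(lat == lat[0]):
        raise ValueError("all points at the same location")
    W = moran_weights(lon, lat, slices, max_distance_km=max_distance_km)
    s0 = W.sum()

    def stat(v):
        vc = v - v.mean()
        return float(n / s0 * (vc @ W @ vc) / (vc @ vc))

    obs = stat(x)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    xp = x.copy()
    for i in range(n_perm):
        rng.shuffle(xp)
        perms[i] = stat(xp)
    p_hi = (1 + np.sum(perms >= obs)) / (n_perm + 1)
    p_lo = (1 + np.sum(perms <= obs)) / (n_perm + 1)
    p = min(1.0, 2 * min(p_hi, p_lo))
    return MoranResult(
        estimate=obs, p_value=float(p), expected=-1.0 / (n - 1), perm_values=perms
    )


def moran_verdict(result: MoranResult, alpha: float = 0.05, trivial_i: float = 0.1) -> bool:
    """Spatial autocorrelation is deemed unproblematic if the test is
    non-significant or the estimate is trivially small."""
    return result.p_value >= alpha or abs(result.estimate) < trivial_i


# -- bundled report ------------------------------------------------------


@dataclass
class DiagnosticsReport:
    correlation: pd.DataFrame
    correlation_ok: bool
    concurvity: pd.Series
    concurvity_ok: bool
    residual_tests: ResidualTests | None = None
    moran: MoranResult | None = None
    thresholds: dict = field(
        default_factory=lambda: {"correlation": 0.7, "concurvity": 0.8}
    )

    def to_dict(self) -> dict:
        out = {
            "correlation_max_abs": float(
                np.nanmax(
                    self.correlation.where(~np.eye(len(self.correlation), dtype=bool))
                    .abs()
                    .to_numpy()
                )
            ),
            "correlation_ok": bool(self.correlation_ok),
            "concurvity": {k: float(v) for k, v in self.concurvity.items()},
            "concurvity_ok": bool(self.concurvity_ok),
            "thresholds": self.thresholds,
        }
        if self.residual_tests is not None:
            rt = self.residual_tests
            out["residuals"] = {
                "uniformity_p": rt.uniformity_p,
                "dispersion_ratio": rt.dispersion_ratio,
                "dispersion_p": rt.dispersion_p,
                "n_outliers": rt.n_outliers,
                "outlier_p": rt.outlier_p,
            }
        if self.moran is not None:
            out["moran"] = {
                "estimate": self.moran.estimate,
                "p_value": self.moran.p_value,
                "expected": self.moran.expected,
            }
        return out


def diagnose_fit(
    fit: FittedGAM,
    env: pd.DataFrame,
    corr_threshold: float = 0.7,
    concurvity_threshold: float = 0.8,
    n_sim: int = 0,
    moran_sample: int = 0,
    seed: int = 0,
) -> DiagnosticsReport:
    """Convenience wrapper running the screen + concurvity and, when
    requested (n_sim/moran_sample > 0), the simulation-based checks."""
    corr, corr_ok = correlation_screen(env, threshold=corr_threshold)
    conc = concurvity(fit)
    conc_ok = bool((conc < concurvity_threshold).all()) if len(conc) else True
    report = DiagnosticsReport(
        correlation=corr,
        correlation_ok=corr_ok,
        concurvity=conc,
        concurvity_ok=conc_ok,
        thresholds={"correlation": corr_threshold, "concurvity": concurvity_threshold},
    )
    if n_sim > 0:
        report.residual_tests = residual_checks(fit, n_sim=n_sim, seed=seed)
    if moran_sample > 0 and fit.train_data is not None and fit.mu is not None:
        td = fit.train_data
        n = len(td)
        take = np.random.default_rng(seed).choice(
            n, size=min(moran_sample, n), replace=False
        )
        resid = (fit.y - fit.mu) / np.sqrt(fit.mu * (1 - fit.mu))
        report.moran = morans_i(
            resid[take],
            td["lon"].to_numpy()[take],
            td["lat"].to_numpy()[take],
            slices=td["time"].to_numpy()[take],
            n_perm=199,
            seed=seed,
        )
    return report
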