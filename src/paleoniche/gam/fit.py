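"""Binomial GAM fitting: penalized IRLS with automatic smoothness selection.

The model is logit P(presence) = alpha + sum of smooth terms, each term a
penalized spline block from :mod:`.basis`. For fixed smoothing parameters
the coefficients solve a penalized iteratively-reweighted-least-squares
problem; the smoothing parameters themselves are chosen by a REML-type
criterion using the generalized Fellner-Schall update, which iterates

    lambda_j <- lambda_j * [tr(S_lambda^- S_j) - tr((X'WX + S_lambda)^-1 S_j)]
                / (beta' S_j beta)

to the (Laplace-approximate) marginal-likelihood optimum at the cost of
one linear solve per penalty per iteration. AICc and GCV are available as
alternative criteria via coordinate-wise golden-section search.

The extra complexity guard gamma (default 1.4) tempers the likelihood
during selection (log-likelihood divided by gamma, the standard REML
semantics), biasing the fit toward smoother solutions; for the AICc/GCV
criteria it instead multiplies the effective degrees of freedom. Effective
degrees of freedom are the trace of the influence matrix
(X'WX + S)^-1 X'WX, with per-term edf as the partial traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .basis import (
    DEFAULT_K_TIME,
    BasisBlock,
    SmoothSpec,
    build_block,
    default_k,
)

CONSTANT_NICHE = "constant_niche"
CHANGING_NICHE = "changing_niche"


class GamConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass
class ModelFormula:
    """Constant-niche (one univariate smooth per environmental variable)
    or changing-niche (one variable x time tensor smooth per variable).

    Both standard formulas also carry one univariate smooth of time
    itself: presences are quota-sampled per slice, so the implied
    per-slice normalization offset varies through time and must be
    absorbed somewhere — the tensor blocks deliberately exclude pure-time
    functions, so without this term the offset would masquerade as niche
    change.
    """

    kind: str
    smooths: list

    def __post_init__(self) -> None:
        if self.kind not in (CONSTANT_NICHE, CHANGING_NICHE):
            raise ValueError(f"unknown model kind {self.kind}")
        seen = [s.variables[0] for s in self.smooths]
        if len(seen) != len(set(seen)):
            raise ValueError("each variable may appear only once")

    @property
    def env_variables(self) -> tuple:
        return tuple(
            s.variables[0] for s in self.smooths if s.variables[0] != "time"
        )


def make_formula(
    kind: str,
    variables,
    k: dict | None = None,
    k_time: int = DEFAULT_K_TIME,
    time_var: str = "time",
    time_main: bool = True,
) -> ModelFormula:
    """Standard formula for a variable set; ``k`` overrides per-variable
    marginal basis dimensions (defaults: 16 for BIO6, 10 otherwise).
    ``time_main`` adds the pure-time normalization smooth (shared by both
    model kinds, so AIC differences reflect only interaction structure)."""
    k = k or {}
    smooths = []
    for var in variables:
        kv = k.get(var, default_k(var))
        if kind == CONSTANT_NICHE:
            smooths.append(SmoothSpec(variables=(var,), k=(kv,)))
        else:
            smooths.append(SmoothSpec(variables=(var, time_var), k=(kv, k_time)))
    if time_main:
        smooths.append(SmoothSpec(variables=(time_var,), k=(k.get(time_var, k_time),)))
    return ModelFormula(kind=kind, smooths=smooths)


# -- linear algebra helpers ----------------------------------------------


def _xtwx(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    A = X * np.sqrt(w)[:, None]
    return A.T @ A


def _solve_spd(A: np.ndarray, b: np.ndarray):
    """Cholesky solve with escalating jitter for near-singular systems."""
    scale = np.mean(np.diag(A)) or 1.0
    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            c, low = linalg.cho_factor(
                A + jitter * scale * np.eye(A.shape[0]), lower=True, check_finite=False
            )
            return linalg.cho_solve((c, low), b, check_finite=False), (c, low)
        except linalg.LinAlgError:
            continue
    raise GamConvergenceError("penalized normal equations are singular", trace=[])


def _deviance(y, mu, m) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(m * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))


def _pirls(X, y, m, S_total, beta0=None, max_iter=200, tol=1e-8):
    """Penalized IRLS for fixed penalty matrix. Converges on relative
    change of the penalized deviance; raises on non-convergence with the
    iteration trace attached."""
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        prev = float(np.sum(m * y))
        beta[0] = np.log((prev + 0.5) / (np.sum(m) - prev + 0.5))
    else:
        beta = beta0.copy()
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    obj = _deviance(y, mu, m) + float(beta @ S_total @ beta)
    trace = [obj]
    converged = False
    for it in range(max_iter):
        wq = np.clip(mu * (1 - mu), 1e-10, None)
        w = m * wq
        z = eta + (y - mu) / wq
        XtWX = _xtwx(X, w)
        XtWz = X.T @ (w * z)
        beta_new, _ = _solve_spd(XtWX + S_total, XtWz)
        # step-halving keeps the penalized deviance monotone; if no step
        # length improves the objective we are at a numerical stationary
        # point and stop
        step = 1.0
        improved = False
        for _ in range(25):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            mu_c = 1.0 / (1.0 + np.exp(-np.clip(eta_c, -35, 35)))
            obj_c = _deviance(y, mu_c, m) + float(cand @ S_total @ cand)
            if np.isfinite(obj_c) and obj_c <= obj + 1e-10 * (abs(obj) + 1):
                improved = True
                break
            step /= 2
        if not improved:
            converged = True
            break
        beta, eta, mu = cand, eta_c, mu_c
        trace.append(obj_c)
        if abs(obj - obj_c) < tol * (abs(obj_c) + 0.1):
            obj = obj_c
            converged = True
            break
        obj = obj_c
    if not converged:
        raise GamConvergenceError(
            f"PIRLS did not converge in {max_iter} iterations", trace=trace
        )
    return beta, mu, trace


@dataclass
class FittedGAM:
    """A fitted penalized binomial GAM with its scores.

    Satisfies AIC = -2*loglik + 2*edf_total; deviance <= null_deviance;
    per-term edf <= per-term basis size.
    """

    formula: ModelFormula
    blocks: list
    beta: np.ndarray
    slices: list  # column slice per block (intercept is column 0)
    lambdas: np.ndarray  # selected smoothing parameters, one per penalty
    penalty_block: list  # block index of each penalty
    gamma: float
    criterion: str
    edf_total: float
    edf_aic: float
    edf_per_term: dict
    loglik: float
    null_deviance: float
    deviance: float
    aic: float
    dev_explained: float
    nagelkerke: float
    n_obs: float
    converged: bool
    n_outer: int
    separated: bool = False
    # training references (dropped by slim())
    X: np.ndarray | None = None
    y: np.ndarray | None = None
    weights: np.ndarray | None = None
    mu: np.ndarray | None = None
    train_data: pd.DataFrame | None = None

    def slim(self) -> "FittedGAM":
        """Drop the stored design matrix and training rows (keeps
        everything prediction and scoring need)."""
        self.X = self.y = self.weights = self.mu = None
        self.train_data = None
        return self

    # -- prediction ------------------------------------------------------

    def linear_predictor(self, data) -> np.ndarray:
        eta = np.full(len(data), self.beta[0], dtype=float)
        for block, sl in zip(self.blocks, self.slices):
            eta += block.design(data) @ self.beta[sl]
        return eta

    def predict(self, data, return_flags: bool = False):
        eta = self.linear_predictor(data)
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        if not return_flags:
            return prob
        flags = np.zeros(len(data), dtype=bool)
        for block in self.blocks:
            for var, (lo, hi) in block.train_range.items():
                pad = 0.05 * (hi - lo)
                x = np.asarray(data[var], dtype=float)
                flags |= (x < lo - pad) | (x > hi + pad)
        return prob, flags

    def term_effect(self, label: str, data) -> np.ndarray:
        for block, sl in zip(self.blocks, self.slices):
            if block.label == label:
                return block.design(data) @ self.beta[sl]
        raise KeyError(f"no term {label} in model")

    def scores(self) -> dict:
        return {
            "aic": self.aic,
            "dev_explained": self.dev_explained,
            "nagelkerke_r2": self.nagelkerke,
            "loglik": self.loglik,
            "edf": self.edf_total,
        }

    def to_dict(self) -> dict:
        return {
            "kind": self.formula.kind,
            "smooths": [
                {
                    "variables": list(s.variables),
                    "k": list(s.k),
                    "degree": s.degree,
                    "penalty_order": s.penalty_order,
                    "basis": s.basis,
                }
                for s in self.formula.smooths
            ],
            "blocks": [b.to_dict() for b in self.blocks],
            "beta": self.beta.tolist(),
            "slices": [[sl.start, sl.stop] for sl in self.slices],
            "lambdas": self.lambdas.tolist(),
            "penalty_block": list(self.penalty_block),
            "gamma": self.gamma,
            "criterion": self.criterion,
            "scores": self.scores(),
            "edf_aic": self.edf_aic,
            "edf_per_term": self.edf_per_term,
            "null_deviance": self.null_deviance,
            "deviance": self.deviance,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_outer": self.n_outer,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedGAM":
        formula = ModelFormula(
            kind=d["kind"],
            smooths=[
                SmoothSpec(
                    variables=tuple(s["variables"]),
                    k=tuple(s["k"]),
                    degree=s["degree"],
                    penalty_order=s["penalty_order"],
                    basis=s["basis"],
                )
                for s in d["smooths"]
            ],
        )
        sc = d["scores"]
        return cls(
            formula=formula,
            blocks=[BasisBlock.from_dict(b) for b in d["blocks"]],
            beta=np.asarray(d["beta"], dtype=float),
            slices=[slice(a, b) for a, b in d["slices"]],
            lambdas=np.asarray(d["lambdas"], dtype=float),
            penalty_block=list(d["penalty_block"]),
            gamma=d["gamma"],
            criterion=d["criterion"],
            edf_total=sc["edf"],
            edf_aic=float(d["edf_aic"]),
            edf_per_term={k: float(v) for k, v in d["edf_per_term"].items()},
            loglik=sc["loglik"],
            null_deviance=d["null_deviance"],
            deviance=d["deviance"],
            aic=sc["aic"],
            dev_explained=sc["dev_explained"],
            nagelkerke=sc["nagelkerke_r2"],
            n_obs=d["n_obs"],
            converged=d["converged"],
            n_outer=d["n_outer"],
        )


def _assemble(blocks):
    """Column slices and embedded-penalty bookkeeping for [1 | blocks]."""
    slices, penalties, penalty_block = [], [], []
    col = 1
    for bi, block in enumerate(blocks):
        sl = slice(col, col + block.ncol)
        slices.append(sl)
        for S in block.penalties:
            penalties.append((sl, S))
            penalty_block.append(bi)
        col += block.ncol
    return slices, penalties, penalty_block, col


def _total_penalty(p, penalties, lam):
    S = np.zeros((p, p))
    for (sl, Sj), lj in zip(penalties, lam):
        S[sl, sl] += lj * Sj
    return S


def _structural_ranks(penalties, penalty_block):
    """Rank of each block's total penalty at generic (unit) lambdas; fixed
    across the lambda search so the log-pseudodeterminant stays continuous."""
    ranks = {}
    for bi in set(penalty_block):
        idx = [j for j, b in enumerate(penalty_block) if b == bi]
        M = sum(penalties[j][1] for j in idx)
        ev = np.linalg.eigvalsh((M + M.T) / 2)
        ranks[bi] = int(np.sum(ev > ev.max() * 1e-9))
    return ranks


def _pinv_trace_terms(penalties, penalty_block, lam, ranks):
    """Per-penalty tr(S_lambda^- S_j) plus the log-pseudodeterminant of
    S_lambda, computed blockwise (S_lambda is block-diagonal across terms).

    The pseudo-inverse and pseudo-determinant keep exactly the block's
    structural rank of eigenvalues — an adaptive cutoff would make the
    marginal-likelihood criterion discontinuous (and spuriously rewarding)
    when the lambdas of one block differ by many orders of magnitude.
    """
    out = np.zeros(len(penalties))
    logdet_plus = 0.0
    for bi in set(penalty_block):
        idx = [j for j, b in enumerate(penalty_block) if b == bi]
        M = sum(lam[j] * penalties[j][1] for j in idx)
        ev, U = np.linalg.eigh((M + M.T) / 2)
        r = ranks[bi]
        keep = np.zeros(len(ev), dtype=bool)
        keep[np.argsort(ev)[-r:]] = True
        safe = np.where(keep & (ev > 0), ev, 1.0)
        inv_ev = np.where(keep & (ev > 0), 1.0 / safe, 0.0)
        Minv = (U * inv_ev) @ U.T
        logdet_plus += float(np.sum(np.log(safe[keep])))
        for j in idx:
            out[j] = float(np.sum(Minv * penalties[j][1].T))
    return out, logdet_plus


def fit_gam(
    data: pd.DataFrame,
    formula: ModelFormula,
    gamma: float = 1.4,
    criterion: str = "reml",
    lambdas=None,
    weights=None,
    response: str = "response",
    max_outer: int = 40,
    keep_design: bool = True,
) -> FittedGAM:
    """Fit a binomial presence/background GAM.

    ``lambdas`` fixes the smoothing parameters (no selection); otherwise
    they are selected by ``criterion`` ("reml" via Fellner-Schall updates,
    or "aicc"/"gcv" via coordinate golden-section search). ``weights`` are
    prior case weights (aggregated rows).
    """
    y = np.asarray(data[response], dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("response must contain both classes")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    m = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    blocks = [build_block(data, spec) for spec in formula.smooths]
    slices, penalties, penalty_block, p = _assemble(blocks)
    X = np.empty((len(y), p))
    X[:, 0] = 1.0
    for block, sl in zip(blocks, slices):
        X[:, sl] = block.design(data)

    n_pen = len(penalties)
    if lambdas is not None:
        lam = np.broadcast_to(np.asarray(lambdas, dtype=float), (n_pen,)).copy()
        S = _total_penalty(p, penalties, gamma * lam)
        beta, mu, trace = _pirls(X, y, m, S)
        n_outer = 0
    elif n_pen == 0:
        lam = np.zeros(0)
        beta, mu, trace = _pirls(X, y, m, np.zeros((p, p)))
        n_outer = 0
    elif criterion == "reml":
        lam, beta, mu, n_outer = _select_fellner_schall(
            X, y, m, penalties, penalty_block, gamma, max_outer
        )
    elif criterion in ("aicc", "gcv"):
        lam, beta, mu, n_outer = _select_search(
            X, y, m, penalties, gamma, criterion
        )
    else:
        raise ValueError(f"unknown criterion {criterion}")

    # final scoring at the selected smoothing parameters (gamma-tempered
    # selection is equivalent to fitting with penalties gamma*lambda)
    S_eff = _total_penalty(p, penalties, gamma * lam) if n_pen else np.zeros((p, p))
    wq = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = _xtwx(X, m * wq)
    _, cho = _solve_spd(XtWX + S_eff, np.zeros(p))
    V = linalg.cho_solve(cho, np.eye(p), check_finite=False)
    A = V @ XtWX  # influence matrix on the coefficient scale
    hat_diag = np.diag(A)
    edf_total = float(hat_diag.sum())
    edf_per_term = {
        block.label: float(hat_diag[sl].sum()) for block, sl in zip(blocks, slices)
    }
    # AIC degrees of freedom with the smoothing-bias correction
    # tr(2A - A^2) >= tr(A): partially shrunk directions cost extra,
    # reflecting that their smoothing parameters were estimated
    edf_aic = float(2.0 * edf_total - np.sum(A * A.T))

    mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
    loglik = float(np.sum(m * (y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c))))
    n_tot = float(np.sum(m))
    p0 = float(np.sum(m * y) / n_tot)
    ll0 = float(n_tot * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
    deviance = -2.0 * loglik
    null_dev = -2.0 * ll0
    aic = -2.0 * loglik + 2.0 * edf_aic
    dev_expl = 1.0 - deviance / null_dev if null_dev > 0 else 0.0
    denom = 1.0 - np.exp(2.0 * ll0 / n_tot)
    nagelkerke = float((1.0 - np.exp(2.0 * (ll0 - loglik) / n_tot)) / denom) if denom > 0 else 0.0

    separated = bool(deviance < 1e-6 * n_tot and edf_total > 1)
    if separated:
        warnings.warn("fit is close to complete separation")

    fit = FittedGAM(
        formula=formula,
        blocks=blocks,
        beta=beta,
        slices=slices,
        lambdas=lam,
        penalty_block=penalty_block,
        gamma=gamma,
        criterion=criterion,
        edf_total=edf_total,
        edf_aic=edf_aic,
        edf_per_term=edf_per_term,
        loglik=loglik,
        null_deviance=null_dev,
        deviance=deviance,
        aic=aic,
        dev_explained=max(0.0, dev_expl),
        nagelkerke=max(0.0, min(1.0, nagelkerke)),
        n_obs=n_tot,
        converged=True,
        n_outer=n_outer,
        separated=separated,
    )
    if keep_design:
        fit.X, fit.y, fit.weights, fit.mu = X, y, m, mu
        fit.train_data = data
    else:
        fit.train_data = data[[c for c in data.columns if c != response]]
    return fit


def _select_fellner_schall(X, y, m, penalties, penalty_block, gamma, max_outer):
    """REML-type selection: likelihood tempered by 1/gamma, generalized
    Fellner-Schall multiplicative lambda updates, accepted only when they
    improve the Laplace-approximate marginal-likelihood criterion (damped
    in log space otherwise)."""
    p = X.shape[1]
    m_t = m / gamma
    ranks = _structural_ranks(penalties, penalty_block)

    def evaluate(lam, beta0):
        S = _total_penalty(p, penalties, lam)
        beta, mu, _ = _pirls(X, y, m_t, S, beta0=beta0, tol=1e-9)
        wq = np.clip(mu * (1 - mu), 1e-10, None)
        XtWX = _xtwx(X, m_t * wq)
        _, cho = _solve_spd(XtWX + S, np.zeros(p))
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        tr_pinv, logdet_S = _pinv_trace_terms(penalties, penalty_block, lam, ranks)
        pen_dev = _deviance(y, mu, m_t) + float(beta @ S @ beta)
        laml = 0.5 * pen_dev + 0.5 * logdet_H - 0.5 * logdet_S
        V = linalg.cho_solve(cho, np.eye(p), check_finite=False)
        return beta, mu, V, tr_pinv, laml

    lam = np.ones(len(penalties))
    beta, mu, V, tr_pinv, laml = evaluate(lam, None)
    outer = 0
    for outer in range(1, max_outer + 1):
        log_step = np.zeros(len(penalties))
        for j, (sl, Sj) in enumerate(penalties):
            tr_V = float(np.sum(V[sl, sl] * Sj.T))
            num = max(tr_pinv[j] - tr_V, 1e-12)
            den = max(float(beta[sl] @ Sj @ beta[sl]), 1e-14)
            log_step[j] = np.clip(np.log(num / den), -np.log(100), np.log(100))
        accepted = False
        for damp in (1.0, 0.5, 0.25):
            lam_try = np.clip(lam * np.exp(damp * log_step), 1e-7, 1e9)
            beta_t, mu_t, V_t, tr_t, laml_t = evaluate(lam_try, beta)
            if laml_t <= laml + 1e-7 * (abs(laml) + 1):
                improved = laml - laml_t
                lam, beta, mu, V, tr_pinv, laml = lam_try, beta_t, mu_t, V_t, tr_t, laml_t
                accepted = True
                break
        if not accepted:
            break
        if np.max(np.abs(damp * log_step)) < 5e-3 or improved < 1e-5 * (abs(laml) + 1):
            break
    # final coefficients under the selected penalties (true weights; the
    # tempered fit equals the true-likelihood fit with penalties gamma*lam)
    S = _total_penalty(p, penalties, gamma * lam)
    beta, mu, _ = _pirls(X, y, m, S, beta0=beta)
    return lam, beta, mu, outer


def _select_search(X, y, m, penalties, gamma, criterion):
    """Coordinate-wise golden-section search on log10(lambda) optimizing
    AICc or GCV with gamma-inflated edf."""
    p = X.shape[1]
    n_tot = float(np.sum(m))

    def score(lam):
        S = _total_penalty(p, penalties, lam)
        beta, mu, _ = _pirls(X, y, m, S)
        wq = np.clip(mu * (1 - mu), 1e-10, None)
        XtWX = _xtwx(X, m * wq)
        _, cho = _solve_spd(XtWX + S, np.zeros(p))
        V = linalg.cho_solve(cho, np.eye(p), check_finite=False)
        edf = gamma * float(np.einsum("ij,ji->i", V, XtWX).sum())
        dev = _deviance(y, mu, m)
        if criterion == "aicc":
            denom = max(n_tot - edf - 1, 1.0)
            return dev + 2 * edf + 2 * edf * (edf + 1) / denom, beta, mu
        return n_tot * dev / max(n_tot - edf, 1.0) ** 2, beta, mu

    lam = np.ones(len(penalties))
    best, beta, mu = score(lam)
    gr = (np.sqrt(5) - 1) / 2
    for sweep in range(2):
        for j in range(len(penalties)):
            grid = np.arange(-4.0, 8.1, 2.0)
            vals = []
            for g in grid:
                lam_try = lam.copy()
                lam_try[j] = 10.0 ** g
                vals.append(score(lam_try)[0])
            gi = int(np.argmin(vals))
            a = grid[max(gi - 1, 0)]
            b = grid[min(gi + 1, len(grid) - 1)]
            x1, x2 = b - gr * (b - a), a + gr * (b - a)
            for _ in range(12):
                lam1, lam2 = lam.copy(), lam.copy()
                lam1[j], lam2[j] = 10.0 ** x1, 10.0 ** x2
                if score(lam1)[0] < score(lam2)[0]:
                    b, x2 = x2, x1
                    x1 = b - gr * (b - a)
                else:
                    a, x1 = x1, x2
                    x2 = a + gr * (b - a)
            lam[j] = 10.0 ** ((a + b) / 2)
        best, beta, mu = score(lam)
    return lam, beta, mu, 2


def predict_gam(fit: FittedGAM, data, return_flags: bool = False):
    """Predicted presence probability for new rows; with
    ``return_flags=True`` also a per-row boolean marking extrapolation
    beyond 5% outside any training range."""
    return fit.predict(data, return_flags=return_flags)


def model_scores(fit: FittedGAM) -> dict:
    """(AIC, deviance explained, Nagelkerke R2, loglik, edf) of a fit."""
    return fit.scores()


def check_basis_dimension(fit: FittedGAM, margin: float = 0.5, k_max: dict | None = None) -> pd.DataFrame:
    """Per-term check that the basis dimension is not binding: flags any
    term whose edf exceeds k-1 minus a safety margin, and suggests a
    doubled k capped at the configured maxima (16 for BIO6, 10 otherwise)."""
    k_max = k_max or {}
    rows = []
    for spec, block in zip(fit.formula.smooths, fit.blocks):
        edf = fit.edf_per_term[block.label]
        kprime = block.ncol  # columns after the identifiability constraint
        flagged = edf > kprime - margin
        var = spec.variables[0]
        cap = k_max.get(var, default_k(var))
        suggestion = min(2 * spec.k[0], max(cap, spec.k[0])) if flagged else spec.k[0]
        rows.append(
            {
                "term": block.label,
                "edf": edf,
                "k_prime": kprime,
                "flagged": flagged,
                "suggested_k": suggestion,
            }
        )
    return pd.DataFrame(rows)
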