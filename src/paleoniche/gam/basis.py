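"""Penalized spline bases and tensor-product interaction blocks.

Smooths are low-rank penalized regression splines: B-spline bases on
equally spaced knots with difference penalties on the coefficients
(P-splines). The second-order difference penalty leaves constant and
linear coefficient vectors unpenalized, and since equally spaced B-splines
reproduce polynomials up to their degree, the penalty null space contains
every linear function of the covariate.

Environment x time interactions are tensor-product smooths: the row-wise
Kronecker product of the two marginal bases, with one penalty per margin
(S_env (x) I and I (x) S_time) so each direction's wiggliness gets its own
smoothing parameter. A coefficient field constant along the time margin is
exactly unpenalized by the time penalty, which is what lets the fit shrink
a changing-niche term back to a constant-niche one.

Every block carries a sum-to-zero identifiability constraint over the
training rows, absorbed by a Householder reparameterization (k columns ->
k-1), so all smooths are orthogonal to the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.interpolate import BSpline


@dataclass
class SmoothSpec:
    """Declaration of one model term.

    ``variables`` is (env_var,) for a univariate smooth or
    (env_var, "time") for a tensor interaction. ``k`` is the marginal basis
    dimension (one per margin); defaults follow the study settings of 16
    for BIO6 and 10 for the other environmental variables, with 5 for the
    time margin. ``penalty_order`` is the difference-penalty order.
    """

    variables: tuple
    k: tuple
    degree: int = 3
    penalty_order: int = 2
    basis: str = "ps"  # "ps" (P-spline) or "linear"

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.k = tuple(int(v) for v in self.k)
        if self.basis == "linear":
            self.k = tuple(2 for _ in self.variables)
        for k in self.k:
            if k < 2:
                raise ValueError("basis dimension k must be >= 2 per margin")

    @property
    def label(self) -> str:
        if len(self.variables) == 1:
            return f"s({self.variables[0]})"
        return f"te({','.join(self.variables)})"


DEFAULT_K = {"BIO6": 16}
DEFAULT_K_OTHER = 10
DEFAULT_K_TIME = 5


def default_k(var: str) -> int:
    return DEFAULT_K.get(var, DEFAULT_K_OTHER)


@dataclass
class MarginBasis:
    """One marginal B-spline basis: evaluation knots and degree."""

    var: str
    knots: np.ndarray
    degree: int

    @property
    def k(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return BSpline.design_matrix(x, self.knots, self.degree, extrapolate=True).toarray()


def _make_knots(x: np.ndarray, k: int, degree: int) -> np.ndarray:
    """Equally spaced knots spanning the data range for k basis functions."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("covariate has no spread")
    n_seg = k - degree
    h = (hi - lo) / n_seg
    return lo + np.arange(-degree, n_seg + degree + 1) * h


def _difference_penalty(k: int, order: int) -> np.ndarray:
    if k - order <= 0:
        return np.zeros((k, k))
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _constraint_null(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z (k x k-m) of the null space of the m x k
    constraint matrix C, via full QR of C'. Deterministic."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    m, k = C.shape
    q, _ = np.linalg.qr(C.T, mode="complete")
    return q[:, m:]


def greville(knots: np.ndarray, degree: int) -> np.ndarray:
    """Greville abscissae: B-spline coefficients that reproduce the
    identity function exactly (for degree >= 1)."""
    k = len(knots) - degree - 1
    return np.array([knots[j + 1 : j + degree + 1].mean() for j in range(k)])


def _rank(S: np.ndarray) -> int:
    if S.size == 0 or not np.any(S):
        return 0
    ev = np.linalg.eigvalsh((S + S.T) / 2)
    return int(np.sum(ev > ev.max() * 1e-9))


@dataclass
class BasisBlock:
    """Constrained design block for one smooth term.

    ``margins`` holds the marginal bases (1 for univariate, 2 for tensor);
    ``constraint`` is the training-column-mean row vector whose null space
    Z (QR-derived, reconstructable) absorbs the sum-to-zero constraint
    against the intercept. Tensor blocks additionally carry
    ``margin_constraint``: the first (environment) margin is centered
    (sum-to-zero over the training rows) before the Kronecker product, so
    the tensor spans environment main effects and interactions but no
    pure function of time — with time-matched backgrounds a pure time
    effect is unidentifiable, and shared unpenalized time functions would
    otherwise be exactly collinear across the per-variable tensors.
    ``penalties`` are the constrained PSD penalty matrices, one per margin
    carrying a penalty.
    """

    label: str
    margins: list
    constraint: np.ndarray
    penalties: list = field(default_factory=list)
    penalty_ranks: list = field(default_factory=list)
    train_range: dict = field(default_factory=dict)
    margin_constraint: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.constraint = np.atleast_2d(np.asarray(self.constraint, dtype=float))
        self.Z = _constraint_null(self.constraint)
        self.Z1 = (
            _constraint_null(self.margin_constraint)
            if self.margin_constraint is not None
            else None
        )

    @property
    def ncol(self) -> int:
        return self.Z.shape[1]

    @property
    def ncol_unconstrained(self) -> int:
        return self.Z.shape[0]

    def design_unconstrained(self, data) -> np.ndarray:
        mats = [m.design(np.asarray(data[m.var], dtype=float)) for m in self.margins]
        if len(mats) == 1:
            return mats[0]
        a, b = mats
        if self.Z1 is not None:
            a = a @ self.Z1
        return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)

    def design(self, data) -> np.ndarray:
        return self.design_unconstrained(data) @ self.Z

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "margins": [
                {"var": m.var, "knots": m.knots.tolist(), "degree": m.degree}
                for m in self.margins
            ],
            "constraint": self.constraint.tolist(),
            "margin_constraint": (
                None if self.margin_constraint is None else self.margin_constraint.tolist()
            ),
            "penalties": [p.tolist() for p in self.penalties],
            "penalty_ranks": list(self.penalty_ranks),
            "train_range": {k: list(v) for k, v in self.train_range.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisBlock":
        mc = d.get("margin_constraint")
        return cls(
            label=d["label"],
            margins=[
                MarginBasis(m["var"], np.asarray(m["knots"], dtype=float), int(m["degree"]))
                for m in d["margins"]
            ],
            constraint=np.asarray(d["constraint"], dtype=float),
            penalties=[np.asarray(p, dtype=float) for p in d["penalties"]],
            penalty_ranks=[int(r) for r in d["penalty_ranks"]],
            train_range={k: tuple(v) for k, v in d["train_range"].items()},
            margin_constraint=None if mc is None else np.asarray(mc, dtype=float),
        )


def _margin_for(x: np.ndarray, var: str, k: int, degree: int) -> tuple:
    """Marginal basis with k possibly reduced to the number of distinct
    values (warning) and degree capped at k-1."""
    n_distinct = len(np.unique(x))
    if n_distinct < 2:
        raise ValueError(f"covariate {var} is constant")
    if n_distinct < k:
        warnings.warn(f"{var}: only {n_distinct} distinct values, reducing k from {k}")
        k = n_distinct
    degree = min(degree, k - 1)
    return MarginBasis(var=var, knots=_make_knots(x, k, degree), degree=degree), k, degree


def build_basis(data, spec: SmoothSpec) -> BasisBlock:
    """Univariate penalized-spline block for one variable.

    k columns before the sum-to-zero constraint, k-1 after; the difference
    penalty's null space contains constant and linear functions. A "linear"
    basis (k=2, degree 1) spans exactly the linear functions and carries no
    penalty, reducing the term to a parametric logistic one.
    """
    (var,) = spec.variables
    x = np.asarray(data[var], dtype=float)
    degree = 1 if spec.basis == "linear" else spec.degree
    margin, k, degree = _margin_for(x, var, spec.k[0], degree)
    X = margin.design(x)
    S = _difference_penalty(k, spec.penalty_order)
    C = X.mean(axis=0)[None, :]
    Z = _constraint_null(C)
    penalties, ranks = [], []
    if spec.basis != "linear" and np.any(S):
        Sc = Z.T @ S @ Z
        penalties, ranks = [Sc], [_rank(Sc)]
    return BasisBlock(
        label=spec.label,
        margins=[margin],
        constraint=C,
        penalties=penalties,
        penalty_ranks=ranks,
        train_range={var: (float(x.min()), float(x.max()))},
    )


def build_tensor(data, spec: SmoothSpec) -> BasisBlock:
    """Tensor-product block for (variable, time) with one penalty per
    margin. k1*k2 columns before any constraint; centering the first
    (environment) margin and the overall sum-to-zero constraint leave
    (k1-1)*k2 - 1. The span contains environment main effects and
    environment x time interactions but no pure function of time."""
    if len(spec.variables) != 2:
        raise ValueError("tensor smooth needs exactly two margins")
    margins, mats, Ss = [], [], []
    for var, k in zip(spec.variables, spec.k):
        x = np.asarray(data[var], dtype=float)
        margin, k_eff, _ = _margin_for(x, var, k, spec.degree)
        margins.append(margin)
        mats.append(margin.design(x))
        Ss.append(_difference_penalty(k_eff, spec.penalty_order))
    a, b = mats
    if a.shape[0] != b.shape[0]:
        raise ValueError("margins built from different row sets")
    c1 = a.mean(axis=0)[None, :]
    Z1 = _constraint_null(c1)
    ac = a @ Z1
    S1c = Z1.T @ Ss[0] @ Z1
    X = (ac[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)
    k1c, k2 = ac.shape[1], b.shape[1]
    P1 = np.kron(S1c, np.eye(k2))
    P2 = np.kron(np.eye(k1c), Ss[1])
    C = X.mean(axis=0)[None, :]
    Z = _constraint_null(C)
    penalties = [Z.T @ P @ Z for P in (P1, P2)]
    return BasisBlock(
        label=spec.label,
        margins=margins,
        constraint=C,
        penalties=penalties,
        penalty_ranks=[_rank(p) for p in penalties],
        train_range={
            m.var: (float(np.min(data[m.var])), float(np.max(data[m.var])))
            for m in margins
        },
        margin_constraint=c1,
    )


def build_block(data, spec: SmoothSpec) -> BasisBlock:
    if len(spec.variables) == 1:
        return build_basis(data, spec)
    return build_tensor(data, spec)
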