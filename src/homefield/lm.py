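"""Least-squares and median (LAD) regression engines for factor designs.

Unbalanced trial networks produce rank-deficient designs (site:year cells
that never occur, confounded factor levels).  The estimability convention
here follows the classical treatment-coded linear model: reference level =
lexicographically first level of each factor, aliased columns detected by a
column-pivoted QR and dropped (their coefficients reported as NaN), and the
fit computed on the estimable subspace.  Gaussian log-likelihood is taken at
the MLE variance, with AIC = −2ℓ + 2k and BIC = −2ℓ + k·log n for
k = rank + 1 (the error variance counts as a parameter).

Median regression minimises the sum of absolute residuals (quantile τ = 0.5)
and is solved exactly as a linear program, so the reported objective is a
certified optimum rather than an iteratively approximated one.  When several
vertices minimise the objective the solver's vertex is reported; the optimum
value is unique even when the coefficients are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import linprog

TermSpec = str | tuple[str, str]


def build_design(
    frame: pd.DataFrame,
    terms: Sequence[TermSpec],
    indicators: Mapping[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build a treatment-coded design matrix with intercept.

    ``terms`` may contain factor column names (dummy-coded against the
    lexicographically first level) and 2-tuples ``(a, b)`` for their
    interaction (products of the non-reference dummies).  ``indicators``
    adds numeric columns verbatim (e.g. the 0/1 home-site flag).
    """
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]

    def factor_dummies(col: str) -> tuple[list[np.ndarray], list[str]]:
        values = frame[col].to_numpy()
        levels = np.unique(values)
        dummies = [(values == lev).astype(float) for lev in levels[1:]]
        labels = [f"{col}[{lev}]" for lev in levels[1:]]
        return dummies, labels

    for term in terms:
        if isinstance(term, tuple):
            a, b = term
            da, la = factor_dummies(a)
            db, lb = factor_dummies(b)
            for xa, na in zip(da, la):
                for xb, nb in zip(db, lb):
                    col = xa * xb
                    if col.any():  # absent combinations are structurally aliased
                        cols.append(col)
                        names.append(f"{na}:{nb}")
        else:
            dummies, labels = factor_dummies(term)
            cols.extend(dummies)
            names.extend(labels)
    for name, values in (indicators or {}).items():
        values = np.asarray(values, dtype=float)
        if values.shape != (n,):
            raise ValueError(f"indicator {name!r} has wrong length")
        cols.append(values)
        names.append(name)
    return np.column_stack(cols), names


@dataclass
class LinearFit:
    """A pivoted least-squares fit.

    Coefficients of aliased (dropped) columns are NaN.  ``loglik`` is the
    Gaussian log-likelihood at the MLE variance ``rss / n``.
    """

    coefficients: pd.Series
    se: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    loglik: float
    aic: float
    bic: float
    n: int
    rank: int
    aliased: list[str]
    sigma2: float

    def __getitem__(self, name: str) -> float:
        return float(self.coefficients[name])


_RANK_TOL = 1e-7  # relative residual-norm threshold for aliasing


def _select_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order-preserving rank filter (modified Gram-Schmidt with re-orth).

    Scans columns left to right and keeps each one only if it adds rank
    beyond the columns already kept — the classical sequential-pivoting
    convention, under which later columns (e.g. an indicator appended last)
    are the ones reported aliased.  Returns (kept indices, orthonormal Q).
    """
    n, p = X.shape
    Q = np.empty((n, min(n, p)))
    kept: list[int] = []
    k = 0
    for j in range(p):
        x = X[:, j]
        nx = np.linalg.norm(x)
        if nx == 0:
            continue
        r = x - Q[:, :k] @ (Q[:, :k].T @ x)
        r -= Q[:, :k] @ (Q[:, :k].T @ r)  # second pass for stability
        nr = np.linalg.norm(r)
        if nr > _RANK_TOL * nx:
            Q[:, k] = r / nr
            kept.append(j)
            k += 1
            if k == min(n, p):
                break
    return np.array(kept, dtype=int), Q[:, :k]


def _pivoted_solve(X: np.ndarray, y: np.ndarray):
    """Sequential-pivot LS; returns (beta, kept_idx, rank, XtX_inv_kept)."""
    kept, Q = _select_columns(X)
    rank = len(kept)
    if rank == 0:
        return np.empty(0), kept, 0, np.empty((0, 0))
    Xk = X[:, kept]
    R = Q.T @ Xk  # upper triangular by construction
    beta_k = scipy.linalg.solve_triangular(R, Q.T @ y)
    Rinv = scipy.linalg.solve_triangular(R, np.eye(rank))
    xtx_inv = Rinv @ Rinv.T
    return beta_k, kept, rank, xtx_inv


def fit_least_squares(
    X: np.ndarray, y: np.ndarray, names: Sequence[str]
) -> LinearFit:
    """Least squares on the estimable subspace of a possibly singular design."""
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n == 0:
        raise ValueError("empty design")
    if len(y) != n:
        raise ValueError("response length mismatch")
    beta_k, kept, rank, xtx_inv = _pivoted_solve(X, y)
    fitted = X[:, kept] @ beta_k
    resid = y - fitted
    rss = float(resid @ resid)
    sigma2 = rss / n  # MLE variance
    if sigma2 > 0:
        loglik = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)
    else:
        loglik = np.inf
    k = rank + 1
    aic = -2 * loglik + 2 * k
    bic = -2 * loglik + k * np.log(n)
    coefs = np.full(p, np.nan)
    coefs[kept] = beta_k
    ses = np.full(p, np.nan)
    if n > rank:
        s2_unbiased = rss / (n - rank)
        ses[kept] = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * s2_unbiased)
    return LinearFit(
        coefficients=pd.Series(coefs, index=list(names)),
        se=pd.Series(ses, index=list(names)),
        fitted=fitted,
        residuals=resid,
        rss=rss,
        loglik=float(loglik),
        aic=float(aic),
        bic=float(bic),
        n=n,
        rank=rank,
        aliased=[names[i] for i in range(p) if i not in set(kept)],
        sigma2=sigma2,
    )


def fit_linear_model(
    frame: pd.DataFrame,
    response: str | np.ndarray,
    terms: Sequence[TermSpec],
    indicators: Mapping[str, np.ndarray] | None = None,
) -> LinearFit:
    """Treatment-coded least-squares fit of ``response`` on ``terms``."""
    if len(frame) == 0:
        raise ValueError("empty data")
    y = frame[response].to_numpy(float) if isinstance(response, str) else response
    X, names = build_design(frame, terms, indicators)
    return fit_least_squares(X, np.asarray(y, float), names)


@dataclass
class LADFit:
    """A median (τ = 0.5) quantile-regression fit."""

    coefficients: pd.Series
    objective: float  # certified minimum of Σ|residual|
    fitted: np.ndarray
    residuals: np.ndarray
    n: int
    rank: int
    aliased: list[str]

    def __getitem__(self, name: str) -> float:
        return float(self.coefficients[name])


def median_quantile_regression(
    X: np.ndarray, y: np.ndarray, names: Sequence[str] | None = None
) -> LADFit:
    """Minimise Σ|y − Xβ| exactly via the standard LP formulation.

    Aliased columns are dropped first (same pivoted-QR rule as the
    least-squares engine) so the LP is bounded; their coefficients are NaN.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if n <= 0:
        raise ValueError("empty problem")
    _, kept, rank, _ = _pivoted_solve(X, y)
    if n <= rank:
        raise ValueError(f"need n > rank ({n} <= {rank})")
    Xk = X[:, kept]
    # min 1'(u+v)  s.t.  Xk b + u - v = y,  u, v >= 0, b free
    c = np.r_[np.zeros(rank), np.ones(2 * n)]
    A_eq = np.hstack([Xk, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * rank + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LAD linear program failed: {res.message}")
    beta_k = res.x[:rank]
    coefs = np.full(p, np.nan)
    coefs[kept] = beta_k
    fitted = Xk @ beta_k
    resid = y - fitted
    return LADFit(
        coefficients=pd.Series(coefs, index=list(names)),
        objective=float(np.abs(resid).sum()),
        fitted=fitted,
        residuals=resid,
        n=n,
        rank=rank,
        aliased=[names[i] for i in range(p) if i not in set(kept)],
    )
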