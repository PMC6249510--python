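"""Vectorized complete-case ordinary least squares shared by the per-probe models.

All per-probe tests in this package are OLS fits of one design matrix against
thousands of probe columns.  Probes sharing the same missingness pattern are
solved together; fully observed data collapses to a single batched solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class RankDeficientDesign(ValueError):
    """Raised when the design matrix is not full column rank."""


@dataclass
class OlsFit:
    """Batched OLS results: arrays indexed (coef, probe) or (probe,)."""

    coef: np.ndarray        # q x p
    se: np.ndarray          # q x p
    df: np.ndarray          # p
    n_used: np.ndarray      # p
    resid: np.ndarray       # n x p, NaN where the response was missing
    sigma2: np.ndarray      # p

    def tstat(self, idx: int) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef[idx] / self.se[idx]

    def pvalue(self, idx: int) -> np.ndarray:
        t = self.tstat(idx)
        df = np.maximum(self.df, 1)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p[~np.isfinite(t)] = np.nan
        return p


def _check_rank(X: np.ndarray, names: list[str] | None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        # point at a culprit: a column whose removal restores full rank
        for j in range(X.shape[1]):
            keep = [i for i in range(X.shape[1]) if i != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                raise RankDeficientDesign(
                    f"design is rank deficient; column {names[j]!r} is aliased"
                )
        raise RankDeficientDesign("design is rank deficient")


def ols_by_pattern(
    Y: np.ndarray, X: np.ndarray, names: list[str] | None = None
) -> OlsFit:
    """Fit ``Y[:, j] ~ X`` per column with complete-case handling.

    Y : (n, p) responses, NaN marking missing entries.
    X : (n, q) fully observed design (rows with NaN in Y are dropped per probe).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = Y.shape
    q = X.shape[1]
    coef = np.full((q, p), np.nan)
    se = np.full((q, p), np.nan)
    df = np.zeros(p)
    n_used = np.zeros(p, dtype=int)
    resid = np.full((n, p), np.nan)
    sigma2 = np.full(p, np.nan)

    mask = np.isnan(Y)
    # group probe columns by identical missingness pattern
    if mask.any():
        pat_codes = {}
        groups: dict[bytes, list[int]] = {}
        for j in range(p):
            key = mask[:, j].tobytes()
            groups.setdefault(key, []).append(j)
        items = groups.items()
    else:
        items = [(b"", list(range(p)))]

    full_rows = ~mask.any(axis=1) if mask.any() else np.ones(n, dtype=bool)
    for key, cols in items:
        rows = ~np.frombuffer(key, dtype=bool) if key else np.ones(n, dtype=bool)
        Xs = X[rows]
        Ys = Y[np.ix_(rows, cols)]
        ns = Xs.shape[0]
        # columns that became constant under this missingness pattern (e.g.
        # a rare factor level absent from the complete cases) are dropped
        # for these probes only; their coefficients stay NaN
        variances = Xs.var(axis=0)
        keep_idx = [0] + [j for j in range(1, Xs.shape[1]) if variances[j] > 0]
        Xk = Xs[:, keep_idx]
        qk = Xk.shape[1]
        if ns <= qk:
            continue  # unestimable pattern; left NaN
        _check_rank(Xk, [(names or [f"x{i}" for i in range(q)])[j] for j in keep_idx])
        XtX = Xk.T @ Xk
        XtX_inv = np.linalg.inv(XtX)
        B = XtX_inv @ (Xk.T @ Ys)
        R = Ys - Xk @ B
        dof = ns - qk
        s2 = (R * R).sum(axis=0) / dof
        coef[np.ix_(keep_idx, cols)] = B
        se[np.ix_(keep_idx, cols)] = np.sqrt(np.outer(np.diag(XtX_inv), s2))
        df[cols] = dof
        n_used[cols] = ns
        sigma2[cols] = s2
        rr = np.full((n, len(cols)), np.nan)
        rr[rows] = R
        resid[:, cols] = rr
    return OlsFit(coef=coef, se=se, df=df, n_used=n_used, resid=resid, sigma2=sigma2)


def race_dummies(race, levels=None, reference: str | None = None):
    """Dummy-code a race vector with the most frequent level as reference.

    Returns (matrix n x (k-1), column names, reference level).
    """
    import pandas as pd

    s = pd.Series(race)
    present = s.value_counts()
    if reference is None:
        reference = present.index[0]
    cats = [l for l in present.index if l != reference]
    cols = [f"race[{c}]" for c in cats]
    M = np.column_stack([(s == c).to_numpy(dtype=float) for c in cats]) if cats else np.empty((len(s), 0))
    return M, cols, reference
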