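"""Maximum generalized variance (MGV) optimal transformation.

Each congener is re-expressed through a restricted (natural) cubic
spline basis, and the transformations are optimised jointly so that
every congener is maximally predictable from the others: sweeping over
congeners, the first canonical variate pair between congener *j*'s
spline basis and the current transformed scores of the remaining
congeners replaces column *j* (basis side, standardized, sign anchored
to positive Spearman correlation with the raw values).  Sweeps repeat
until the transformed matrix stops changing.  The result is a set of
zero-mean, unit-variance congener scores on which linear methods
(principal components, linear regression) capture monotone but
non-linear co-variation.

A restricted cubic spline with ``k`` knots contributes ``k - 1``
regression columns (the identity plus ``k - 2`` truncated-cubic terms)
and is linear beyond the boundary knots, so the transformation does not
oscillate in the tails where concentration data are sparse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

#: Knot placement quantiles, per knot count (the conventional choices
#: for regression splines on modest samples).
DEFAULT_KNOT_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


@dataclass
class SplineBasis:
    """Restricted cubic spline basis for one variable."""

    knots: np.ndarray
    k: int
    basis: np.ndarray = field(repr=False)


def knot_positions(
    x: np.ndarray, k: int, quantiles: Optional[tuple[float, ...]] = None
) -> np.ndarray:
    if quantiles is None:
        if k not in DEFAULT_KNOT_QUANTILES:
            raise ValueError(f"no default knot quantiles for k={k}; pass them")
        quantiles = DEFAULT_KNOT_QUANTILES[k]
    if len(quantiles) != k:
        raise ValueError("need exactly k knot quantiles")
    knots = np.quantile(np.asarray(x, dtype=float), quantiles)
    if np.unique(knots).size < k:
        raise ValueError(
            f"duplicate knots at {knots}; the variable has too many ties "
            "for k={k} knots - use fewer knots"
        )
    return knots


def rcs_basis(
    x, k: int = 3, quantiles: Optional[tuple[float, ...]] = None
) -> SplineBasis:
    """Restricted cubic spline basis of ``x`` with ``k`` quantile knots.

    Column 1 is ``x`` itself; columns ``2 .. k-1`` are the restricted
    cubic terms, scaled by the squared boundary-knot span so all columns
    share the scale of ``x``.  The basis is linear outside the boundary
    knots.
    """
    x = np.asarray(x, dtype=float)
    if k < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if np.unique(x).size < k:
        raise ValueError("need at least k distinct values")
    t = knot_positions(x, k, quantiles)
    cols = [x]
    span2 = (t[-1] - t[0]) ** 2
    denom = t[-1] - t[-2]
    for j in range(k - 2):
        tj = t[j]
        term = (
            np.clip(x - tj, 0, None) ** 3
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - tj) / denom
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - tj) / denom
        ) / span2
        cols.append(term)
    return SplineBasis(knots=t, k=k, basis=np.column_stack(cols))


@dataclass
class TransformedMatrix:
    """MGV-transformed congener scores (zero mean, unit variance)."""

    scores: pd.DataFrame = field(repr=False)
    iterations: int = 0
    converged: bool = False
    max_delta: float = np.inf
    #: per sweep, per congener: first canonical correlation at the update
    cancor_history: list[list[float]] = field(default_factory=list)
    #: per sweep maximum absolute entry change
    delta_history: list[float] = field(default_factory=list)

    def convergence_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.delta_history) + 1),
                "max_delta": self.delta_history,
            }
        )


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std(ddof=1)
    if s == 0 or not np.isfinite(s):
        raise ValueError("degenerate (constant) transformed column")
    return (v - v.mean()) / s


def _blom_scores(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    r = rankdata(x)
    return norm.ppf((r - 0.375) / (n + 0.25))


def _first_canonical_weight(bc: np.ndarray, yc: np.ndarray) -> tuple[np.ndarray, float]:
    """Basis-side weights and correlation of the first canonical pair."""
    sxx = bc.T @ bc
    syy = yc.T @ yc
    sxy = bc.T @ yc

    def chol(s):
        return np.linalg.cholesky(s)

    try:
        lx, ly = chol(sxx), chol(syy)
    except np.linalg.LinAlgError:
        warnings.warn(
            "rank-deficient canonical system; adding 1e-8 ridge", stacklevel=3
        )
        sxx = sxx + 1e-8 * np.eye(sxx.shape[0]) * max(np.trace(sxx), 1.0)
        syy = syy + 1e-8 * np.eye(syy.shape[0]) * max(np.trace(syy), 1.0)
        lx, ly = chol(sxx), chol(syy)
    kmat = np.linalg.solve(lx, sxy) @ np.linalg.inv(ly).T
    u, s, _ = np.linalg.svd(kmat, full_matrices=False)
    a = np.linalg.solve(lx.T, u[:, 0])
    return a, float(s[0])


def mgv(
    x: pd.DataFrame,
    k: int = 3,
    tol: float = 1e-6,
    max_iter: int = 50,
    quantiles: Optional[tuple[float, ...]] = None,
    init: str = "rank_normal",
    basis_scale: str = "raw",
    init_scores: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
) -> TransformedMatrix:
    """Iterative MGV transformation of a congener table.

    Parameters
    ----------
    x
        Subjects x congeners table on the original (positive) scale.
    k
        Knots per congener spline (quantile placement).
    tol, max_iter
        Sweeps stop when the maximum absolute entry change falls below
        ``tol`` or after ``max_iter`` sweeps.
    init
        ``"rank_normal"`` starts from standardized normal scores of the
        ranks (robust default); ``"raw"`` starts from the standardized
        raw columns, which makes an exactly linear system a fixed point
        of the very first sweep.
    basis_scale
        ``"raw"`` builds each congener's spline basis on its original
        values (conventional); ``"rank_normal"`` builds it on the
        normal scores of the ranks, making the whole transformation an
        exact function of ranks and therefore invariant under strictly
        monotone re-expression of any input column.
    init_scores
        Optional warm start (subjects x congeners).  Restarting from a
        converged result's ``scores`` is a fixed point of the sweep and
        terminates immediately.
    seed
        Unused by the deterministic default configuration; accepted so
        callers can thread one seed through every stage.

    Notes
    -----
    Congeners are updated sequentially (Gauss-Seidel) in column order;
    the update order is part of the reproducibility contract.
    """
    n, p = x.shape
    if p < 2:
        raise ValueError("MGV needs at least 2 congeners")
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} subjects")
    if init not in ("rank_normal", "raw"):
        raise ValueError(f"unknown init {init!r}")
    if basis_scale not in ("raw", "rank_normal"):
        raise ValueError(f"unknown basis_scale {basis_scale!r}")
    a = x.to_numpy(dtype=float)

    bases = []
    for j in range(p):
        v = a[:, j] if basis_scale == "raw" else _blom_scores(a[:, j])
        b = rcs_basis(v, k, quantiles).basis
        b = b - b.mean(axis=0)
        # unit-scale columns: canonical variates are scale-invariant but
        # raw cubic terms of wide-ranging concentrations are not well
        # conditioned
        scale = b.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        bases.append(b / scale)
    raw_ranks = [rankdata(a[:, j]) for j in range(p)]

    if init_scores is not None:
        t = np.column_stack(
            [_standardize(init_scores[c].to_numpy(dtype=float)) for c in x.columns]
        )
    elif init == "rank_normal":
        t = np.column_stack([_standardize(_blom_scores(a[:, j])) for j in range(p)])
    else:
        t = np.column_stack([_standardize(a[:, j]) for j in range(p)])

    cancor_history: list[list[float]] = []
    delta_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        t_prev = t.copy()
        sweep_cors: list[float] = []
        for j in range(p):
            others = np.delete(t, j, axis=1)
            yc = others - others.mean(axis=0)
            wt, cor = _first_canonical_weight(bases[j], yc)
            new = _standardize(bases[j] @ wt)
            rho_sign = np.corrcoef(rankdata(new), raw_ranks[j])[0, 1]
            if rho_sign < 0:
                new = -new
            t[:, j] = new
            sweep_cors.append(cor)
        cancor_history.append(sweep_cors)
        delta = float(np.abs(t - t_prev).max())
        delta_history.append(delta)
        if delta < tol:
            converged = True
            break

    return TransformedMatrix(
        scores=pd.DataFrame(t, index=x.index, columns=x.columns),
        iterations=it,
        converged=converged,
        max_delta=delta_history[-1] if delta_history else 0.0,
        cancor_history=cancor_history,
        delta_history=delta_history,
    )
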