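"""Marker subset selection within stable congener clusters.

A stable cluster with more than two members is summarised by the first
principal component (PC1) of its MGV-transformed scores; the share of
within-cluster variance it explains (``R2_PC1``) measures how
one-dimensional the cluster is.  A linear model then predicts the PC1
score from 3-knot restricted cubic spline bases of the members'
*original-scale* concentrations, and members are deleted greedily - at
each step removing the congener whose loss hurts the refitted R² least
- until a further deletion would push R² below the target (0.95 by
default).  The congeners remaining are the representative markers for
the cluster (``PCB_R`` when the cluster is made of dioxin-like PCBs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mgv import rcs_basis


@dataclass
class MarkerSelectionResult:
    """Deletion path and retained markers for one cluster."""

    cluster: list[str]
    pc1_var: float
    r2_path: list[tuple[str, float]] = field(default_factory=list)
    markers: list[str] = field(default_factory=list)
    final_r2: float = np.nan
    #: True when even the full model misses the R² target
    target_unmet: bool = False

    def to_row(self) -> dict:
        return {
            "pc1_var": self.pc1_var,
            "final_r2": self.final_r2,
            "markers": ";".join(self.markers),
            "n_markers": len(self.markers),
            "target_unmet": self.target_unmet,
        }


def pc1_score(t: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of standardized cluster columns.

    Returns the per-subject PC1 scores and the fraction of variance the
    leading eigenvalue of the correlation matrix explains.  The sign is
    fixed so the loading sum is positive.  Restricted to clusters with
    more than two members, where a single summary direction is a
    meaningful reduction.
    """
    n, p = t.shape
    if p <= 2:
        raise ValueError("PC1 summary requires a cluster with more than 2 members")
    a = t.to_numpy(dtype=float)
    a = (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)
    corr = a.T @ a / (n - 1)
    vals, vecs = np.linalg.eigh(corr)
    lead = vecs[:, -1]
    if lead.sum() < 0:
        lead = -lead
    scores = a @ lead
    return pd.Series(scores, index=t.index, name="pc1"), float(vals[-1] / p)


def _spline_design(x_raw: pd.DataFrame, members: list[str], k: int = 3) -> np.ndarray:
    cols = [np.ones(len(x_raw))]
    for c in members:
        cols.append(rcs_basis(x_raw[c].to_numpy(), k=k).basis)
    return np.column_stack(cols)


def _r2(design: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / tss


def select_markers(
    x_raw: pd.DataFrame,
    scores: pd.Series,
    r2_target: float = 0.95,
    k: int = 3,
) -> MarkerSelectionResult:
    """Greedy backward deletion of spline terms against the PC1 score.

    ``x_raw`` holds the cluster members on the original (imputed TEQ)
    scale; each member contributes a 3-knot restricted cubic spline
    (knots at its own 10th/50th/90th percentiles).  Whole congeners
    (both spline columns) are deleted at once; at each step the congener
    whose removal leaves the largest refitted R² goes, and deletion
    stops before R² would cross below ``r2_target``.  If even the full
    model misses the target, all members are kept and the result is
    flagged.
    """
    members = list(x_raw.columns)
    if len(members) < 2:
        raise ValueError("need at least 2 candidate congeners")
    y = scores.to_numpy(dtype=float)

    full_r2 = _r2(_spline_design(x_raw, members, k), y)
    result = MarkerSelectionResult(cluster=members, pc1_var=np.nan)
    if full_r2 < r2_target:
        result.markers = members
        result.final_r2 = full_r2
        result.target_unmet = True
        return result

    current = members
    current_r2 = full_r2
    path: list[tuple[str, float]] = []
    while len(current) > 1:
        best_c, best_r2 = None, -np.inf
        for c in current:
            rest = [m for m in current if m != c]
            r2 = _r2(_spline_design(x_raw, rest, k), y)
            if r2 > best_r2:
                best_c, best_r2 = c, r2
        if best_r2 < r2_target:
            break
        current = [m for m in current if m != best_c]
        current_r2 = best_r2
        path.append((best_c, best_r2))

    result.markers = current
    result.final_r2 = current_r2
    result.r2_path = path
    return result
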