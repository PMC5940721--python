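"""Correlation analyses for marker sums and cross-matrix agreement.

Associations are summarised by Spearman's rank correlation with
nonparametric percentile-bootstrap confidence intervals: subjects are
resampled in pairs (keeping each subject's two values together) and the
interval bounds are percentiles of the resampled correlation
distribution.  The headline analysis correlates a representative-PCB
TEQ sum (the selected markers, optionally augmented with PCB#77 and/or
higher-chlorinated dl-PCBs) against total PCDD/F within each biological
matrix; a per-congener table of correlations between matrix pairs
quantifies how well one specimen type proxies another.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import ExposureDataset
from .preprocess import sum_groups


@dataclass
class CorrelationResult:
    label: str
    rho: float
    ci_low: float
    ci_high: float
    level: float
    replicates: int

    def to_row(self) -> dict:
        return {
            "label": self.label,
            "rho": self.rho,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "replicates": self.replicates,
        }


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def rho_with_ci(
    x,
    y,
    B: int = 10000,
    level: float = 0.95,
    seed: Optional[int] = None,
    label: str = "",
) -> CorrelationResult:
    """Spearman correlation with a paired percentile-bootstrap interval.

    ``B`` paired resamples of the ``n`` subjects are drawn with
    replacement; the interval is the ``(1-level)/2`` and
    ``1-(1-level)/2`` percentiles of the resampled correlations.  Ties
    take average ranks throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must be paired")
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rho = _spearman(x, y)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    xr, yr = x[idx], y[idx]
    rx = rankdata(xr, axis=1).astype(float)
    ry = rankdata(yr, axis=1).astype(float)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx * rx).sum(axis=1) * (ry * ry).sum(axis=1))
    good = den > 0
    boot = num[good] / den[good]  # degenerate resamples (all-tied) dropped
    alpha = 1.0 - level
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return CorrelationResult(
        label=label,
        rho=rho,
        ci_low=float(min(lo, rho)),
        ci_high=float(max(hi, rho)),
        level=level,
        replicates=B,
    )


def cross_matrix_table(dataset: ExposureDataset) -> pd.DataFrame:
    """Per-congener Spearman correlation for every pair of matrices.

    Rows are congeners, columns matrix pairs (``maternal_blood|cord_blood``
    etc.); values are Spearman rho over the shared subjects.
    """
    names = list(dataset.matrices)
    if len(names) < 2:
        raise ValueError("need at least 2 matrices")
    out = {}
    for ma, mb in combinations(names, 2):
        xa, xb = dataset.matrices[ma], dataset.matrices[mb]
        out[f"{ma}|{mb}"] = [
            _spearman(xa[c].to_numpy(), xb[c].to_numpy()) for c in dataset.congeners
        ]
    return pd.DataFrame(out, index=dataset.congeners)


def marker_sum_analysis(
    dataset: ExposureDataset,
    markers_per_matrix: dict[str, list[str]],
    pcddf_group: list[str],
    extra_congeners: Optional[dict[str, list[str]]] = None,
    B: int = 10000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> list[CorrelationResult]:
    """Correlate the representative-PCB sum with total PCDD/F per matrix.

    ``markers_per_matrix`` gives the marker congeners whose TEQ values
    are summed in each matrix (any congeners to add across the board,
    e.g. PCB#77, should already be included).  ``extra_congeners`` maps
    a matrix name to additional congeners; for each such matrix a second
    result row is emitted with the augmented sum, mirroring the usual
    presentation where cord tissue is analysed twice (with and without
    the higher-chlorinated dl-PCBs).
    """
    if not pcddf_group:
        raise ValueError("PCDD/F group is empty")
    results: list[CorrelationResult] = []
    rng = np.random.default_rng(seed)
    for m, markers in markers_per_matrix.items():
        if not markers:
            raise ValueError(f"marker set for {m!r} is empty")
        variants = [(m, list(markers))]
        if extra_congeners and m in extra_congeners:
            variants.append(
                (f"{m}+extra", list(dict.fromkeys(markers + extra_congeners[m])))
            )
        for label, mk in variants:
            sums = sum_groups(
                dataset.subset_congeners(
                    list(dict.fromkeys(mk + list(pcddf_group)))
                ),
                {"pcb_sum": mk, "pcddf_sum": list(pcddf_group)},
            )[m]
            results.append(
                rho_with_ci(
                    sums["pcb_sum"],
                    sums["pcddf_sum"],
                    B=B,
                    level=level,
                    seed=int(rng.integers(2**31)),
                    label=label,
                )
            )
    return results


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
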