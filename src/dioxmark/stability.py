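"""Cluster stability by multiscale bootstrap AU p-values.

For every internal node of a reference dendrogram, the bootstrap
probability (BP) at sampling fraction ``lambda`` is the fraction of
``B`` resamples of ``round(lambda * n)`` subjects (drawn with
replacement, then re-ranked, re-dissimilarised and re-clustered with the
same configuration) whose dendrogram contains a subtree with exactly the
node's member set.  BP values across a grid of sampling fractions are
converted to normal quantiles of the complement,
``z = Phi^-1(1 - BP)``, and a two-parameter curve
``z(lambda) = alpha * sqrt(lambda) + beta / sqrt(lambda)`` is fitted by
(weighted) least squares; ``alpha`` estimates the signed distance of
the cluster hypothesis from the data and ``beta`` the boundary
curvature, and the approximately unbiased p-value is
``AU = Phi(-alpha + beta)``.  A genuinely supported cluster has BP
rising with the sampling fraction, hence ``alpha`` negative and AU near
one.  Clusters with AU at or above a threshold (0.95 by default) are
flagged stable.

BP values of exactly 0 or 1 have infinite normal quantiles and carry
no information about the trend in ``lambda``; those sampling fractions
are excluded from the fit.  When fewer than two informative fractions
remain the evidence is unanimous and AU snaps to the clipped bound
``1/(2B)`` or ``1 - 1/(2B)`` on the majority side (no curve is fitted,
``alpha``/``beta`` stay NaN), so a cluster recovered in every single
resample is reported as maximally supported rather than discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .cluster import (
    DendrogramNode,
    dissimilarity_from_ranks,
    merged_member_sets,
    rank_columns,
)

#: Default sampling-fraction grid: the conventional 0.5 .. 1.4 range in
#: steps of 0.1.
DEFAULT_LAMBDAS: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


@dataclass
class ClusteringConfig:
    """How each bootstrap resample is re-clustered."""

    linkage: str = "average"
    tie_rule: str = "average"


@dataclass
class ClusterStabilityRecord:
    """Per-node multiscale bootstrap summary."""

    members: frozenset[str]
    bp: dict[float, float] = field(default_factory=dict)
    replicates: dict[float, int] = field(default_factory=dict)
    alpha: float = math.nan
    beta: float = math.nan
    au: float = math.nan
    stable: bool = False
    fit_ok: bool = False
    #: number of sampling fractions whose BP was strictly inside the
    #: clipping bounds (diagnostic; the fit uses every fraction)
    n_interior: int = 0


def bootstrap_bp(
    x,
    reference: DendrogramNode,
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS,
    B: int = 1000,
    clustering: Optional[ClusteringConfig] = None,
    seed: Optional[int] = None,
) -> dict[frozenset[str], ClusterStabilityRecord]:
    """Estimate BP for every internal node of ``reference``.

    Parameters
    ----------
    x
        Subjects x congeners DataFrame (the matrix that produced
        ``reference``).
    reference
        Dendrogram whose nodes are scored.  Leaves are skipped (they are
        trivially present); the root is kept (BP is identically 1, a
        useful self-check).
    lambdas
        Sampling fractions; each resample has ``round(lambda * n)``
        subjects.  Fractions giving fewer than 3 subjects are skipped
        with a warning.
    B
        Replicates per sampling fraction.
    clustering
        Linkage and tie rule applied to every resample.
    seed
        Seeds subject resampling and (if ``tie_rule="random"``) the rank
        tie-splitting.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cfg = clustering or ClusteringConfig()
    n, p = x.shape
    if n < 4:
        raise ValueError("need at least 4 subjects for the bootstrap")
    labels = list(x.columns)
    idx_of = {c: i for i, c in enumerate(labels)}
    a = x.to_numpy(dtype=float)

    nodes = [nd for nd in reference.internal_nodes()]
    targets = {
        nd.members: frozenset(idx_of[c] for c in nd.members) for nd in nodes
    }
    records = {
        members: ClusterStabilityRecord(members=members) for members in targets
    }

    rng = np.random.default_rng(seed)
    for lam in lambdas:
        m = int(round(lam * n))
        if m < 3:
            warnings.warn(
                f"sampling fraction {lam} gives {m} < 3 subjects; skipped",
                stacklevel=2,
            )
            continue
        counts = {members: 0 for members in targets}
        for _ in range(B):
            rows = rng.integers(0, n, size=m)
            ranks = rank_columns(
                a[rows], cfg.tie_rule, rng if cfg.tie_rule == "random" else None
            )
            d = dissimilarity_from_ranks(ranks)
            present = merged_member_sets(d, cfg.linkage)
            for members, as_idx in targets.items():
                if as_idx in present:
                    counts[members] += 1
        for members in targets:
            records[members].bp[lam] = counts[members] / B
            records[members].replicates[lam] = B
    return records


def fit_au(
    record: ClusterStabilityRecord, weighting: str = "ml"
) -> ClusterStabilityRecord:
    """Fit ``z(lambda) = alpha*sqrt(lambda) + beta/sqrt(lambda)`` and set AU.

    ``z`` is the normal quantile of the complement of BP, so the fitted
    ``alpha`` (distance) and ``beta`` (curvature) give
    ``AU = Phi(-alpha + beta)``.

    Three fitting schemes are offered.  ``"ml"`` (default) maximises
    the binomial likelihood of the BP counts under
    ``BP(lambda) = 1 - Phi(z(lambda))``; unlike the least-squares
    schemes it uses the information in sampling fractions where every
    replicate recovered (or missed) the cluster, which matters when
    ``B`` cannot resolve probabilities that close to 0 or 1.
    ``"wls"`` performs weighted least squares on the z-values with
    delta-method binomial weights ``B * phi(z)^2 / (BP (1 - BP))``;
    ``"ols"`` weights all fractions equally.  The least-squares schemes
    exclude degenerate BP values (exactly 0 or 1), whose z is infinite;
    on an exact closed-form BP curve they reproduce the generating
    coefficients to numerical precision.

    With fewer than two informative (non-degenerate) fractions and no
    ML information to exploit beyond unanimity, AU snaps to the clipped
    bound ``1/(2B)`` or ``1 - 1/(2B)`` on the majority side and
    ``alpha``/``beta`` stay NaN.  ``fit_ok`` is False only when the
    record holds fewer than two sampling fractions altogether.
    """
    if weighting not in ("ml", "wls", "ols"):
        raise ValueError(f"unknown weighting {weighting!r}")
    lams = sorted(record.bp)
    if len(lams) < 2:
        record.fit_ok = False
        record.au = math.nan if not lams else record.bp[lams[0]]
        return record

    bp = np.array([record.bp[l] for l in lams])
    b = np.array([record.replicates[l] for l in lams], dtype=float)
    lam = np.asarray(lams, dtype=float)
    usable = (bp > 0.0) & (bp < 1.0)
    record.n_interior = int(usable.sum())

    if usable.sum() < 2:
        # unanimous (or nearly so) evidence at 0 or 1: no trend to fit
        record.alpha = math.nan
        record.beta = math.nan
        bound = 1.0 / (2.0 * float(b.max()))
        record.au = float(1.0 - bound) if bp.mean() >= 0.5 else float(bound)
        record.fit_ok = True
        return record

    # least-squares fit on the informative fractions (also the ML start)
    bp_u, b_u, lam_u = bp[usable], b[usable], lam[usable]
    z = norm.ppf(1.0 - bp_u)
    design = np.column_stack([np.sqrt(lam_u), 1.0 / np.sqrt(lam_u)])
    if weighting == "wls":
        w = b_u * norm.pdf(z) ** 2 / (bp_u * (1.0 - bp_u))
    else:
        w = np.ones_like(z)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)

    if weighting == "ml":
        coef = _ml_fit(bp, b, lam, coef)

    record.alpha, record.beta = float(coef[0]), float(coef[1])
    record.au = float(norm.cdf(-record.alpha + record.beta))
    record.fit_ok = True
    return record


def _ml_fit(bp: np.ndarray, b: np.ndarray, lam: np.ndarray, start: np.ndarray):
    """Binomial ML estimate of (alpha, beta) over all sampling fractions."""
    from scipy.optimize import minimize

    k = np.round(bp * b)
    sqrt_l = np.sqrt(lam)
    inv_sqrt_l = 1.0 / sqrt_l
    tiny = 1e-12

    def nll(theta):
        zc = np.clip(theta[0] * sqrt_l + theta[1] * inv_sqrt_l, -8.0, 8.0)
        p = np.clip(norm.sf(zc), tiny, 1.0 - tiny)
        return -float(k @ np.log(p) + (b - k) @ np.log1p(-p))

    res = minimize(
        nll,
        np.clip(start, -8.0, 8.0),
        method="L-BFGS-B",
        bounds=[(-10.0, 10.0)] * 2,
    )
    return res.x


def fit_all(
    records: dict[frozenset[str], ClusterStabilityRecord],
    weighting: str = "ml",
    threshold: float = 0.95,
    n_leaves: Optional[int] = None,
) -> dict[frozenset[str], ClusterStabilityRecord]:
    """Fit AU for every record and set the stable flag.

    The root (member count equal to ``n_leaves``, inferred as the
    largest record when not given) and singletons are never flagged
    stable: their presence in every dendrogram is vacuous.
    """
    total = n_leaves
    if total is None and records:
        total = max(len(m) for m in records)
    for rec in records.values():
        fit_au(rec, weighting)
        rec.stable = bool(
            rec.fit_ok
            and rec.au >= threshold
            and 1 < len(rec.members) < (total or 2)
        )
    return records


def stable_clusters(
    records: dict[frozenset[str], ClusterStabilityRecord],
    threshold: float = 0.95,
    n_leaves: Optional[int] = None,
) -> list[frozenset[str]]:
    """Member sets with a trustworthy AU at or above ``threshold``.

    Singletons and the root (the full congener set, inferred as the
    largest record unless ``n_leaves`` is given) are excluded; results
    are ordered by AU, descending.
    """
    if not records:
        return []
    total = n_leaves if n_leaves is not None else max(len(m) for m in records)
    kept = [
        rec
        for rec in records.values()
        if rec.fit_ok and rec.au >= threshold and 1 < len(rec.members) < total
    ]
    kept.sort(key=lambda r: (-r.au, sorted(r.members)))
    for rec in kept:
        rec.stable = True
    return [rec.members for rec in kept]
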