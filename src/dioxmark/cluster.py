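"""Congener clustering on Spearman dissimilarity.

Co-variation between congeners within one biological matrix is measured
by ``d = 1 - |rho|`` with ``rho`` the Spearman rank correlation over
subjects, so that strongly correlated congeners are close regardless of
the sign of the association, and any strictly monotone rescaling of a
congener (e.g. TEQ conversion) leaves the dissimilarity unchanged.

Agglomeration is standard hierarchical clustering (average linkage by
default, complete and single offered) with a documented deterministic
tie-break: among equally close pairs, the pair whose sorted member
tuples compare lexicographically smallest (in input column order) is
merged first, so dendrograms are bit-reproducible.

LOD/2 substitution leaves many tied values in weakly detected
congeners; ranks can split such ties either by mid-ranks
(``tie_rule="average"``, deterministic) or uniformly at random with a
seed (``tie_rule="random"``), matching the rank-splitting convention of
the original analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

LINKAGES = ("average", "complete", "single")


@dataclass
class DissimilarityMatrix:
    """Symmetric congener dissimilarity table, ``d_ij = 1 - |rho_ij|``."""

    labels: list[str]
    d: pd.DataFrame

    def __post_init__(self) -> None:
        a = self.d.to_numpy()
        if a.shape[0] != a.shape[1] or list(self.d.index) != self.labels:
            raise ValueError("dissimilarity table misaligned with labels")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("dissimilarity table is not symmetric")
        if (a < -1e-12).any() or (a > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")

    def to_csv(self, path) -> None:
        self.d.to_csv(path, index_label="congener_id")


@dataclass
class DendrogramNode:
    """A dendrogram subtree: member set, merge height, two children (or leaf)."""

    members: frozenset[str]
    height: float
    children: Optional[tuple["DendrogramNode", "DendrogramNode"]] = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def internal_nodes(self) -> list["DendrogramNode"]:
        """All non-leaf nodes of the subtree, root included, post-order."""
        out: list[DendrogramNode] = []
        if self.children is not None:
            for ch in self.children:
                out.extend(ch.internal_nodes())
            out.append(self)
        return out

    def member_sets(self) -> set[frozenset[str]]:
        return {n.members for n in self.internal_nodes()}

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""

        def rec(node: DendrogramNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                (label,) = node.members
                return f"{label}:{bl:.10g}"
            a, b = node.children
            return f"({rec(a, node.height)},{rec(b, node.height)}):{bl:.10g}"

        a, b = self.children
        return f"({rec(a, self.height)},{rec(b, self.height)});"


# ---------------------------------------------------------------------------
# rank / dissimilarity primitives (array fast path shared with the bootstrap)
# ---------------------------------------------------------------------------

def rank_columns(
    x: np.ndarray, tie_rule: str = "average", rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Column-wise ranks; ties by mid-rank or seeded random splitting."""
    if tie_rule == "average":
        return rankdata(x, axis=0)
    if tie_rule == "random":
        if rng is None:
            raise ValueError("tie_rule='random' requires an rng")
        n, p = x.shape
        ranks = np.empty((n, p))
        seq = np.arange(1, n + 1, dtype=float)
        for j in range(p):
            order = np.lexsort((rng.random(n), x[:, j]))
            ranks[order, j] = seq
        return ranks
    raise ValueError(f"unknown tie_rule {tie_rule!r}")


def dissimilarity_from_ranks(ranks: np.ndarray) -> np.ndarray:
    """``1 - |corr|`` of rank columns; constant columns yield d = 1."""
    r = ranks - ranks.mean(axis=0)
    norm = np.sqrt((r * r).sum(axis=0))
    ok = norm > 0
    r[:, ok] /= norm[ok]
    rho = r.T @ r
    rho[~ok, :] = 0.0
    rho[:, ~ok] = 0.0
    d = 1.0 - np.abs(np.clip(rho, -1.0, 1.0))
    np.fill_diagonal(d, 0.0)
    return d


def spearman_matrix(
    x: pd.DataFrame, tie_rule: str = "average", seed: Optional[int] = None
) -> DissimilarityMatrix:
    """Spearman dissimilarity between congener columns.

    With ``tie_rule="average"`` a congener constant across subjects has
    an undefined rank correlation and is rejected; with
    ``tie_rule="random"`` its ties are split randomly (seeded).
    """
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if p < 2:
        raise ValueError("need at least 2 congeners")
    a = x.to_numpy(dtype=float)
    if tie_rule == "average":
        constant = [c for j, c in enumerate(x.columns) if np.ptp(a[:, j]) == 0]
        if constant:
            raise ValueError(
                f"Spearman correlation undefined for constant congeners "
                f"{constant} under average ties; use tie_rule='random' or drop them"
            )
    rng = np.random.default_rng(seed) if tie_rule == "random" else None
    ranks = rank_columns(a, tie_rule, rng)
    d = dissimilarity_from_ranks(ranks)
    labels = list(x.columns)
    return DissimilarityMatrix(labels, pd.DataFrame(d, index=labels, columns=labels))


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------

def merge_sequence(
    d: np.ndarray, linkage: str = "average"
) -> list[tuple[tuple[int, ...], tuple[int, ...], float]]:
    """Agglomerative merge order on a square dissimilarity array.

    Returns one ``(members_a, members_b, height)`` triple per merge,
    member tuples holding sorted column indices.  Ties in the minimum
    linkage distance are broken by the lexicographically smallest sorted
    pair of member tuples.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    p = d.shape[0]
    D = d.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(p)}
    sizes = np.ones(p)
    alive = np.ones(p, dtype=bool)
    merges = []
    for _ in range(p - 1):
        flat = int(np.argmin(D))
        i, j = divmod(flat, p)
        h = D[i, j]
        ties = np.argwhere(D == h)
        if len(ties) > 2:  # symmetric pairs appear twice
            best = None
            for a, b in ties:
                if a < b:
                    key = tuple(sorted((members[a], members[b])))
                    if best is None or key < best[0]:
                        best = (key, int(a), int(b))
            i, j = best[1], best[2]
        elif i > j:
            i, j = j, i
        ma, mb = sorted((members[i], members[j]))
        merges.append((ma, mb, float(h)))
        di, dj = D[i].copy(), D[j].copy()
        if linkage == "average":
            new = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        elif linkage == "complete":
            new = np.maximum(di, dj)
        else:
            new = np.minimum(di, dj)
        new[~alive] = np.inf
        D[i, :] = new
        D[:, i] = new
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        alive[j] = False
        sizes[i] += sizes[j]
        members[i] = tuple(sorted(members[i] + members[j]))
        del members[j]
    return merges


def min_decision_gap(d: np.ndarray, linkage: str = "average") -> float:
    """Smallest margin by which any merge decision was made.

    Replays the agglomeration and returns the minimum, over merge steps,
    of the difference between the chosen linkage distance and the next
    distinct candidate distance.  A gap near zero means the dendrogram
    depends on the tie-break and cannot be compared across
    implementations with different tie conventions.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    p = d.shape[0]
    D = d.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    sizes = np.ones(p)
    alive = np.ones(p, dtype=bool)
    gap = np.inf
    for _ in range(p - 1):
        flat = int(np.argmin(D))
        i, j = divmod(flat, p)
        if i > j:
            i, j = j, i
        h = D[i, j]
        if (D == h).sum() > 2:  # symmetric entries count twice
            return 0.0
        bigger = D[D > h]
        if bigger.size:
            gap = min(gap, float(bigger.min() - h))
        di, dj = D[i].copy(), D[j].copy()
        if linkage == "average":
            new = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        elif linkage == "complete":
            new = np.maximum(di, dj)
        else:
            new = np.minimum(di, dj)
        new[~alive] = np.inf
        D[i, :] = new
        D[:, i] = new
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        alive[j] = False
        sizes[i] += sizes[j]
    return gap


def merged_member_sets(d: np.ndarray, linkage: str = "average") -> set[frozenset[int]]:
    """Member index sets of every internal node of the dendrogram on ``d``."""
    out: set[frozenset[int]] = set()
    for ma, mb, _ in merge_sequence(d, linkage):
        out.add(frozenset(ma + mb))
    return out


def agglomerate(D: DissimilarityMatrix, linkage: str = "average") -> DendrogramNode:
    """Build the dendrogram for a dissimilarity matrix.

    Heights are the linkage distances at each merge; leaves sit at
    height 0.
    """
    labels = D.labels
    merges = merge_sequence(D.d.to_numpy(), linkage)
    nodes: dict[tuple[int, ...], DendrogramNode] = {
        (i,): DendrogramNode(frozenset([c]), 0.0) for i, c in enumerate(labels)
    }
    root = None
    for ma, mb, h in merges:
        a, b = nodes.pop(ma), nodes.pop(mb)
        node = DendrogramNode(a.members | b.members, h, (a, b))
        nodes[tuple(sorted(ma + mb))] = node
        root = node
    return root
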