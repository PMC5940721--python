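import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from dioxmark.cluster import (
    DissimilarityMatrix,
    agglomerate,
    merge_sequence,
    min_decision_gap,
    spearman_matrix,
)


def brute_force_spearman_d(x: pd.DataFrame) -> np.ndarray:
    """Independent oracle: ranks from explicit sorting, pairwise loops."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    p = x.shape[1]
    d = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            ri = ranks(x.iloc[:, i].to_numpy())
            rj = ranks(x.iloc[:, j].to_numpy())
            rho = np.corrcoef(ri, rj)[0, 1]
            d[i, j] = 1 - abs(rho)
    np.fill_diagonal(d, 0)
    return d


class TestSpearmanMatrix:
    def test_monotone_transform_gives_zero_distance(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": np.exp(x)})
        d = spearman_matrix(df).d
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_negation_gives_zero_distance(self, rng):
        x = rng.normal(size=30)
        d = spearman_matrix(pd.DataFrame({"a": x, "b": -x})).d
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(12, 5)), columns=list("abcde")
        )
        # inject ties to exercise the average rule
        df.iloc[0, 0] = df.iloc[1, 0]
        d = spearman_matrix(df).d.to_numpy()
        assert np.allclose(d, brute_force_spearman_d(df), atol=1e-12)

    def test_constant_column_rejected_under_average_ties(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="b"):
            spearman_matrix(df)

    def test_random_tie_rule_is_seeded(self):
        df = pd.DataFrame(
            {"a": [1.0, 1.0, 2.0, 2.0, 3.0], "b": [2.0, 1.0, 5.0, 4.0, 3.0]}
        )
        d1 = spearman_matrix(df, tie_rule="random", seed=42).d
        d2 = spearman_matrix(df, tie_rule="random", seed=42).d
        pd.testing.assert_frame_equal(d1, d2)

    def test_invariant_under_monotone_transform(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        d1 = spearman_matrix(df).d.to_numpy()
        df2 = df.copy()
        df2["b"] = np.exp(df2["b"])
        df2["c"] = df2["c"] ** 3
        d2 = spearman_matrix(df2).d.to_numpy()
        assert np.allclose(d1, d2, atol=1e-12)


class TestAgglomerate:
    def _dm(self, d, labels):
        return DissimilarityMatrix(
            labels, pd.DataFrame(d, index=labels, columns=labels)
        )

    def test_two_leaves_single_root(self):
        dm = self._dm(np.array([[0.0, 0.3], [0.3, 0.0]]), ["a", "b"])
        root = agglomerate(dm)
        assert root.members == frozenset(["a", "b"])
        assert root.height == pytest.approx(0.3)
        assert all(ch.is_leaf for ch in root.children)

    def test_two_perfect_blocks(self):
        labels = list("abcd")
        d = np.full((4, 4), 0.8)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        np.fill_diagonal(d, 0.0)
        root = agglomerate(self._dm(d, labels))
        kids = {ch.members for ch in root.children}
        assert kids == {frozenset("ab"), frozenset("cd")}

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_matches_scipy_linkage(self, linkage, rng):
        """Merge heights and member sets match scipy's implementation."""
        from scipy.spatial.distance import squareform

        for _ in range(20):
            while True:
                p = int(rng.integers(5, 7))
                rho = np.corrcoef(rng.normal(size=(p, 30)))
                d = 1 - np.abs(rho)
                np.fill_diagonal(d, 0.0)
                d = (d + d.T) / 2
                if min_decision_gap(d, linkage) > 1e-9:
                    break
            labels = [f"c{i}" for i in range(p)]
            z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
            ours = merge_sequence(d, linkage)
            assert np.allclose(
                sorted(h for _, _, h in ours), sorted(z[:, 2]), atol=1e-12
            )
            scipy_sets = {
                frozenset(leaves)
                for leaves in _scipy_member_sets(z, p)
            }
            our_sets = {frozenset(a + b) for a, b, _ in ours}
            assert our_sets == scipy_sets

    def test_average_height_bounded_by_pairwise_extremes(self, rng):
        rho = np.corrcoef(rng.normal(size=(6, 40)))
        d = 1 - np.abs(rho)
        np.fill_diagonal(d, 0.0)
        for a, b, h in merge_sequence(d, "average"):
            pair_d = [d[i, j] for i in a for j in b]
            assert min(pair_d) - 1e-12 <= h <= max(pair_d) + 1e-12

    def test_deterministic_tie_break(self):
        # all distances equal: merges must follow lexicographic member order
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        merges = merge_sequence(d, "average")
        assert merges[0][:2] == ((0,), (1,))
        assert merges[1][:2] == ((0, 1), (2,))
        assert merges[2][:2] == ((0, 1, 2), (3,))


def _scipy_member_sets(z, p):
    members = {i: (i,) for i in range(p)}
    out = []
    for step, (i, j, _, _) in enumerate(z):
        merged = tuple(sorted(members[int(i)] + members[int(j)]))
        members[p + step] = merged
        out.append(merged)
    return out


class TestNewick:
    def test_round_trip_leaf_set_and_heights(self, two_block_dataset):
        import io

        from Bio import Phylo

        x = two_block_dataset.matrices["maternal_blood"]
        root = agglomerate(spearman_matrix(x))
        nwk = root.to_newick()
        tree = Phylo.read(io.StringIO(nwk), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == set(x.columns)
        # path length from root to any leaf equals the root height
        depths = tree.depths()
        leaf_depths = [v for k, v in depths.items() if k.name in leaves]
        assert np.allclose(leaf_depths, root.height, atol=1e-9)
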