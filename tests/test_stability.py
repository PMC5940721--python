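import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dioxmark.cluster import agglomerate, spearman_matrix
from dioxmark.stability import (
    DEFAULT_LAMBDAS,
    ClusterStabilityRecord,
    bootstrap_bp,
    fit_all,
    fit_au,
    stable_clusters,
)


def record_from_curve(alpha, beta, lambdas=DEFAULT_LAMBDAS, B=10**9):
    """BP values lying exactly on z(lambda) = alpha*sqrt(l) + beta/sqrt(l)."""
    rec = ClusterStabilityRecord(members=frozenset({"x", "y"}))
    for lam in lambdas:
        z = alpha * math.sqrt(lam) + beta / math.sqrt(lam)
        rec.bp[lam] = float(1.0 - norm.cdf(z))
        rec.replicates[lam] = B
    return rec


class TestFitAu:
    @pytest.mark.parametrize("weighting", ["ols", "wls"])
    def test_exact_curve_recovery(self, weighting):
        """Least-squares fit inverts an exact z-curve to numerical precision."""
        rec = record_from_curve(-1.0, 0.2)
        fit_au(rec, weighting=weighting)
        assert rec.alpha == pytest.approx(-1.0, abs=1e-8)
        assert rec.beta == pytest.approx(0.2, abs=1e-8)
        assert rec.au == pytest.approx(norm.cdf(1.2), abs=1e-8)

    def test_symmetric_coefficients_give_half(self):
        rec = fit_au(record_from_curve(0.7, 0.7), weighting="ols")
        assert rec.au == pytest.approx(0.5, abs=1e-10)

    def test_ml_recovers_exact_curve(self):
        rec = fit_au(record_from_curve(-0.8, 0.1, B=10**6), weighting="ml")
        assert rec.alpha == pytest.approx(-0.8, abs=1e-3)
        assert rec.beta == pytest.approx(0.1, abs=1e-3)

    def test_all_unanimous_bp_snaps_high(self):
        rec = ClusterStabilityRecord(members=frozenset({"x", "y"}))
        for lam in DEFAULT_LAMBDAS:
            rec.bp[lam] = 1.0
            rec.replicates[lam] = 1000
        fit_au(rec)
        assert rec.au > 0.999
        assert rec.fit_ok
        assert math.isnan(rec.alpha)

    def test_all_zero_bp_snaps_low(self):
        rec = ClusterStabilityRecord(members=frozenset({"x", "y"}))
        for lam in DEFAULT_LAMBDAS:
            rec.bp[lam] = 0.0
            rec.replicates[lam] = 1000
        fit_au(rec)
        assert rec.au < 0.001

    def test_single_lambda_not_fittable(self):
        rec = ClusterStabilityRecord(members=frozenset({"x", "y"}))
        rec.bp[1.0] = 0.8
        rec.replicates[1.0] = 100
        fit_au(rec)
        assert not rec.fit_ok


class TestStableClusters:
    def _rec(self, members, au, fit_ok=True):
        r = ClusterStabilityRecord(members=frozenset(members))
        r.au, r.fit_ok = au, fit_ok
        return r

    def test_threshold_is_inclusive(self):
        recs = {r.members: r for r in [self._rec("ab", 0.95), self._rec("cd", 0.949)]}
        out = stable_clusters(recs, threshold=0.95, n_leaves=5)
        assert out == [frozenset("ab")]

    def test_unfittable_excluded(self):
        recs = {r.members: r for r in [self._rec("ab", 0.99, fit_ok=False)]}
        assert stable_clusters(recs, n_leaves=5) == []

    def test_root_excluded_and_order(self):
        recs = {
            r.members: r
            for r in [
                self._rec("abcde", 1.0),
                self._rec("ab", 0.96),
                self._rec("cde", 0.99),
            ]
        }
        out = stable_clusters(recs, n_leaves=5)
        assert out == [frozenset("cde"), frozenset("ab")]

    def test_empty(self):
        assert stable_clusters({}, n_leaves=3) == []


class TestBootstrapBP:
    def test_duplicate_columns_bp_one_everywhere(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame(
            {"a": x, "b": x * 2 + 1, "c": rng.normal(size=30),
             "d": rng.normal(size=30)}
        )
        root = agglomerate(spearman_matrix(df))
        recs = bootstrap_bp(df, root, lambdas=(0.5, 1.0, 1.4), B=100, seed=0)
        assert all(v == 1.0 for v in recs[frozenset(["a", "b"])].bp.values())

    def test_root_bp_one_everywhere(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        root = agglomerate(spearman_matrix(df))
        recs = bootstrap_bp(df, root, lambdas=(0.6, 1.0), B=50, seed=1)
        assert all(v == 1.0 for v in recs[frozenset("abcd")].bp.values())

    def test_binomial_dispersion_across_seeds(self, two_block_dataset):
        """BP replication noise is consistent with a binomial proportion."""
        x = two_block_dataset.matrices["maternal_blood"]
        root = agglomerate(spearman_matrix(x))
        node = frozenset(["PCB105", "PCB118", "PCB123", "PCB126"])
        B = 200
        bps = [
            bootstrap_bp(x, root, lambdas=(0.5,), B=B, seed=s)[node].bp[0.5]
            for s in range(12)
        ]
        p = float(np.mean(bps))
        assert 0 < p <= 1
        expected_sd = math.sqrt(p * (1 - p) / B)
        assert np.std(bps) < 4 * max(expected_sd, 1e-3)

    def test_small_lambda_skipped_with_warning(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        root = agglomerate(spearman_matrix(df))
        with pytest.warns(UserWarning, match="skipped"):
            recs = bootstrap_bp(df, root, lambdas=(0.1, 1.0), B=20, seed=2)
        rec = next(iter(recs.values()))
        assert 0.1 not in rec.bp and 1.0 in rec.bp

    def test_deterministic_given_seed(self, two_block_dataset):
        x = two_block_dataset.matrices["cord_blood"]
        root = agglomerate(spearman_matrix(x))
        r1 = bootstrap_bp(x, root, lambdas=(0.8, 1.0), B=100, seed=9)
        r2 = bootstrap_bp(x, root, lambdas=(0.8, 1.0), B=100, seed=9)
        assert all(r1[k].bp == r2[k].bp for k in r1)


def test_planted_blocks_flagged_stable(two_block_dataset):
    """Both planted 4-congener blocks reach AU >= 0.95 on one cohort."""
    x = two_block_dataset.matrices["maternal_blood"]
    root = agglomerate(spearman_matrix(x))
    recs = fit_all(bootstrap_bp(x, root, B=400, seed=3))
    stable = set(stable_clusters(recs, n_leaves=x.shape[1]))
    assert frozenset(["PCB105", "PCB118", "PCB123", "PCB126"]) in stable
    assert frozenset(["PCB156", "PCB157", "PCB167", "PCB169"]) in stable
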