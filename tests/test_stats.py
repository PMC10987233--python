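"""PERMDISP and exact signed-rank test behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pondvarpart import permdisp, wilcoxon_paired_exact
from pondvarpart.stats import st_relative_excluding_time


class TestWilcoxon:
    def test_seven_direction_consistent_pairs(self):
        """Seven pairs all moving one way: the statistic hits its extremum
        and the exact two-sided p is 2/2^7 = 0.015625 ≈ 0.016."""
        base = np.array([0.3, 0.5, 0.2, 0.7, 0.4, 0.6, 0.1])
        up = wilcoxon_paired_exact(base + 0.05, base)
        down = wilcoxon_paired_exact(base, base + 0.05)
        assert up.V == 28.0  # 7·8/2
        assert down.V == 0.0
        assert up.p == pytest.approx(2.0 / 2.0**7)
        assert down.p == pytest.approx(2.0 / 2.0**7)
        assert round(up.p, 3) == 0.016

    def test_symmetric_two_pairs(self):
        res = wilcoxon_paired_exact(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert res.p == 1.0

    def test_zero_differences_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero difference"):
            res = wilcoxon_paired_exact(
                np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0])
            )
        assert res.n == 2

    def test_all_zero_differences_fail(self):
        with pytest.raises(ValueError, match="no informative pairs"):
            wilcoxon_paired_exact(np.ones(4), np.ones(4))

    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_matches_scipy_exact_distribution(self, diffs):
        """Agreement with an independent exact implementation on tie-free
        integer differences."""
        from scipy.stats import wilcoxon as scipy_wilcoxon

        # scipy's exact mode requires tie-free nonzero differences
        d = np.array([float(v) for v in diffs if v != 0])
        if len(d) < 3 or len(set(np.abs(d))) != len(d):
            return
        x = np.cumsum(np.abs(d) * 0 + 1.0)
        ours = wilcoxon_paired_exact(x + d, x)
        theirs = scipy_wilcoxon(x + d, x, mode="exact")
        assert ours.p == pytest.approx(theirs.pvalue, abs=1e-12)

    def test_normal_approximation_agreement_at_n10(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        y = x + rng.standard_normal(10) * 0.8 + 0.3
        res = wilcoxon_paired_exact(x, y)
        # large-sample normal reference
        n = res.n
        mu = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        z = (abs(res.V - mu) - 0.5) / sd  # continuity-corrected
        from scipy.stats import norm

        p_norm = 2 * norm.sf(z)
        assert abs(res.p - p_norm) < 0.02

    def test_statistic_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.standard_normal(8)
            y = rng.standard_normal(8)
            res = wilcoxon_paired_exact(x, y)
            assert 0 <= res.V <= res.n * (res.n + 1) / 2
            assert 0 < res.p <= 1


class TestPermdisp:
    def _two_groups(self, seed, scale=1.0, n=30, p=5):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((n, p))
        B = rng.standard_normal((n, p)) * scale
        return np.vstack([A, B]), np.array(["a"] * n + ["b"] * n)

    def test_identical_groups_give_zero_F(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((15, 4))
        X = np.vstack([A, A])
        g = np.array(["a"] * 15 + ["b"] * 15)
        res = permdisp(X, g, n_perm=99, seed=0)
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_detects_tripled_dispersion(self):
        X, g = self._two_groups(3, scale=3.0)
        res = permdisp(X, g, n_perm=999, seed=0)
        assert res.p <= 0.01

    def test_p_resolution_and_range(self):
        X, g = self._two_groups(4)
        res = permdisp(X, g, n_perm=199, seed=1)
        assert 0 < res.p <= 1
        assert (res.p * 200) == pytest.approx(round(res.p * 200))

    def test_reproducible_and_order_invariant(self):
        X, g = self._two_groups(5)
        r1 = permdisp(X, g, n_perm=199, seed=7)
        r2 = permdisp(X, g, n_perm=199, seed=7)
        assert r1.p == r2.p and r1.F == r2.F
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(g))
        r3 = permdisp(X[perm], g[perm], n_perm=199, seed=7)
        assert r3.F == pytest.approx(r1.F, abs=1e-10)

    def test_agrees_with_skbio_centroid_F(self):
        """Cross-check the F statistic against scikit-bio's PERMDISP."""
        from skbio.stats.distance import DistanceMatrix, permdisp as skbio_permdisp
        from scipy.spatial.distance import pdist, squareform

        X, g = self._two_groups(6, n=20, p=4)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        res = permdisp(X, g, n_perm=99, seed=0, center="centroid")
        dm = DistanceMatrix(squareform(pdist(Xs)))
        ref = skbio_permdisp(dm, pd.Series(g, index=dm.ids, name="group"),
                             test="centroid", permutations=99)
        assert res.F == pytest.approx(float(ref["test statistic"]), rel=1e-6)

    def test_median_variant_differs_from_centroid(self):
        X, g = self._two_groups(8)
        rm = permdisp(X, g, n_perm=99, seed=0, center="median")
        rc = permdisp(X, g, n_perm=99, seed=0, center="centroid")
        assert rm.F != rc.F  # distinct centre definitions

    def test_degenerate_groups_rejected(self):
        X = np.random.default_rng(9).standard_normal((4, 3))
        with pytest.raises(ValueError):
            permdisp(X, np.array(["a", "a", "a", "b"]), n_perm=9)
        with pytest.raises(ValueError):
            permdisp(X, np.array(["a"] * 4), n_perm=9)


def test_st_relative_excluding_time_renormalizes():
    class Dummy:
        corrected = None
        fractions = {
            "pure_E": 0.1, "pure_S": 0.2, "pure_T": 0.3,
            "ES_given_T": 0.1, "ET_given_S": 0.05, "ST_given_E": 0.05,
            "EST": 0.0,
        }

    rel = st_relative_excluding_time(Dummy())
    assert rel["pure_E"] == pytest.approx(0.25)
    assert rel["pure_S"] == pytest.approx(0.5)
    assert rel["common"] == pytest.approx(0.25)
    assert sum(rel.values()) == pytest.approx(1.0)
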