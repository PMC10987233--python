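"""Inclusion–exclusion identities, linear bridge, truncation and correction."""

import numpy as np
import pandas as pd
import pytest

from pondvarpart import (
    SmoothSpec,
    correct_env,
    partition_three,
    partition_two,
    relative_fractions,
)
from pondvarpart.partition import _fractions_three


def _random_instance(seed, n=24):
    r = np.random.default_rng(seed)
    pred = pd.DataFrame(
        {
            "e1": r.uniform(0, 1, n),
            "e2": r.uniform(0, 1, n),
            "x_km": r.uniform(0, 100, n),
            "y_km": r.uniform(0, 100, n),
            "days": np.resize([0.0, 150.0, 250.0], n),
        }
    )
    y = r.standard_normal((n, r.integers(1, 3)))
    E = [SmoothSpec(("e1",), k=4)]
    if r.random() < 0.5:
        E.append(SmoothSpec(("e2",), k=4))
    S = [SmoothSpec(("x_km", "y_km"), k=6)]
    T = [SmoothSpec(("days",), k=3)]
    return y, pred, E, S, T


class TestIdentities:
    @pytest.mark.parametrize("seed", range(25))
    def test_two_way_fractions_sum_to_total(self, seed):
        y, pred, E, S, _ = _random_instance(seed)
        res = partition_two(y, pred, E, S)
        assert sum(res.fractions.values()) == pytest.approx(res.total, abs=1e-10)
        # identity with the stored model R²s
        m = res.model_r2
        assert res.fractions["pure_E"] == pytest.approx(m["ES"] - m["S"], abs=1e-12)
        assert res.fractions["common"] == pytest.approx(
            m["E"] + m["S"] - m["ES"], abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(25, 45))
    def test_three_way_fractions_sum_to_total(self, seed):
        y, pred, E, S, T = _random_instance(seed)
        res = partition_three(y, pred, E, S, T)
        assert sum(res.fractions.values()) == pytest.approx(res.total, abs=1e-10)

    def test_identical_E_and_S_sets_pure_zero(self):
        r = np.random.default_rng(1)
        pred = pd.DataFrame({"v": r.uniform(0, 1, 30)})
        y = np.sin(4 * pred["v"].to_numpy()) + 0.2 * r.standard_normal(30)
        same = [SmoothSpec(("v",), k=5)]
        res = partition_two(y, pred, same, same)
        assert res.fractions["pure_E"] == pytest.approx(0.0, abs=1e-10)
        assert res.fractions["pure_S"] == pytest.approx(0.0, abs=1e-10)
        assert res.fractions["common"] == pytest.approx(res.total, abs=1e-10)

    def test_T_redundant_with_S_moves_mass_to_overlap(self):
        r = np.random.default_rng(2)
        n = 30
        pred = pd.DataFrame(
            {"s": r.uniform(0, 1, n), "e": r.uniform(0, 1, n)}
        )
        pred["t"] = pred["s"]  # T identical to the spatial predictor
        y = np.sin(5 * pred["s"].to_numpy()) + 0.1 * r.standard_normal(n)
        res = partition_three(
            y, pred,
            [SmoothSpec(("e",), k=4)],
            [SmoothSpec(("s",), k=4)],
            [SmoothSpec(("t",), k=4)],
        )
        assert res.fractions["pure_T"] == pytest.approx(0.0, abs=1e-10)
        assert res.fractions["pure_S"] == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_empty_selections_flagged(self):
        y = np.random.default_rng(3).standard_normal(20)
        res = partition_two(y, pd.DataFrame(index=range(20)), [], [])
        assert res.total == 0.0
        assert any("degenerate" in f for f in res.flags)


class TestLinearBridge:
    def test_matches_classical_linear_varpart(self):
        """With smooths restricted to their penalty null space the partition
        equals traditional (RDA-style) linear variation partitioning."""
        r = np.random.default_rng(4)
        n = 20
        pred = pd.DataFrame(
            {
                "e1": r.standard_normal(n),
                "e2": r.standard_normal(n),
                "x_km": r.uniform(0, 50, n),
                "y_km": r.uniform(0, 50, n),
            }
        )
        Y = r.standard_normal((n, 2))
        E = [SmoothSpec(("e1",), k=5), SmoothSpec(("e2",), k=5)]
        S = [SmoothSpec(("x_km", "y_km"), k=8)]
        res = partition_two(Y, pred, E, S, linear=True)

        def adj_r2_ols(cols, y):
            X = np.column_stack([np.ones(n)] + cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            tss = float(((y - y.mean()) ** 2).sum())
            p = X.shape[1] - 1
            return 1.0 - (rss / (n - p - 1)) / (tss / (n - 1))

        e_cols = [pred["e1"].to_numpy(), pred["e2"].to_numpy()]
        s_cols = [pred["x_km"].to_numpy(), pred["y_km"].to_numpy()]
        a = np.mean([adj_r2_ols(e_cols, Y[:, j]) for j in range(2)])
        b = np.mean([adj_r2_ols(s_cols, Y[:, j]) for j in range(2)])
        ab = np.mean([adj_r2_ols(e_cols + s_cols, Y[:, j]) for j in range(2)])
        assert res.fractions["pure_E"] == pytest.approx(ab - b, abs=1e-8)
        assert res.fractions["pure_S"] == pytest.approx(ab - a, abs=1e-8)
        assert res.fractions["common"] == pytest.approx(a + b - ab, abs=1e-8)


class TestRelative:
    def test_arithmetic(self):
        res = partition_two(
            np.zeros(5), pd.DataFrame(index=range(5)), [], []
        )
        res.fractions = {"pure_E": 0.2, "pure_S": 0.1, "common": 0.1}
        res.total = 0.4
        rel = relative_fractions(res)
        assert rel == pytest.approx(
            {"pure_E": 0.5, "pure_S": 0.25, "common": 0.25}
        )

    def test_single_nonzero_fraction(self):
        res = partition_two(np.zeros(5), pd.DataFrame(index=range(5)), [], [])
        res.fractions = {"pure_E": 0.3, "pure_S": 0.0, "common": 0.0}
        res.total = 0.3
        assert relative_fractions(res)["pure_E"] == pytest.approx(1.0)

    def test_negative_fraction_truncated_before_normalization(self):
        res = partition_two(np.zeros(5), pd.DataFrame(index=range(5)), [], [])
        res.fractions = {"pure_E": 0.2, "pure_S": -0.03, "common": 0.1}
        res.total = 0.27
        rel = relative_fractions(res)
        assert rel["pure_S"] == 0.0
        assert rel["pure_E"] == pytest.approx(0.2 / 0.3)
        assert sum(rel.values()) == pytest.approx(1.0)

    def test_undefined_when_nothing_explained(self):
        res = partition_two(np.zeros(5), pd.DataFrame(index=range(5)), [], [])
        res.fractions = {"pure_E": -0.1, "pure_S": -0.05, "common": 0.0}
        res.total = -0.15
        assert relative_fractions(res) is None
        assert any("undefined" in f for f in res.flags)


class TestMoebius:
    def test_three_way_mass_formulas_on_synthetic_union_function(self):
        """Against a union function built from known non-negative masses."""
        masses = {
            "pure_E": 0.10, "pure_S": 0.20, "pure_T": 0.05,
            "ES_given_T": 0.08, "ET_given_S": 0.04, "ST_given_E": 0.03,
            "EST": 0.06,
        }
        contains = {
            "E": ["pure_E", "ES_given_T", "ET_given_S", "EST"],
            "S": ["pure_S", "ES_given_T", "ST_given_E", "EST"],
            "T": ["pure_T", "ET_given_S", "ST_given_E", "EST"],
        }
        u = {}
        for key in ("E", "S", "T", "ES", "ET", "ST", "EST"):
            covered = set()
            for c in key:
                covered.update(contains[c])
            u[key] = sum(masses[f] for f in covered)
        rec = _fractions_three(u)
        for k, v in masses.items():
            assert rec[k] == pytest.approx(v, abs=1e-12)


class TestCorrection:
    def test_identity_when_no_env_terms(self):
        r = np.random.default_rng(5)
        coords = r.uniform(0, 100, (10, 2))
        pred = pd.DataFrame({"x_km": coords[:, 0], "y_km": coords[:, 1]})
        y = r.standard_normal(10)
        res = partition_two(y, pred, [], [SmoothSpec(("x_km", "y_km"), k=6)])
        correct_env(res, coords, n_null=9, seed=0)
        assert res.corrected == res.fractions

    def test_too_few_ponds_flagged(self):
        r = np.random.default_rng(6)
        coords = r.uniform(0, 10, (3, 2))
        pred = pd.DataFrame({"e": r.standard_normal(3)})
        y = r.standard_normal(3)
        res = partition_two(y, pred, [SmoothSpec(("e",), k=3)], [])
        correct_env(res, coords, n_null=9, seed=0)
        assert res.corrected is None
        assert any("fewer than 4 ponds" in f for f in res.flags)

    def test_unstructured_env_correction_is_small(self):
        """Spatially unstructured environment: the null removes ~nothing."""
        deltas = []
        for s in range(5):
            r = np.random.default_rng(60 + s)
            n = 30
            coords = r.uniform(0, 100, (n, 2))
            pred = pd.DataFrame(
                {
                    "e": r.standard_normal(n),  # no spatial structure
                    "x_km": coords[:, 0],
                    "y_km": coords[:, 1],
                }
            )
            y = pred["e"].to_numpy() + 0.5 * r.standard_normal(n)
            res = partition_two(
                y, pred, [SmoothSpec(("e",), k=5)], [SmoothSpec(("x_km", "y_km"), k=6)]
            )
            correct_env(res, coords, n_null=49, seed=s)
            env_raw = res.fractions["pure_E"] + res.fractions["common"]
            env_cor = res.corrected["pure_E"] + res.corrected["common"]
            deltas.append(env_raw - env_cor)
        assert abs(np.mean(deltas)) < 0.05


def test_axis_sign_flip_leaves_partition_unchanged():
    r = np.random.default_rng(7)
    n = 30
    pred = pd.DataFrame({"e": r.uniform(0, 1, n), "x_km": r.uniform(0, 50, n),
                         "y_km": r.uniform(0, 50, n)})
    A = r.standard_normal((n, 2))
    E = [SmoothSpec(("e",), k=5)]
    S = [SmoothSpec(("x_km", "y_km"), k=6)]
    res1 = partition_two(A, pred, E, S)
    res2 = partition_two(A * np.array([1.0, -1.0]), pred, E, S)
    for k in res1.fractions:
        assert res1.fractions[k] == pytest.approx(res2.fractions[k], abs=1e-10)
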