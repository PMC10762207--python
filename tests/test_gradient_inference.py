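"""Trend GLMs, collinearity pruning, selection, PCNM, variance partitioning."""

import numpy as np
import pandas as pd
import pytest

from domcascade.gradient_inference import (
    GradientDesign,
    fit_trend,
    forward_select,
    hierarchical_partition,
    pcnm,
    rda_adj_r2,
    reduce_collinear,
    variance_partition,
)


class TestFitTrend:
    def test_two_group_binomial_toy(self):
        """20/100 vs 80/100: closed-form proportions, Wald z ~ 7.84."""
        toy = pd.DataFrame({"succ": [20, 80], "trials": [100, 100], "grp": ["a", "b"]})
        res = fit_trend(
            GradientDesign(data=toy, response="succ", focal="grp",
                           family="binomial", trials="trials")
        )
        means = res.emmeans.set_index("level")["emmean"]
        assert means["a"] == pytest.approx(0.20, abs=1e-9)
        assert means["b"] == pytest.approx(0.80, abs=1e-9)
        assert res.contrasts["p_adj"].iloc[0] < 0.001
        lo, hi = res.emmeans.set_index("level").loc["a", ["ci_low", "ci_high"]]
        assert lo < 0.20 < hi

    def test_constant_response_null_case(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({
            "y": np.full(24, 3.7),
            "grp": np.repeat(["a", "b", "c"], 8),
            "block": list("xy") * 12,
        })
        res = fit_trend(GradientDesign(data=data, response="y", focal="grp",
                                       covariates=("block",)))
        assert np.allclose(res.emmeans["emmean"], 3.7)
        assert np.allclose(res.contrasts["p_adj"], 1.0)

    def test_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame({
            "y": rng.normal(size=40) + np.repeat([0, 0.3, 0.6, 0.2], 10),
            "grp": np.repeat(list("abcd"), 10),
        })
        res = fit_trend(GradientDesign(data=data, response="y", focal="grp"))
        assert (res.contrasts["p_adj"] >= res.contrasts["p_unadj"] - 1e-12).all()

    def test_emmeans_average_over_covariates(self):
        # balanced two-way layout: emmeans equal the plain group means
        rng = np.random.default_rng(1)
        eff = {"a": 0.0, "b": 1.0}
        blk = {"x": 0.0, "y": 2.0}
        rows = []
        for g in "ab":
            for b in "xy":
                for _ in range(10):
                    rows.append(dict(grp=g, block=b, y=eff[g] + blk[b] + rng.normal(0, 0.1)))
        data = pd.DataFrame(rows)
        res = fit_trend(GradientDesign(data=data, response="y", focal="grp",
                                       covariates=("block",)))
        means = res.emmeans.set_index("level")["emmean"]
        grand = data.groupby("grp")["y"].mean()
        assert means["a"] == pytest.approx(grand["a"], abs=0.05)
        assert means["b"] == pytest.approx(grand["b"], abs=0.05)

    def test_interaction_dropped_when_absent(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({
            "y": rng.normal(size=48) + np.tile(np.repeat([0.0, 1.0], 12), 2),
            "grp": np.tile(np.repeat(["a", "b"], 12), 2),
            "blk": np.repeat(["u", "v"], 24),
        })
        res = fit_trend(GradientDesign(data=data, response="y", focal="grp",
                                       covariates=("blk",), interaction_with="blk"))
        assert res.interaction_dropped is True

    def test_logit_family_keeps_means_in_unit_interval(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame({
            "y": np.clip(rng.normal(0.5, 0.2, size=30), 0.01, 0.99),
            "grp": np.repeat(list("abc"), 10),
        })
        res = fit_trend(GradientDesign(data=data, response="y", focal="grp",
                                       family="gaussian-logit"))
        assert ((res.emmeans[["emmean", "ci_low", "ci_high"]] > 0)
                & (res.emmeans[["emmean", "ci_low", "ci_high"]] < 1)).all().all()

    def test_aliased_design_reports_term(self):
        data = pd.DataFrame({
            "y": np.arange(8.0),
            "grp": list("aabbccdd"),
            "dup": list("aabbccdd"),  # perfectly aliased with grp
        })
        with pytest.raises(ValueError, match="aliased"):
            fit_trend(GradientDesign(data=data, response="y", focal="grp",
                                     covariates=("dup",)))


class TestReduceCollinear:
    def test_duplicate_removed(self):
        rng = np.random.default_rng(0)
        v1 = rng.normal(size=60)
        env = pd.DataFrame({"v1": v1, "v2": v1 + rng.normal(0, 1e-9, 60),
                            "v3": rng.normal(size=60)})
        kept = reduce_collinear(env)
        assert "v3" in kept and len(kept) == 2
        assert kept[0] in ("v1", "v2")

    def test_identity_when_uncorrelated(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        assert reduce_collinear(env) == list("abcd")

    def test_chain_matches_direct_rule_simulation(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=300)
        env = pd.DataFrame({
            "v1": base + rng.normal(0, 0.3, 300),
            "v2": base + rng.normal(0, 0.3, 300),
            "v3": base + rng.normal(0, 0.3, 300),
            "v4": rng.normal(size=300),
        })

        # independent brute-force application of the written rule
        kept = list(env.columns)
        while True:
            corr = env[kept].corr().abs()
            offending = [
                (a, b) for i, a in enumerate(kept) for b in kept[i + 1:]
                if corr.loc[a, b] > 0.80
            ]
            if not offending:
                break
            involved = sorted({v for pair in offending for v in pair}, key=kept.index)
            mean_r = {
                v: corr.loc[v, [u for u in kept if u != v]].mean() for v in involved
            }
            worst = max(involved, key=lambda v: (mean_r[v], kept.index(v)))
            kept.remove(worst)

        assert reduce_collinear(env) == kept

    def test_constant_dropped_with_warning(self):
        env = pd.DataFrame({"v1": np.arange(30.0), "v2": np.ones(30),
                            "v3": np.arange(30.0)[::-1]})
        with pytest.warns(UserWarning, match="constant"):
            kept = reduce_collinear(env)
        assert "v2" not in kept


class TestForwardSelect:
    def test_signal_predictor_selected(self):
        exact = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"X1": rng.normal(size=50), "X2": rng.normal(size=50)})
            Y = np.outer(X["X1"], [1.0, 0.6]) + rng.normal(0, 0.5, size=(50, 2))
            selected = forward_select(Y, X, n_perm=99, seed=seed)
            assert "X1" in selected  # the signal predictor is never missed
            if selected == ["X1"]:
                exact += 1
        # X2 slips in at roughly the alpha = 0.10 false-inclusion rate
        assert exact >= 9

    def test_noise_rarely_selected(self):
        empty = 0
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
            Y = rng.normal(size=(50, 2))
            if not forward_select(Y, X, n_perm=99, seed=seed):
                empty += 1
        assert empty >= 8  # ~alpha=0.1 per candidate; most runs select nothing

    def test_single_strong_predictor(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"X1": rng.normal(size=40)})
        Y = np.outer(X["X1"], [1.0]) + rng.normal(0, 0.2, size=(40, 1))
        assert forward_select(Y, X, n_perm=99, seed=1) == ["X1"]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        Y = np.outer(X["a"], [1, 1]) + rng.normal(0, 1.0, size=(40, 2))
        assert forward_select(Y, X, seed=5) == forward_select(Y, X, seed=5)


class TestPCNM:
    def test_two_point_hand_case(self):
        table, ev = pcnm(np.array([[0.0], [1.0]]))
        assert ev == pytest.approx([0.5])
        v = table["PCNM1"].to_numpy()
        assert v == pytest.approx([1 / np.sqrt(2), -1 / np.sqrt(2)])

    def test_transect_matches_vegan_oracle(self):
        """Frozen oracle: R vegan::pcnm on a 10-point unit transect."""
        table, ev = pcnm(np.arange(10.0)[:, None])
        vegan_values = [20.6188, 18.2413, 14.2312, 10.4220, 5.8653, 1.9156]
        assert ev == pytest.approx(vegan_values, abs=1e-3)
        vegan_pcnm1 = np.array([0.231, 0.388, 0.422, 0.322, 0.120,
                                -0.120, -0.322, -0.422, -0.388, -0.231])
        got = table["PCNM1"].to_numpy()
        if got[0] < 0:
            got = -got
        assert got == pytest.approx(vegan_pcnm1, abs=1e-3)

    def test_eigenvector_count_bounded(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(15, 2))
        table, _ = pcnm(pts)
        assert table.shape[1] <= 14

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            pcnm(np.zeros((4, 2)))


class TestRdaAdjR2:
    def test_perfect_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        Y = X @ rng.normal(size=(2, 3))
        r2, adj = rda_adj_r2(Y, X)
        assert r2 == pytest.approx(1.0)
        assert adj == pytest.approx(1.0)

    def test_ezekiel_arithmetic(self):
        # engineered R2 = 0.5 at n = 10, p = 2 -> adj = 1 - 0.5*9/7
        rng = np.random.default_rng(1)
        n, p = 10, 2
        X = rng.normal(size=(n, p))
        Xc = X - X.mean(0)
        Q, _ = np.linalg.qr(Xc)
        inside = Q[:, 0]
        resid = rng.normal(size=n)
        resid -= resid.mean()
        resid -= Q @ (Q.T @ resid)
        y = inside + resid * np.linalg.norm(inside) / np.linalg.norm(resid)
        r2, adj = rda_adj_r2(y, X)
        assert r2 == pytest.approx(0.5, abs=1e-10)
        assert adj == pytest.approx(1 - 0.5 * 9 / 7, abs=1e-10)

    def test_orthogonal_gives_negative_adjustment(self):
        n = 10
        y = np.zeros(n)
        y[:5] = 1.0
        y = y - y.mean()
        rng = np.random.default_rng(2)
        X = rng.normal(size=(n, 2))
        Xc = X - X.mean(0)
        # orthogonalise X against y
        Xc -= np.outer(y, y @ Xc) / (y @ y)
        r2, adj = rda_adj_r2(y, Xc)
        assert r2 == pytest.approx(0.0, abs=1e-10)
        assert adj == pytest.approx(1 - 9 / 7, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="aliased"):
            rda_adj_r2(rng.normal(size=(30, 2)), X)


class TestVariancePartition:
    def test_inclusion_exclusion_identity(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(100, 4))
        X1, X2, X3 = (rng.normal(size=(100, 3)) for _ in range(3))
        for Xs in [(X1, X2), (X1, X2, X3)]:
            vp = variance_partition(Y, *Xs)
            assert sum(vp.components.values()) == pytest.approx(vp.total_adj_r2, abs=1e-10)

    def test_duplicated_matrix_all_shared(self):
        rng = np.random.default_rng(1)
        X1 = rng.normal(size=(80, 3))
        Y = X1 @ rng.normal(size=(3, 2)) + rng.normal(0, 1.0, size=(80, 2))
        vp = variance_partition(Y, X1, X1.copy(), names=("A", "B"))
        assert vp.components[frozenset({"A"})] == pytest.approx(0.0, abs=1e-10)
        assert vp.components[frozenset({"B"})] == pytest.approx(0.0, abs=1e-10)
        assert vp.components[frozenset({"A", "B"})] == pytest.approx(
            vp.adj_r2[frozenset({"A"})], abs=1e-10
        )

    def test_orthogonal_matrices_share_nothing(self):
        rng = np.random.default_rng(2)
        n = 200
        X1 = rng.normal(size=(n, 2))
        X2 = rng.normal(size=(n, 2))
        Y = X1 @ np.array([[1.0], [0.5]]) + X2 @ np.array([[0.0], [0.8]]) \
            + rng.normal(0, 0.5, size=(n, 1))
        vp = variance_partition(Y, X1, X2)
        shared = vp.components[frozenset(vp.names)]
        assert abs(shared) < 0.02

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(60, 3))
        X1 = rng.normal(size=(60, 2))
        X2 = rng.normal(size=(60, 2))
        a = variance_partition(Y, X1, X2, names=("P", "Q"))
        b = variance_partition(Y, X2, X1, names=("Q", "P"))
        for key in a.components:
            assert a.components[key] == pytest.approx(b.components[key], abs=1e-12)

    def test_truncated_view_nonnegative(self):
        rng = np.random.default_rng(4)
        vp = variance_partition(rng.normal(size=(50, 2)),
                                rng.normal(size=(50, 2)), rng.normal(size=(50, 2)))
        assert (vp.fractions["truncated"] >= 0).all()


class TestHierarchicalPartition:
    def test_single_predictor_is_adj_r2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 1))
        Y = x @ np.array([[1.0, 0.5]]) + rng.normal(0, 0.5, size=(40, 2))
        hp = hierarchical_partition(Y, pd.DataFrame(x, columns=["x"]))
        _, adj = rda_adj_r2(Y, x)
        assert hp["x"] == pytest.approx(adj, abs=1e-12)

    def test_contributions_sum_to_full_model(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        Y = rng.normal(size=(60, 3))
        hp = hierarchical_partition(Y, X)
        _, adj_full = rda_adj_r2(Y, X)
        assert hp.sum() == pytest.approx(adj_full, abs=1e-8)

    def test_orthogonal_predictors_get_unique_shares(self):
        rng = np.random.default_rng(2)
        n = 300
        A = rng.normal(size=(n, 1))
        B = rng.normal(size=(n, 1))
        B -= A @ np.linalg.lstsq(A, B, rcond=None)[0]  # exactly orthogonal
        Y = A + 0.5 * B + rng.normal(0, 0.3, size=(n, 1))
        hp = hierarchical_partition(Y, {"A": A, "B": B})
        _, adj_a = rda_adj_r2(Y, A)
        _, adj_b = rda_adj_r2(Y, B)
        # equals the unique adjusted R2 up to the small adjustment nonlinearity
        assert hp["A"] == pytest.approx(adj_a, abs=0.01)
        assert hp["B"] == pytest.approx(adj_b, abs=0.01)

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        with pytest.raises(ValueError, match="group"):
            hierarchical_partition(rng.normal(size=(30, 1)), X, max_p=5)
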