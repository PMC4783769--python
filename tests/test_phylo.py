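import numpy as np
import pandas as pd
import pytest

import anchorgm as agm
from anchorgm.phylo import phylogenetic_weighted_mean


def star_tree(labels, length=1.0):
    return agm.Phylogeny.from_newick(
        "(" + ",".join(f"{t}:{length}" for t in labels) + ");"
    )


class TestPhylogeny:
    def test_two_tip_covariance(self):
        p = agm.Phylogeny.from_newick("(A:1,B:1);")
        np.testing.assert_allclose(p.C, np.eye(2))

    def test_nested_covariance_path_sums(self):
        p = agm.Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        C = pd.DataFrame(p.C, index=p.tip_labels, columns=p.tip_labels)
        assert C.loc["A", "A"] == C.loc["B", "B"] == 2
        assert C.loc["A", "B"] == 1
        assert C.loc["A", "C"] == 0

    def test_missing_branch_lengths_rejected_unless_assumed(self):
        with pytest.raises(ValueError):
            agm.Phylogeny.from_newick("(A,B);")
        p = agm.Phylogeny.from_newick("(A,B);", assume_unit_lengths=True)
        np.testing.assert_allclose(p.C, np.eye(2))

    def test_covariance_positive_definite(self, tree13):
        w = np.linalg.eigvalsh(tree13.C)
        assert w.min() > 0
        assert np.allclose(np.diag(tree13.C), 1.0)  # unit-depth ultrametric


class TestAncestralStates:
    def test_symmetric_two_tip_root_is_midpoint(self):
        p = agm.Phylogeny.from_newick("(A:1,B:1);")
        anc = agm.bm_ancestral_states(p, pd.DataFrame({"t": [0.0, 2.0]}, index=["A", "B"]))
        assert anc.loc["root", "t"] == pytest.approx(1.0)

    def test_star_tree_root_is_arithmetic_mean(self, rng):
        labels = list("ABCDE")
        p = star_tree(labels)
        vals = rng.normal(size=5)
        anc = agm.bm_ancestral_states(p, pd.DataFrame({"t": vals}, index=labels))
        assert anc.loc["root", "t"] == pytest.approx(vals.mean())

    def test_unequal_branches_match_gls_oracle(self):
        p = agm.Phylogeny.from_newick("(A:1,B:3);")
        anc = agm.bm_ancestral_states(p, pd.DataFrame({"t": [0.0, 2.0]}, index=["A", "B"]))
        # closed form (1' C^-1 y)/(1' C^-1 1) with C = diag(1, 3)
        assert anc.loc["root", "t"] == pytest.approx(0.5)

    def test_root_matches_weighted_mean_any_tree(self, tree13, rng):
        Y = agm.simulate_bm_tips(tree13, 3, rng=rng)
        anc = agm.bm_ancestral_states(tree13, Y)
        np.testing.assert_allclose(
            anc.loc["root"].to_numpy(),
            phylogenetic_weighted_mean(tree13.C, Y.to_numpy()),
            atol=1e-9,
        )

    def test_root_invariant_to_tip_reordering(self, tree13, rng):
        Y = agm.simulate_bm_tips(tree13, 2, rng=rng)
        shuffled = Y.sample(frac=1.0, random_state=1)
        a = agm.bm_ancestral_states(tree13, Y)
        b = agm.bm_ancestral_states(tree13, shuffled)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_unmatched_names_listed(self, tree13):
        traits = pd.DataFrame({"t": [1.0]}, index=["nosuch"])
        with pytest.raises(ValueError, match="nosuch"):
            agm.bm_ancestral_states(tree13, traits)


class TestKmult:
    def test_scale_invariance(self, tree13, rng):
        Y = agm.simulate_bm_tips(tree13, 5, rng=rng).to_numpy()
        k1 = agm.kmult_statistic(tree13.C, Y)
        k2 = agm.kmult_statistic(tree13.C, 1000.0 * Y)
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_mean_near_one_under_brownian_motion(self, tree13, rng):
        ks = [
            agm.kmult_statistic(tree13.C, agm.simulate_bm_tips(tree13, 44, rng=rng).to_numpy())
            for _ in range(60)
        ]
        assert np.mean(ks) == pytest.approx(1.0, abs=0.1)

    def test_permutation_p_valid_and_reproducible(self, tree13, rng):
        Y = agm.simulate_bm_tips(tree13, 6, rng=rng)
        r1 = agm.kmult_test(tree13, Y, iterations=199, seed=5)
        r2 = agm.kmult_test(tree13, Y, iterations=199, seed=5)
        assert 0 < r1.p <= 1
        assert r1.p == r2.p and r1.K == pytest.approx(r2.K)

    def test_signal_detected_for_bm_traits(self, tree13, rng):
        Y = agm.simulate_bm_tips(tree13, 44, rng=np.random.default_rng(17))
        res = agm.kmult_test(tree13, Y, iterations=499, seed=2)
        assert res.p < 0.05  # strong multivariate BM signal on 13 tips

    def test_zero_variance_rejected(self, tree13):
        Y = pd.DataFrame(np.ones((13, 2)), index=tree13.tip_labels)
        with pytest.raises(ValueError):
            agm.kmult_statistic(tree13.C, Y.to_numpy())


class TestPglsScalar:
    def test_star_tree_equals_ols(self, rng):
        labels = [f"t{i}" for i in range(12)]
        p = star_tree(labels)
        X = pd.DataFrame({"x": rng.normal(size=12)}, index=labels)
        y = pd.Series(rng.normal(size=12), index=labels)
        res = agm.pgls_scalar(p, y, X)
        Xm = np.column_stack([np.ones(12), X["x"]])
        beta = np.linalg.lstsq(Xm, y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.params["coef"], beta, atol=1e-10)

    def test_exact_fit_when_response_equals_covariate(self, tree13, rng):
        x = agm.simulate_bm_tips(tree13, 1, rng=rng).iloc[:, 0]
        res = agm.pgls_scalar(tree13, x, x.to_frame("x"))
        assert res.params.loc["x", "coef"] == pytest.approx(1.0)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-9)

    def test_matches_transformed_ols_oracle(self, tree13, rng):
        X = pd.DataFrame(
            {"a": rng.normal(size=13), "b": rng.normal(size=13)}, index=tree13.tip_labels
        )
        y = pd.Series(rng.normal(size=13), index=tree13.tip_labels)
        res = agm.pgls_scalar(tree13, y, X)
        # oracle: OLS on C^(-1/2)-transformed data
        w, U = np.linalg.eigh(tree13.C)
        P = U @ np.diag(w**-0.5) @ U.T
        Xm = P @ np.column_stack([np.ones(13), X.to_numpy()])
        beta = np.linalg.lstsq(Xm, P @ y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.params["coef"], beta, atol=1e-8)

    def test_slope_recovery_under_bm(self, tree13):
        # parameter recovery: mean estimated slope within 2 MC SEs of truth
        rng = np.random.default_rng(33)
        slopes = []
        for _ in range(50):
            x = agm.simulate_bm_tips(tree13, 1, rng=rng).iloc[:, 0]
            noise = agm.simulate_bm_tips(tree13, 1, rng=rng).iloc[:, 0]
            y = 2.0 * x + 0.5 * noise
            res = agm.pgls_scalar(tree13, y, x.to_frame("x"))
            slopes.append(res.params.loc["x", "coef"])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 2.0) < 2 * se + 1e-9

    def test_singular_design_rejected(self, tree13, rng):
        x = rng.normal(size=13)
        X = pd.DataFrame({"a": x, "b": 2 * x}, index=tree13.tip_labels)
        y = pd.Series(rng.normal(size=13), index=tree13.tip_labels)
        with pytest.raises(np.linalg.LinAlgError):
            agm.pgls_scalar(tree13, y, X)


class TestShapeRrpp:
    def test_star_tree_matches_untransformed_oracle(self, rng):
        labels = [f"t{i}" for i in range(10)]
        p = star_tree(labels)
        Y = pd.DataFrame(rng.normal(size=(10, 5)), index=labels)
        X = pd.DataFrame({"x": rng.normal(size=10)}, index=labels)
        tab = agm.pgls_shape_rrpp(p, Y, X, iterations=100, seed=1)
        # oracle: sequential SS from raw OLS fits
        ones = np.ones((10, 1))
        D1 = np.column_stack([ones, X["x"]])
        Yc = Y.to_numpy()
        rss0 = np.sum((Yc - ones @ np.linalg.lstsq(ones, Yc, rcond=None)[0]) ** 2)
        rss1 = np.sum((Yc - D1 @ np.linalg.lstsq(D1, Yc, rcond=None)[0]) ** 2)
        assert tab.loc[0, "SS"] == pytest.approx(rss0 - rss1, rel=1e-8)

    def test_exact_linear_response_gets_minimal_p(self, tree13, rng):
        x = agm.simulate_bm_tips(tree13, 1, rng=rng)
        Y = pd.DataFrame(
            np.outer(x.iloc[:, 0], rng.normal(size=4)), index=tree13.tip_labels
        )
        tab = agm.pgls_shape_rrpp(tree13, Y, x.rename(columns={"trait0": "x"}), iterations=199, seed=3)
        assert tab.loc[0, "p"] == pytest.approx(1 / 199)

    def test_type_one_error_calibrated(self, tree13):
        rng = np.random.default_rng(55)
        rej = 0
        sims = 150
        for _ in range(sims):
            Y = agm.simulate_bm_tips(tree13, 6, rng=rng)
            X = pd.DataFrame(
                {"x": agm.simulate_bm_tips(tree13, 1, rng=rng).iloc[:, 0]},
                index=tree13.tip_labels,
            )
            tab = agm.pgls_shape_rrpp(
                tree13, Y, X, iterations=100, seed=int(rng.integers(2**31))
            )
            rej += tab.loc[0, "p"] <= 0.05
        assert 0.01 <= rej / sims <= 0.11  # ~0.05 within Monte-Carlo slack

    def test_interaction_term_present(self, tree13, rng):
        Y = agm.simulate_bm_tips(tree13, 4, rng=rng)
        X = pd.DataFrame(
            {"body": rng.normal(size=13), "anchor": rng.normal(size=13)},
            index=tree13.tip_labels,
        )
        tab = agm.pgls_shape_rrpp(tree13, Y, X, interaction=True, iterations=100, seed=1)
        assert "body:anchor" in tab["term"].tolist()

    def test_low_iterations_warn(self, tree13, rng, caplog):
        import logging

        Y = agm.simulate_bm_tips(tree13, 3, rng=rng)
        X = pd.DataFrame({"x": rng.normal(size=13)}, index=tree13.tip_labels)
        with caplog.at_level(logging.WARNING):
            agm.pgls_shape_rrpp(tree13, Y, X, iterations=50, seed=1)
        assert "unreliable" in caplog.text


class TestPhyloPls:
    def test_identical_blocks_give_unit_correlation(self, tree13, rng):
        A = agm.simulate_bm_tips(tree13, 5, rng=rng)
        res = agm.phylo_pls(tree13, A, A.copy(), iterations=50, seed=1)
        assert res.r_pls == pytest.approx(1.0)

    def test_star_tree_matches_ordinary_pls_oracle(self, rng):
        labels = [f"t{i}" for i in range(12)]
        p = star_tree(labels)
        A = pd.DataFrame(rng.normal(size=(12, 4)), index=labels)
        B = pd.DataFrame(rng.normal(size=(12, 3)), index=labels)
        res = agm.phylo_pls(p, A, B, iterations=50, seed=1)
        # oracle: direct SVD of the ordinary cross-covariance
        Ac = A.to_numpy() - A.to_numpy().mean(0)
        Bc = B.to_numpy() - B.to_numpy().mean(0)
        U, s, Vt = np.linalg.svd(Ac.T @ Bc / 11)
        r = np.corrcoef(Ac @ U[:, 0], Bc @ Vt[0])[0, 1]
        assert abs(res.r_pls) == pytest.approx(abs(r), abs=1e-9)

    def test_type_one_error_calibrated(self, tree13):
        rng = np.random.default_rng(77)
        rej = 0
        sims = 150
        for _ in range(sims):
            A = agm.simulate_bm_tips(tree13, 4, rng=rng)
            B = agm.simulate_bm_tips(tree13, 4, rng=rng)
            res = agm.phylo_pls(tree13, A, B, iterations=100, seed=int(rng.integers(2**31)))
            rej += res.p <= 0.05
        assert 0.01 <= rej / sims <= 0.11

    def test_zero_variance_block_rejected(self, tree13, rng):
        A = agm.simulate_bm_tips(tree13, 3, rng=rng)
        B = pd.DataFrame(np.ones((13, 2)), index=tree13.tip_labels)
        with pytest.raises(ValueError):
            agm.phylo_pls(tree13, A, B, iterations=10, seed=1)


class TestPhylomorphospace:
    def test_two_tip_internal_row_at_midpoint(self):
        p = agm.Phylogeny.from_newick("(A:1,B:1);")
        traits = pd.DataFrame({"pc1": [0.0, 2.0]}, index=["A", "B"])
        table, edges = agm.phylomorphospace_table(p, traits)
        assert table.loc["root", "pc1"] == pytest.approx(1.0)
        assert len(edges) == 2

    def test_row_count_for_bifurcating_tree(self, tree13, rng):
        traits = agm.simulate_bm_tips(tree13, 2, rng=rng)
        table, edges = agm.phylomorphospace_table(tree13, traits)
        assert table.shape[0] == 13 + 12  # N tips + N-1 internal nodes
        assert len(edges) == table.shape[0] - 1

    def test_star_tree_single_internal_row(self, rng):
        labels = list("ABCD")
        p = star_tree(labels)
        traits = pd.DataFrame({"t": rng.normal(size=4)}, index=labels)
        table, _ = agm.phylomorphospace_table(p, traits)
        internal = table[~table["is_tip"]]
        assert internal.shape[0] == 1
        assert internal.iloc[0]["t"] == pytest.approx(traits["t"].mean())
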