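"""Independent contrasts, Pagel's lambda, Blomberg's K, sister pairs."""

import json
import subprocess

import numpy as np
import pytest
from scipy import stats as sps

from bacrate import phylo, simulate


class TestPIC:
    def test_two_tip_hand_value(self, two_tip_tree):
        cs = phylo.pic(two_tip_tree, {"A": 3.0, "B": 1.0})
        assert len(cs) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(2 / np.sqrt(2), abs=1e-9)
        assert cs.expected_sd[0] == pytest.approx(np.sqrt(2))

    def test_constant_trait_gives_zero_contrasts(self, balanced_four_tip_tree):
        cs = phylo.pic(balanced_four_tip_tree, dict.fromkeys("ABCD", 5.0))
        np.testing.assert_array_equal(cs.contrasts, 0.0)

    def test_contrast_count_is_tips_minus_one(self, yule_tree_100):
        trait = simulate.simulate_traits(yule_tree_100, ["x"], seed=0)["x"]
        assert len(phylo.pic(yule_tree_100, trait)) == 99

    def test_missing_tip_value_raises(self, two_tip_tree):
        with pytest.raises(ValueError, match="missing"):
            phylo.pic(two_tip_tree, {"A": 1.0})

    def test_zero_length_siblings(self):
        import dendropy

        tree = dendropy.Tree.get(data="((A:0,B:0):1,C:2);", schema="newick")
        cs = phylo.pic(tree, {"A": 1.0, "B": 1.0, "C": 3.0})
        assert cs.contrasts[0] == 0.0
        with pytest.raises(ZeroDivisionError):
            phylo.pic(tree, {"A": 1.0, "B": 2.0, "C": 3.0})

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_through_origin_slope_equals_gls_slope(self, seed):
        """Contrast regression is the GLS slope under BM covariance."""
        rng = np.random.default_rng(seed)
        tree = simulate.simulate_tree(6, seed=seed + 100)
        C, labels = phylo.vcv_matrix(tree)
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        cx = phylo.pic(tree, dict(zip(labels, x)))
        cy = phylo.pic(tree, dict(zip(labels, y)))
        slope_pic = (cx.contrasts @ cy.contrasts) / (cx.contrasts @ cx.contrasts)
        Ci = np.linalg.inv(C)
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert slope_pic == pytest.approx(beta[1], abs=1e-8)

    def test_contrasts_are_standard_normal_under_bm(self):
        """Pooled standardized contrasts from BM simulations pass Shapiro-Wilk."""
        pooled = []
        for rep in range(20):
            tree = simulate.simulate_tree(51, seed=rep)
            trait = simulate.simulate_traits(tree, ["x"], lam=1.0, seed=1000 + rep)["x"]
            pooled.extend(phylo.pic(tree, trait).contrasts)
        pooled = np.asarray(pooled)[:1000]
        assert sps.shapiro(pooled).pvalue > 0.01


class TestLowVarianceFilter:
    def test_threshold_extremes(self):
        cs = phylo.ContrastSet(
            contrasts=np.arange(9.0),
            expected_sd=np.linspace(0.05, 1.0, 9),
            node_ids=[f"n{i}" for i in range(9)],
        )
        same, removed = phylo.filter_low_variance_contrasts(cs, threshold=0.0)
        assert removed == 0 and len(same) == 9
        none, removed = phylo.filter_low_variance_contrasts(cs, threshold=np.inf)
        assert removed == 9 and len(none) == 0

    def test_default_threshold_rule(self):
        sds = np.array([0.1, 0.15, 0.2, 0.25, 0.3, 0.5, 0.7, 0.9, 1.1])
        cs = phylo.ContrastSet(
            contrasts=np.ones(9), expected_sd=sds, node_ids=list("abcdefghi")
        )
        kept, removed = phylo.filter_low_variance_contrasts(cs)  # threshold 0.21
        assert removed == 3
        assert len(kept) == 6


class TestSignal:
    def test_lambda_bounds_and_recovery(self, yule_tree_100):
        trait = simulate.simulate_traits(yule_tree_100, ["x"], lam=1.0, seed=7)["x"]
        lam, loglik, p = phylo.pagel_lambda(yule_tree_100, trait)
        assert 0.0 <= lam <= 1.0
        assert lam > 0.8
        assert p < 0.01

    def test_lambda_near_zero_for_shuffled_trait(self, yule_tree_100):
        trait = simulate.simulate_traits(yule_tree_100, ["x"], lam=1.0, seed=8)["x"]
        rng = np.random.default_rng(0)
        shuffled = dict(zip(trait.index, rng.permutation(trait.to_numpy())))
        lam, _, _ = phylo.pagel_lambda(yule_tree_100, shuffled)
        assert lam < 0.2

    def test_blomberg_k_near_one_under_bm(self, yule_tree_100):
        # K is right-skewed under BM; the mean calibrates to ~1
        labels = phylo.tip_labels(yule_tree_100)
        C, order = phylo.vcv_matrix(yule_tree_100)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(order)))
        rng = np.random.default_rng(200)
        ks = []
        for _ in range(40):
            x = L @ rng.standard_normal(len(order))
            K, _ = phylo.blomberg_k(yule_tree_100, dict(zip(order, x)), n_perm=0)
            ks.append(K)
        assert 0.75 < np.mean(ks) < 1.25

    def test_blomberg_k_small_for_white_noise(self, yule_tree_100):
        rng = np.random.default_rng(4)
        labels = phylo.tip_labels(yule_tree_100)
        K, p = phylo.blomberg_k(
            yule_tree_100, dict(zip(labels, rng.standard_normal(100))),
            n_perm=199, seed=0,
        )
        assert K < 0.5
        assert p > 0.05

    def test_k_permutation_detects_signal(self, yule_tree_100):
        trait = simulate.simulate_traits(yule_tree_100, ["x"], lam=1.0, seed=9)["x"]
        _, p = phylo.blomberg_k(yule_tree_100, trait, n_perm=199, seed=0)
        assert p < 0.05

    def test_affine_invariance(self, yule_tree_100):
        trait = simulate.simulate_traits(yule_tree_100, ["x"], lam=1.0, seed=10)["x"]
        lam1, _, _ = phylo.pagel_lambda(yule_tree_100, trait)
        lam2, _, _ = phylo.pagel_lambda(yule_tree_100, trait * 3.0 - 7.0)
        K1, _ = phylo.blomberg_k(yule_tree_100, trait, n_perm=0)
        K2, _ = phylo.blomberg_k(yule_tree_100, trait * 3.0 - 7.0, n_perm=0)
        assert lam1 == pytest.approx(lam2, abs=1e-4)
        assert K1 == pytest.approx(K2, rel=1e-10)

    def test_no_permutations_returns_undefined_p(self, yule_tree_100):
        trait = simulate.simulate_traits(yule_tree_100, ["x"], seed=11)["x"]
        K, p = phylo.blomberg_k(yule_tree_100, trait, n_perm=0)
        assert p is None and K > 0


class TestSisterPairs:
    def test_two_mixed_cherries(self, balanced_four_tip_tree):
        labels = {"A": "ob", "B": "op", "C": "op", "D": "ob"}
        pairs = phylo.sister_pairs(balanced_four_tip_tree, labels)
        assert len(pairs) == 2
        used = [t for p in pairs for t in p]
        assert len(used) == len(set(used))  # disjoint

    def test_no_mixed_cherries_warns(self, balanced_four_tip_tree):
        labels = dict.fromkeys("ABCD", "same")
        with pytest.warns(UserWarning, match="no mixed-label"):
            assert phylo.sister_pairs(balanced_four_tip_tree, labels) == []


class TestAgainstRReference:
    """Cross-check contrasts and signal statistics against ape/phytools."""

    def test_pic_lambda_and_k_match_r(self, tmp_path):
        tree = simulate.simulate_tree(12, seed=21)
        trait = simulate.simulate_traits(tree, ["x"], lam=1.0, seed=22)["x"]
        tree_path = tmp_path / "tree.nwk"
        tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
        csv_path = tmp_path / "trait.csv"
        trait.rename("x").rename_axis("species").reset_index().to_csv(
            csv_path, index=False
        )
        script = f"""
        suppressMessages({{library(ape); library(phytools)}})
        tr <- read.tree("{tree_path}")
        d <- read.csv("{csv_path}")
        x <- setNames(d$x, d$species)
        contrasts <- pic(x, tr)
        lam <- phylosig(tr, x, method="lambda", test=FALSE)
        K <- phylosig(tr, x, method="K", test=FALSE)
        cat(sprintf('{{"pic": [%s], "lambda": %.10f, "K": %.10f}}',
            paste(sprintf("%.12f", sort(abs(contrasts))), collapse=","),
            lam$lambda, as.numeric(K)))
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        cs = phylo.pic(tree, trait)
        np.testing.assert_allclose(
            np.sort(np.abs(cs.contrasts)), np.array(ref["pic"]), atol=1e-8
        )
        K, _ = phylo.blomberg_k(tree, trait, n_perm=0)
        assert K == pytest.approx(ref["K"], abs=1e-6)
        lam, _, _ = phylo.pagel_lambda(tree, trait)
        # phytools allows lambda above 1; compare after clipping to our box
        assert lam == pytest.approx(min(ref["lambda"], 1.0), abs=5e-3)
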