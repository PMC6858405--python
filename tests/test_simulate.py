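"""Synthetic-data generators and the engineered reference benchmark."""

import numpy as np
import pytest

from bacrate import comparative_stats as cstats
from bacrate import curation, diversity, phylo, simulate


class TestTree:
    def test_tip_count_and_cherry(self):
        tree = simulate.simulate_tree(2, seed=0)
        assert len(phylo.tip_labels(tree)) == 2

    def test_reproducible_by_seed(self):
        a = simulate.simulate_tree(10, seed=5).as_string(schema="newick")
        b = simulate.simulate_tree(10, seed=5).as_string(schema="newick")
        assert a == b

    def test_ultrametric(self):
        tree = simulate.simulate_tree(30, seed=1)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9

    def test_depth_grows_logarithmically(self):
        """Yule expectation: tree height ~ sum_{k=2..n} 1/(k b) ~ log(n)/b."""
        def mean_depth(n, reps):
            out = []
            for rep in range(reps):
                t = simulate.simulate_tree(n, birth_rate=1.0, seed=1000 + rep)
                out.append(next(t.leaf_node_iter()).distance_from_root())
            return np.mean(out)

        d4 = mean_depth(4, 100)
        d32 = mean_depth(32, 100)
        expect4 = sum(1.0 / k for k in range(2, 5)) + 1.0 / 4
        expect32 = sum(1.0 / k for k in range(2, 33)) + 1.0 / 32
        assert d4 == pytest.approx(expect4, rel=0.25)
        assert d32 == pytest.approx(expect32, rel=0.25)
        assert d32 > d4


class TestTraits:
    def test_target_correlation_recovered(self):
        tree = simulate.simulate_tree(200, seed=2)
        corr = np.array([[1.0, 0.7], [0.7, 1.0]])
        df = simulate.simulate_traits(tree, ["u", "v"], correlation=corr, seed=3)
        r = cstats.pearson(df["u"], df["v"]).r
        assert r == pytest.approx(0.7, abs=0.15)

    def test_lambda_zero_destroys_signal(self):
        tree = simulate.simulate_tree(80, seed=4)
        df = simulate.simulate_traits(tree, ["x"], lam=0.0, seed=5)
        lam, _, _ = phylo.pagel_lambda(tree, df["x"])
        assert lam < 0.3

    def test_non_psd_matrix_rejected(self):
        tree = simulate.simulate_tree(5, seed=6)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate.simulate_traits(tree, ["u", "v"], correlation=bad, seed=0)


class TestRateEstimates:
    @staticmethod
    def species_frame(n=10):
        import pandas as pd

        return pd.DataFrame(
            {"species": [f"sp{i}" for i in range(n)], "log_rate": np.linspace(-7, -5, n)}
        )

    def test_zero_noise_zero_slope_reproduces_species_rates(self):
        df = simulate.simulate_rate_estimates(
            self.species_frame(), estimates_per_species=(3, 3),
            rate_noise_sd=0.0, time_effect_slope=0.0, seed=0,
        )
        by = df.groupby("species")["rate"].nunique()
        assert (by == 1).all()

    def test_single_estimate_averaging_is_identity(self):
        df = simulate.simulate_rate_estimates(
            self.species_frame(), estimates_per_species=(1, 1),
            rate_noise_sd=0.0, seed=1,
        )
        means = curation.average_by_species(df)
        np.testing.assert_allclose(
            np.sort(means["mean_rate"]), np.sort(df["rate"]), rtol=1e-12
        )

    def test_injected_time_slope_recovered_by_ancova(self):
        slopes = []
        for rep in range(25):
            df = simulate.simulate_rate_estimates(
                self.species_frame(12), estimates_per_species=(4, 6),
                rate_noise_sd=0.15, time_effect_slope=-0.5, seed=rep,
            )
            groups = {
                sp: (
                    np.log10(sub["sampling_time"].to_numpy()),
                    np.log10(sub["rate"].to_numpy()),
                )
                for sp, sub in df.groupby("species")
            }
            slopes.append(cstats.ancova_common_slope(groups).common_slope)
        assert np.mean(slopes) == pytest.approx(-0.5, abs=0.1)

    def test_flag_injection(self):
        df = simulate.simulate_rate_estimates(
            self.species_frame(40), estimates_per_species=(3, 3),
            hypermutator_fraction=0.3, synonymous_fraction=0.3, seed=2,
        )
        assert df["hypermutator"].any()
        assert (df["site_class"] == "synonymous").any()
        kept, audit = curation.filter_estimates(df)
        assert len(kept) + len(audit) == len(df)


class TestCodonAlignment:
    def test_omega_zero_means_no_nonsynonymous_diversity(self):
        aln = simulate.simulate_codon_alignment(4, 300, theta_syn=0.1, omega=0.0, seed=0)
        res = diversity.pi_n_pi_s(aln)
        assert res.pi_n == 0.0
        assert res.pi_s > 0.0

    def test_theta_zero_means_identical_sequences(self):
        aln = simulate.simulate_codon_alignment(3, 50, theta_syn=0.0, omega=1.0, seed=1)
        assert len(set(aln.sequences)) == 1

    def test_neutral_ratio_near_one(self):
        aln = simulate.simulate_codon_alignment(
            6, 5000, theta_syn=0.02, omega=1.0, seed=2
        )
        res = diversity.pi_n_pi_s(aln)
        assert res.ratio == pytest.approx(1.0, abs=0.2)

    def test_purifying_selection_lowers_ratio(self):
        aln = simulate.simulate_codon_alignment(
            6, 4000, theta_syn=0.02, omega=0.2, seed=3
        )
        res = diversity.pi_n_pi_s(aln)
        assert res.ratio == pytest.approx(0.2, abs=0.1)


class TestReferenceDataset:
    def test_imposed_statistics_hold_exactly(self, reference_data):
        ds = reference_data
        kept, audit = curation.filter_estimates(ds["estimates"])
        means = curation.average_by_species(kept)
        merged = means.merge(ds["traits"], on="species")
        no_out = merged[merged["species"] != simulate.REFERENCE_OUTLIER]
        stats = ds["statistics"]
        got = {
            "r_rate_vs_time": cstats.pearson(
                np.log10(kept["sampling_time"]), np.log10(kept["rate"])
            ).r,
            "r_rate_vs_genome_all": cstats.pearson(
                merged["genome_size"], merged["log_rate"]
            ).r,
            "r_rate_vs_genome_excl": cstats.pearson(
                no_out["genome_size"], no_out["log_rate"]
            ).r,
            "r_rate_vs_gc_all": cstats.pearson(merged["gc"], merged["log_rate"]).r,
            "r_rate_vs_gc_excl": cstats.pearson(no_out["gc"], no_out["log_rate"]).r,
            "r_pinpis_vs_gc": cstats.pearson(merged["pin_pis"], merged["gc"]).r,
            "r_mutation_vs_genome": cstats.pearson(
                np.log10(ds["mutation_rates"]["mutation_rate"]),
                np.log10(ds["mutation_rates"]["genome_size"]),
            ).r,
        }
        for key, expected in got.items():
            assert expected == pytest.approx(stats[key], abs=1e-8), key

    def test_curation_exercised(self, reference_data):
        kept, audit = curation.filter_estimates(reference_data["estimates"])
        reasons = [a.reason for a in audit]
        assert sum("hypermutator" in r for r in reasons) == 2
        assert sum("synonymous" in r for r in reasons) == 1
        assert sum("sampling_time" in r for r in reasons) == 2
        assert curation.average_by_species(kept)["species"].nunique() == 34

    def test_tree_covers_all_species(self, reference_data):
        tips = set(phylo.tip_labels(reference_data["tree"]))
        assert tips == set(reference_data["traits"]["species"])

    def test_outlier_weakens_correlations(self, reference_data):
        stats = reference_data["statistics"]
        assert abs(stats["r_rate_vs_genome_all"]) < abs(stats["r_rate_vs_genome_excl"])
        assert abs(stats["r_rate_vs_gc_all"]) < abs(stats["r_rate_vs_gc_excl"])


def test_end_to_end_known_correlation_recovered():
    """Injected -0.6 GC correlation survives the full estimate->curation path."""
    tree = simulate.simulate_tree(100, seed=30)
    corr = np.array([[1.0, -0.6], [-0.6, 1.0]])
    # lam=0 keeps tips exchangeable so the r +/- 0.15 band reflects n=100;
    # with full BM signal the effective sample size would be far smaller
    traits = simulate.simulate_traits(
        tree, ["log_rate_dev", "gc_dev"], lam=0.0, correlation=corr, seed=31
    )
    species = traits.index.tolist()
    frame = traits.reset_index(names="species")
    frame["log_rate"] = -6.0 + frame["log_rate_dev"]
    estimates = simulate.simulate_rate_estimates(
        frame[["species", "log_rate"]], estimates_per_species=(1, 3),
        rate_noise_sd=0.1, seed=32,
    )
    kept, _ = curation.filter_estimates(estimates)
    means = curation.average_by_species(kept)
    merged = means.merge(frame[["species", "gc_dev"]], on="species")
    r = cstats.pearson(merged["log_rate"], merged["gc_dev"]).r
    assert r == pytest.approx(-0.6, abs=0.15)
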