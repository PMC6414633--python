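import numpy as np
import pytest

import cecaphylo as cp
from cecaphylo.traits import CECAL_CONSTANT_CM


@pytest.fixture(scope="module")
def tree12():
    return cp.yule_tree(12, depth=10.0, seed=31)


class TestContinuousSimulators:
    def test_zero_rate_returns_root_value(self, tree12):
        vals = cp.simulate_bm(tree12, sigma2=0.0, root_value=3.5, seed=0)
        np.testing.assert_allclose(vals.to_numpy(), 3.5)

    def test_bm_moments_match_tree(self, tree12):
        """Tip variance ~ sigma2 * depth; tip covariance ~ sigma2 * shared
        path length (Monte-Carlo against the closed form)."""
        sigma2, n_rep = 0.7, 1500
        rng = np.random.default_rng(2)
        C = cp.vcv(tree12)
        draws = np.stack([
            cp.simulate_bm(tree12, sigma2=sigma2, rng=rng).to_numpy()
            for _ in range(n_rep)])
        emp = np.cov(draws, rowvar=False)
        # 3-standard-error band for a sample (co)variance of a normal
        se = sigma2 * 10.0 * np.sqrt(2.0 / n_rep) * 3.0
        i, j = 0, 1
        assert abs(emp[i, i] - sigma2 * C.matrix[i, i]) < se
        assert abs(emp[i, j] - sigma2 * C.matrix[i, j]) < se

    def test_lambda_zero_values_uncorrelated(self, tree12):
        rng = np.random.default_rng(3)
        draws = np.stack([
            cp.simulate_with_model(tree12, cp.EvolutionModel.pagel(0.0),
                                   sigma2=1.0, rng=rng).to_numpy()
            for _ in range(800)])
        corr = np.corrcoef(draws, rowvar=False)
        off = corr[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_ou_huge_alpha_uncorrelated(self, tree12):
        rng = np.random.default_rng(4)
        draws = np.stack([
            cp.simulate_with_model(tree12, cp.EvolutionModel.ou(50.0),
                                   sigma2=1.0, rng=rng).to_numpy()
            for _ in range(800)])
        corr = np.corrcoef(draws, rowvar=False)
        assert np.abs(corr[~np.eye(12, dtype=bool)]).max() < 0.15

    def test_lambda_parameter_recovery(self):
        """lambda_ml recovers an intermediate generating lambda."""
        tree = cp.yule_tree(300, depth=10.0, seed=6)
        C = cp.vcv(tree)
        rng = np.random.default_rng(7)
        hats = []
        for _ in range(40):
            y = cp.simulate_with_model(tree, cp.EvolutionModel.pagel(0.5),
                                       sigma2=1.0, rng=rng)
            hats.append(cp.lambda_ml(C, y.to_numpy()).lam_hat)
        assert abs(np.mean(hats) - 0.5) < 0.07


class TestMk:
    def test_zero_rate_is_constant(self, tree12):
        states = cp.simulate_mk(tree12, n_states=4, rate=0.0, seed=1)
        assert states.nunique() == 1
        assert cp.fitch_length(tree12, states.to_dict()) == 0

    def test_same_seed_reproducible(self, tree12):
        a = cp.simulate_mk(tree12, n_states=3, rate=0.1, seed=5)
        b = cp.simulate_mk(tree12, n_states=3, rate=0.1, seed=5)
        assert (a == b).all()

    def test_saturated_rate_matches_shuffle_null(self):
        """At very high rates the character forgets the tree: its parsimony
        length matches the tip-shuffle null mean within 3 se."""
        tree = cp.yule_tree(40, depth=10.0, seed=9)
        rng = np.random.default_rng(10)
        lengths, null_means = [], []
        for _ in range(40):
            states = cp.simulate_mk(tree, n_states=3, rate=50.0, rng=rng)
            lengths.append(cp.fitch_length(tree, states.to_dict()))
            vals = states.to_numpy().copy()
            shuffled_lengths = []
            for _ in range(20):
                rng.shuffle(vals)
                shuffled_lengths.append(cp.fitch_length(
                    tree, dict(zip(states.index, vals))))
            null_means.append(np.mean(shuffled_lengths))
        diff = np.mean(lengths) - np.mean(null_means)
        se = np.std(np.array(lengths) - np.array(null_means), ddof=1) / np.sqrt(40)
        assert abs(diff) < 3 * max(se, 0.2)


class TestStudyLikeDataset:
    def test_noiseless_dataset_recovers_slope_exactly(self):
        cfg = cp.SyntheticConfig(
            n_taxa=40, seed=12, sigma2=1e-12,
            clade_offsets=dict.fromkeys(cp.CLADE_LEVELS, 0.0),
            diet_offsets=dict.fromkeys(cp.DIET_LEVELS, 0.0))
        tree, traits, truth = cp.make_study_like_dataset(cfg)
        keep = traits["cecal_length_cm"] > 0  # clipped rows break linearity
        fit = np.polyfit(traits["log_mass"][keep], traits["log_cecum"][keep], 1)
        assert fit[0] == pytest.approx(truth["true_slope"], abs=1e-6)

    def test_back_transform_round_trip(self, study_dataset):
        _, traits, _ = study_dataset
        raw = traits["cecal_length_cm"]
        np.testing.assert_allclose(
            traits["log_cecum"], np.log10(raw + CECAL_CONSTANT_CM), atol=1e-12)

    def test_clades_are_monophyletic_blocks(self, study_dataset):
        tree, traits, truth = study_dataset
        clade_of = dict(zip(traits["species"], traits["clade"].astype(str)))
        # each clade's tips descend from a single node whose subtree holds
        # exactly those tips
        from collections import defaultdict
        groups = defaultdict(set)
        for sp, cl in clade_of.items():
            groups[cl].add(sp)
        assert len(groups) == 7
        mrca_sizes = {}
        for cl, members in groups.items():
            mrca = tree.mrca(taxon_labels=sorted(members))
            mrca_sizes[cl] = len(mrca.leaf_nodes())
            assert mrca_sizes[cl] == len(members)
        assert sum(mrca_sizes.values()) == truth["n_taxa"]

    def test_reproducible_and_seed_sensitive(self):
        cfg = cp.SyntheticConfig(n_taxa=30, seed=14)
        _, t1, _ = cp.make_study_like_dataset(cfg)
        _, t2, _ = cp.make_study_like_dataset(cfg)
        assert t1.equals(t2)
        _, t3, _ = cp.make_study_like_dataset(
            cp.SyntheticConfig(n_taxa=30, seed=15))
        assert not t1["log_cecum"].equals(t3["log_cecum"])

    def test_written_files_feed_the_pipeline_readers(self, tmp_path,
                                                     study_dataset):
        tree, traits, _ = study_dataset
        cp.write_tree(tree, tmp_path / "t.nwk")
        cp.write_traits(traits, tmp_path / "t.csv")
        back_tree = cp.read_tree(tmp_path / "t.nwk")
        back_traits = cp.load_traits(tmp_path / "t.csv")
        aligned, pruned = cp.align_to_tree(back_traits, back_tree,
                                           policy="strict")
        assert len(aligned) == len(traits)

    def test_model_selection_recovers_generating_structure(self):
        """The ladder prefers a phylogenetically weighted clade+diet model
        over unweighted simple allometry on data generated with the study's
        effect sizes."""
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = cp.SyntheticConfig(n_taxa=120, seed=1000 + rep)
            tree, traits, _ = cp.make_study_like_dataset(cfg)
            # reference the modal diet so the contrast basis always exists
            ref = {"diet": traits["diet"].mode()[0]}
            specs = [cp.DesignSpec(),
                     cp.DesignSpec(factors=("clade", "diet")).with_references(ref)]
            ladder = cp.fit_ladder(traits, tree, specs)
            best = ladder.best
            if (best.spec.factors and best.model_kind in ("brownian", "ou")):
                wins += 1
        assert wins >= 0.95 * n_rep
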