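import numpy as np
import pandas as pd
import pytest

import cecaphylo as cp
from cecaphylo.pgls import DesignSpec, t_test

from oracles import ols_oracle


def cycled_table(n=155):
    """Deterministic trait table with every diet/clade/flight level present."""
    diets = list(cp.DIET_LEVELS)
    clades = list(cp.CLADE_LEVELS)
    flights = list(cp.FLIGHT_LEVELS)
    rows = [(f"sp{i:03d}", 1.0 + (i % 11), 10.0 * (1 + i % 23),
             diets[i % 7], flights[i % 3], clades[(i // 7) % 7])
            for i in range(n)]
    return cp.load_traits(pd.DataFrame(
        rows, columns=["species", "cecal_length_cm", "body_mass_g",
                       "diet", "flight", "clade"]))


class TestDesign:
    def test_diet_plus_clade_dimensionality(self):
        traits = cycled_table(155)
        X, labels = cp.build_design(
            traits, DesignSpec(factors=("diet", "clade")))
        assert X.shape == (155, 14)
        assert len(labels) == 14

    def test_simple_design_two_columns(self):
        X, labels = cp.build_design(cycled_table(20), DesignSpec())
        assert labels == ["(Intercept)", "log_mass"]
        np.testing.assert_allclose(X[:, 0], 1.0)

    def test_interaction_single_three_level_factor(self):
        X, labels = cp.build_design(
            cycled_table(30), DesignSpec(factors=("flight",),
                                         interaction=True))
        assert X.shape[1] == 6  # 1 + 1 + 2 dummies + 2 slope modifiers

    def test_interaction_with_two_factors_rejected(self):
        with pytest.raises(ValueError, match="exactly one factor"):
            DesignSpec(factors=("diet", "clade"), interaction=True)

    def test_absent_reference_level_is_error(self):
        traits = cycled_table(30)  # clade cycle never reaches Inopinaves
        assert "Inopinaves" not in set(traits["clade"].astype(str))
        with pytest.raises(ValueError, match="reference level"):
            cp.build_design(traits, DesignSpec(factors=("clade",)))


class TestGLSFit:
    def random_instance(self, seed, n=40, p=4):
        rng = np.random.default_rng(seed)
        tree = cp.yule_tree(n, depth=10.0, rng=rng)
        C = cp.vcv(tree)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        y = X @ rng.standard_normal(p) + rng.standard_normal(n)
        return y, X, C

    @pytest.mark.parametrize("seed", range(10))
    def test_independent_matches_normal_equations(self, seed):
        y, X, C = self.random_instance(seed)
        fit = cp.gls_fit(y, X, C, cp.EvolutionModel.independent())
        V = np.diag(np.diag(C.matrix))
        beta, sigma2 = ols_oracle(y, X, V)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-10)
        assert fit.sigma2_ml == pytest.approx(sigma2, abs=1e-10)

    def test_brownian_on_star_tree_equals_ols(self):
        n = 12
        star = cp.parse_tree("(" + ",".join(f"t{i}:5" for i in range(n)) + ");")
        C = cp.vcv(star)
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = 2 + 0.5 * X[:, 1] + rng.standard_normal(n)
        bm = cp.gls_fit(y, X, C, cp.EvolutionModel.brownian())
        beta_ols, _ = ols_oracle(y, X)
        np.testing.assert_allclose(bm.beta, beta_ols, atol=1e-12)

    def test_ou_high_alpha_approaches_ols(self):
        y, X, C = self.random_instance(2)
        fit = cp.gls_fit(y, X, C, cp.EvolutionModel.ou(100.0))
        beta_ols, _ = ols_oracle(y, X)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-4)

    def test_rank_deficiency_reported(self):
        y, X, C = self.random_instance(3)
        X = np.column_stack([X, X[:, 1]])  # duplicate column
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            cp.gls_fit(y, X, C, cp.EvolutionModel.brownian())

    def test_ou_alpha_profiling_beats_fixed_alpha(self, study_dataset):
        tree, traits, truth = study_dataset
        C = cp.vcv(tree)
        spec = DesignSpec(factors=("clade", "diet"))
        free = cp.fit_design(traits, C, spec, cp.EvolutionModel("ou"))
        assert free.model.alpha is not None and free.model.alpha > 0
        for alpha in (free.model.alpha * 3, free.model.alpha / 3):
            fixed = cp.fit_design(traits, C, spec, cp.EvolutionModel.ou(alpha))
            assert free.loglik >= fixed.loglik - 1e-6
        assert free.k == fixed.k  # both count alpha as a parameter

    def test_slope_invariant_to_mass_units(self, study_dataset):
        tree, traits, _ = study_dataset
        C = cp.vcv(tree)
        spec = DesignSpec(factors=("clade",))
        fit_g = cp.fit_design(traits, C, spec, cp.EvolutionModel.brownian())
        rescaled = traits.copy()
        rescaled["log_mass"] = traits["log_mass"] - 3.0  # grams -> kilograms
        fit_kg = cp.fit_design(rescaled, C, spec, cp.EvolutionModel.brownian())
        assert fit_kg.coef("log_mass") == pytest.approx(
            fit_g.coef("log_mass"), abs=1e-8)
        assert fit_kg.coef("(Intercept)") != pytest.approx(
            fit_g.coef("(Intercept)"), abs=1e-3)


class TestInference:
    def test_t_statistics_reduce_to_textbook_form(self):
        t, df, p = t_test(0.5, 0.25, 10, 0.5)
        assert (t, p) == (0.0, 1.0)
        t, df, p = t_test(0.5, 0.25, 10, 0.0)
        assert t == pytest.approx(2.0)
        assert p < 0.08

    def test_coef_test_on_fit(self, study_dataset):
        tree, traits, truth = study_dataset
        C = cp.vcv(tree)
        fit = cp.fit_design(traits, C, DesignSpec(factors=("clade", "diet")),
                            cp.EvolutionModel("ou"))
        t, df, p = cp.coef_test(fit, "log_mass", truth["true_slope"])
        assert df == fit.n - len(fit.labels)
        assert p > 0.01  # truth should rarely be rejected

    def test_relevel_preserves_fit_and_flips_contrast(self, study_dataset):
        tree, traits, _ = study_dataset
        C = cp.vcv(tree)
        spec = DesignSpec(factors=("clade", "diet"))
        model = cp.EvolutionModel.ou(0.17)
        base = cp.fit_design(traits, C, spec, model)
        releveled = cp.relevel_fit(
            traits, C, spec,
            {"clade": "Galloanserae", "diet": "herbivore"}, model)
        assert releveled.loglik == pytest.approx(base.loglik, abs=1e-10)
        assert releveled.aic == pytest.approx(base.aic, abs=1e-10)
        np.testing.assert_allclose(releveled.fitted, base.fitted, atol=1e-8)
        assert releveled.coef("diet[carnivore-vertebrates]") == pytest.approx(
            -base.coef("diet[herbivore]"), abs=1e-8)


class TestLadder:
    def test_single_model_is_best_with_zero_delta(self, study_dataset):
        tree, traits, _ = study_dataset
        ladder = cp.fit_ladder(traits, tree, [DesignSpec()],
                               models=("brownian",))
        assert len(ladder.entries) == 1
        assert ladder.entries[0].delta_aic == 0.0
        assert not ladder.entries[0].rejected

    def test_delta_aic_consistency(self, study_dataset):
        tree, traits, _ = study_dataset
        ladder = cp.fit_ladder(traits, tree, cp.study_designs())
        aics = [e.fit.aic for e in ladder.entries if e.fit]
        best = min(aics)
        for e in ladder.entries:
            if e.fit:
                assert e.delta_aic == pytest.approx(e.fit.aic - best)
                assert e.rejected == (e.delta_aic >= 3.0)
        assert sum(e.delta_aic == 0.0 for e in ladder.entries if e.fit) == 1

    def test_nested_designs_aic_tracks_lr_statistic(self, study_dataset):
        """For ML fits under the same V, AIC difference of nested designs
        equals 2*delta_k minus the likelihood-ratio statistic."""
        tree, traits, _ = study_dataset
        C = cp.vcv(tree)
        model = cp.EvolutionModel.brownian()
        small = cp.fit_design(traits, C, DesignSpec(), model)
        big = cp.fit_design(traits, C, DesignSpec(factors=("clade",)), model)
        lr = 2.0 * (big.loglik - small.loglik)
        dk = big.k - small.k
        assert big.aic - small.aic == pytest.approx(2 * dk - lr, abs=1e-9)

    def test_failed_cells_reported_not_fatal(self, study_dataset):
        tree, traits, _ = study_dataset
        # constant covariate makes the design collinear with the intercept
        broken = traits.copy()
        broken["log_mass"] = 1.0
        ladder = cp.fit_ladder(broken, tree, [DesignSpec()],
                               models=("independent", "brownian"))
        assert all(e.fit is None and e.error for e in ladder.entries)
        with pytest.raises(ValueError, match="no model"):
            ladder.best
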