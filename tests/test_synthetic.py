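"""Synthetic-data generator: distributional fidelity, determinism, and
generative/inferential duality with the downstream models."""

import numpy as np
import pytest
from scipy import stats

from phylospan import (
    KernelParams,
    default_truth,
    life_expectancy,
    simulate_census,
    simulate_dataset,
    simulate_traits,
    simulate_tree,
)
from phylospan.sem import MODEL_PREDICTORS


class TestTree:
    def test_minimum_size_tree(self):
        tree = simulate_tree(2, seed=0)
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 2
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 1
        d0, d1 = (l.distance_from_root() for l in leaves)
        assert d0 == pytest.approx(d1)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)

    def test_same_seed_gives_byte_identical_newick(self):
        s1 = simulate_tree(50, seed=1).as_string(schema="newick")
        s2 = simulate_tree(50, seed=1).as_string(schema="newick")
        assert s1 == s2

    def test_different_seeds_differ(self):
        s1 = simulate_tree(50, seed=1).as_string(schema="newick")
        s2 = simulate_tree(50, seed=2).as_string(schema="newick")
        assert s1 != s2

    def test_unit_depth_ultrametric(self):
        tree = simulate_tree(30, seed=9)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert np.allclose(depths, 1.0)


class TestTraits:
    def test_null_model_gives_iid_life_expectancy(self):
        null = {k: 0.0 for k in ("I", "BO", "RB", "LA", "D", "DT", "CS", "AFR")}
        truth = default_truth(
            200, tree_seed=0, sem_coefficients=null,
            kernel_params=KernelParams(eta_sq=0.0, rho=1.0, sigma_ind=0.6),
            missing_fractions={}, size_bias=0.0)
        ds = simulate_traits(simulate_tree(200, seed=0), truth, seed=4)
        fr = ds.traits_true.frame
        z_le = (fr.le_mean - fr.le_mean.mean()) / fr.le_mean.std()
        r = np.corrcoef(z_le, fr.body_mean)[0, 1]
        assert abs(r) < 0.2
        # marginal normality of standardized log LE
        assert stats.shapiro(z_le).pvalue > 0.01

    def test_rb_effect_recovered_by_ols_on_true_values(self):
        import statsmodels.api as sm
        truth = default_truth(
            300, tree_seed=2,
            kernel_params=KernelParams(eta_sq=0.05, rho=3.0, sigma_ind=0.45),
            missing_fractions={}, size_bias=0.0)
        ds = simulate_traits(simulate_tree(300, seed=2), truth, seed=8)
        fr = ds.traits_true.frame

        def z(x):
            return (x - np.mean(x)) / np.std(x, ddof=1)

        body = z(fr.body_mean)
        brain = z(fr.brain_mean)
        co = np.polyfit(body, brain, 1)
        resid = brain - co[1] - co[0] * body
        X = sm.add_constant(np.column_stack([
            fr.insularity, body, z(resid),
            z(np.log(fr.max_latitude_range)), (fr.diet - 1) / 3,
        ]))
        fit = sm.OLS(z(fr.le_mean), X).fit()
        rb_hat, rb_se = fit.params.iloc[3], fit.bse.iloc[3]
        assert rb_hat == pytest.approx(
            truth.sem_coefficients["RB"], abs=3.5 * rb_se)

    def test_missing_fraction_within_binomial_error(self):
        truth = default_truth(400, tree_seed=1,
                              missing_fractions={"le": 0.3}, size_bias=0.0)
        ds = simulate_traits(simulate_tree(400, seed=1), truth, seed=3)
        frac = ds.traits_observed.frame.le_mean.isna().mean()
        se = np.sqrt(0.3 * 0.7 / 400)
        assert abs(frac - 0.3) < 3.5 * se

    def test_size_bias_makes_small_species_more_missing(self):
        truth = default_truth(400, tree_seed=1,
                              missing_fractions={"le": 0.4}, size_bias=2.0)
        ds = simulate_traits(simulate_tree(400, seed=1), truth, seed=3)
        obs = ds.traits_observed.frame
        body = ds.traits_true.frame.body_mean
        missing = obs.le_mean.isna()
        assert body[missing].mean() < body[~missing].mean()

    def test_observed_cells_have_explicit_state_everywhere(self):
        truth = default_truth(50, tree_seed=1)
        ds = simulate_traits(simulate_tree(50, seed=1), truth, seed=2)
        mask = ds.traits_observed.missing_mask()
        assert mask.shape[0] == 50  # every species has a row per variable

    def test_siler_params_match_generated_life_expectancy(self):
        truth = default_truth(20, tree_seed=6, missing_fractions={})
        ds = simulate_traits(simulate_tree(20, seed=6), truth, seed=5)
        fr = ds.traits_true.frame
        for sp in fr.index[:5]:
            e0 = life_expectancy(truth.siler_params_by_species[sp])
            assert e0 == pytest.approx(np.exp(fr.loc[sp, "le_mean"]), rel=1e-6)

    def test_generative_inferential_duality(self):
        """Every SEM coefficient, the allometry and the kernel exist as
        ground-truth fields."""
        truth = default_truth(10)
        for mid in (1, 2, 3):
            for pred in MODEL_PREDICTORS[mid]:
                assert pred in truth.sem_coefficients
        assert truth.allometry.slope and truth.allometry.residual_sd > 0
        assert truth.kernel_params.eta_sq >= 0


class TestCensus:
    def test_constant_hazard_mean_age(self, constant_hazard_params):
        recs = simulate_census(constant_hazard_params, 10_000,
                               study_window=1e6, unknown_birth_fraction=0.0,
                               seed=1)
        ages = np.array([r.end_time - r.birth_time for r in recs])
        assert ages.mean() == pytest.approx(10.0, abs=0.4)

    def test_long_window_leaves_no_censoring(self, ref_params):
        recs = simulate_census(ref_params, 500, study_window=1e6,
                               unknown_birth_fraction=0.0, seed=2)
        assert all(r.died for r in recs)

    def test_ages_at_death_match_closed_form_survival(self, ref_params):
        recs = simulate_census(ref_params, 20_000, study_window=1e6,
                               unknown_birth_fraction=0.0, seed=3)
        ages = np.array([r.end_time - r.birth_time for r in recs])
        from phylospan import siler_survival
        ks = stats.kstest(ages, lambda x: 1 - siler_survival(ref_params, x))
        # critical value at alpha=0.01 for n=20000 is ~1.63/sqrt(n)
        assert ks.statistic < 1.63 / np.sqrt(20_000)

    def test_unknown_birth_records_carry_bound_and_side_channel(self, ref_params):
        recs, tb = simulate_census(
            ref_params, 500, study_window=60.0, unknown_birth_fraction=0.3,
            seed=4, return_true_births=True)
        unknown = [r for r in recs if r.birth_time is None]
        assert 0.2 < len(unknown) / 500 < 0.4
        for r in unknown:
            assert r.individual_id in tb
            true_age_entry = r.entry_time - tb[r.individual_id]
            assert true_age_entry >= r.min_age_at_entry

    def test_invalid_arguments_rejected(self, ref_params):
        with pytest.raises(ValueError):
            simulate_census(ref_params, 0, 10.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_census(ref_params, 10, 10.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            simulate_census("not params", 10, 10.0, 0.0, seed=1)


class TestDeterminism:
    def test_identical_seeds_give_byte_identical_outputs(self, tmp_path):
        for sub in ("a", "b"):
            ds = simulate_dataset(12, seed=9, individuals_per_species=20)
            ds.write(tmp_path / sub)
        for name in ("tree.nwk", "traits.csv", "census.csv", "truth.json"):
            fa = (tmp_path / "a" / name).read_bytes()
            fb = (tmp_path / "b" / name).read_bytes()
            assert fa == fb, name

    def test_truth_validation(self):
        from phylospan.synthetic import Missingness
        with pytest.raises(ValueError):
            Missingness(fractions={"le": 1.0})
        with pytest.raises(ValueError):
            default_truth(10, measurement_error_sds={"le": 0.0,
                                                     "body": 0.1,
                                                     "brain": 0.1})
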