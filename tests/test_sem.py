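"""Structural-equation model: design assembly, coefficient summaries,
latent relative brain size, measurement-error propagation and imputation."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from phylospan import (
    SEMSamplerConfig,
    SEMSpec,
    build_design,
    compare_models,
    default_truth,
    fit_sem,
    impute_report,
    simulate_dataset,
    summarize_coefficients,
)
from phylospan.sem import CoefficientSummary, _overlap_with_zero

warnings.filterwarnings("ignore", message="SEM did not converge")


@pytest.fixture(scope="module")
def small_dataset():
    truth = default_truth(
        60, tree_seed=13, missing_fractions={"le": 0.25}, size_bias=0.0)
    return simulate_dataset(60, seed=31, truth=truth)


@pytest.fixture(scope="module")
def small_fit(small_dataset):
    ds = small_dataset
    spec = SEMSpec(model_id=1)
    bundle = build_design(ds.traits_observed, spec, ds.tree)
    post = fit_sem(bundle, spec,
                   SEMSamplerConfig(n_chains=2, n_iter=2500, max_rerun=0),
                   seed=5)
    return ds, bundle, post


class TestBuildDesign:
    def test_species_with_no_observed_variable_dropped(self, small_dataset):
        ds = small_dataset
        table = ds.traits_observed
        frame = table.frame.copy()
        victim = frame.index[0]
        frame.loc[victim, :] = np.nan
        from phylospan.traits import SpeciesTraitTable
        bundle = build_design(SpeciesTraitTable(frame=frame),
                              SEMSpec(model_id=1), ds.tree)
        assert victim in bundle.dropped_species
        assert victim not in bundle.species

    def test_model3_design_restricted_to_afr_observed(self, small_dataset):
        ds = small_dataset
        frame = ds.traits_observed.frame.copy()
        frame["afr"] = np.nan
        observed = frame.index[:17]
        frame.loc[observed, "afr"] = 2.0 + np.arange(17) * 0.1
        from phylospan.traits import SpeciesTraitTable
        bundle = build_design(SpeciesTraitTable(frame=frame),
                              SEMSpec(model_id=3), ds.tree)
        assert bundle.n == 17
        assert set(bundle.species) == set(observed)

    def test_model3_needs_enough_afr_species(self, small_dataset):
        ds = small_dataset
        frame = ds.traits_observed.frame.copy()
        frame["afr"] = np.nan
        frame.loc[frame.index[:5], "afr"] = 2.0
        from phylospan.traits import SpeciesTraitTable
        with pytest.raises(ValueError, match="AFR"):
            build_design(SpeciesTraitTable(frame=frame),
                         SEMSpec(model_id=3), ds.tree)

    def test_alignment_of_arrays_and_kernel(self, small_fit):
        _, bundle, _ = small_fit
        n = bundle.n
        assert bundle.le.shape == (n,)
        assert bundle.dist.distances.shape == (n, n)
        assert list(bundle.dist.species) == bundle.species

    def test_zero_species_overlap_rejected(self, small_dataset):
        ds = small_dataset
        frame = ds.traits_observed.frame.copy()
        frame.index = ["x" + s for s in frame.index]
        from phylospan.traits import SpeciesTraitTable
        with pytest.raises(ValueError, match="no overlapping species"):
            build_design(SpeciesTraitTable(frame=frame),
                         SEMSpec(model_id=1), ds.tree)

    def test_model_predictor_sets(self):
        assert SEMSpec(model_id=1).predictors == ["I", "BO", "RB", "LA", "D"]
        assert SEMSpec(model_id=2).predictors == [
            "I", "BO", "RB", "LA", "D", "DT", "CS"]
        assert SEMSpec(model_id=3).predictors[-1] == "AFR"
        with pytest.raises(ValueError):
            SEMSpec(model_id=4)


class TestOverlapWithZero:
    def test_all_positive_draws(self):
        assert _overlap_with_zero(np.ones(500)) == 0.0

    def test_symmetric_draws(self):
        rng = np.random.default_rng(0)
        assert _overlap_with_zero(rng.standard_normal(200_000)) == pytest.approx(
            0.5, abs=0.01)

    def test_gaussian_tail_oracle(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0.2, 0.1, 100_000)
        # P(draw < 0) = Phi(-2) ~ 0.0228
        assert _overlap_with_zero(draws) == pytest.approx(
            sps.norm.cdf(-2.0), abs=0.005)


class TestPosterior:
    def test_summaries_have_all_predictors(self, small_fit):
        _, _, post = small_fit
        summ = summarize_coefficients(post)
        assert [s.predictor for s in summ] == ["I", "BO", "RB", "LA", "D"]
        for s in summ:
            assert s.interval_low <= s.mean <= s.interval_high
            assert 0.0 <= s.overlap_with_zero <= 0.5 + 1e-12

    def test_relative_brain_size_is_orthogonal_to_body(self, small_fit):
        """Per-draw regression of the latent allometric residual (relative
        brain size) on latent body mass has slope ~ 0: the allometry soaks
        up the body-size dependence of brain mass by construction."""
        _, bundle, post = small_fit
        n = bundle.n
        slopes = [
            np.polyfit(post.latent_draws[k, :n], post.rb_latent_draws[k], 1)[0]
            for k in range(post.latent_draws.shape[0])
        ]
        assert abs(np.mean(slopes)) < 0.05

    def test_imputed_draws_exist_exactly_for_missing_cells(self, small_fit):
        ds, bundle, post = small_fit
        missing_le = {bundle.species[i]
                      for i in np.flatnonzero(np.isnan(bundle.le))}
        got_le = {sp for (sp, var) in post.imputed if var == "le_mean"}
        assert got_le == missing_le

    def test_observed_cells_unchanged_by_fitting(self, small_fit):
        ds, bundle, post = small_fit
        frame = ds.traits_observed.frame
        obs = ~np.isnan(bundle.le)
        st = bundle.standardizers["le"]
        reconstructed = st.inverse(bundle.le[obs])
        original = frame.loc[np.array(bundle.species)[obs], "le_mean"]
        assert np.allclose(reconstructed, original.to_numpy())

    def test_deterministic_under_seed(self, small_dataset):
        ds = small_dataset
        spec = SEMSpec(model_id=1)
        bundle = build_design(ds.traits_observed, spec, ds.tree)
        cfg = SEMSamplerConfig(n_chains=2, n_iter=600, max_rerun=0)
        p1 = fit_sem(bundle, spec, cfg, seed=9)
        p2 = fit_sem(bundle, spec, cfg, seed=9)
        assert np.array_equal(p1.chains, p2.chains)

    def test_summaries_require_enough_draws(self, small_dataset):
        ds = small_dataset
        spec = SEMSpec(model_id=1)
        bundle = build_design(ds.traits_observed, spec, ds.tree)
        post = fit_sem(bundle, spec,
                       SEMSamplerConfig(n_chains=2, n_iter=240, thin_store=60,
                                        max_rerun=0), seed=2)
        with pytest.raises(ValueError):
            summarize_coefficients(post)


class TestMeasurementError:
    def test_doubling_ses_widens_rb_interval(self):
        """With measurement error below the residual spread (the regular
        regime), doubling all SEs widens the relative-brain-size posterior
        interval."""
        from phylospan.synthetic import Allometry
        truth = default_truth(
            60, tree_seed=17, missing_fractions={}, size_bias=0.0,
            allometry=Allometry(slope=0.6, intercept=-2.3, residual_sd=0.3),
            measurement_error_sds={"le": 0.05, "body": 0.03, "brain": 0.06})
        ds = simulate_dataset(60, seed=23, truth=truth)
        spec = SEMSpec(model_id=1)
        cfg = SEMSamplerConfig(n_chains=2, n_iter=2500, max_rerun=0)
        bundle1 = build_design(ds.traits_observed, spec, ds.tree)
        post1 = fit_sem(bundle1, spec, cfg, seed=3)
        table2 = ds.traits_observed.frame.copy()
        for col in ("le_se", "body_se", "brain_se"):
            table2[col] = table2[col] * 2.0
        from phylospan.traits import SpeciesTraitTable
        bundle2 = build_design(SpeciesTraitTable(frame=table2), spec, ds.tree)
        post2 = fit_sem(bundle2, spec, cfg, seed=3)

        def width(post):
            s = next(x for x in summarize_coefficients(post)
                     if x.predictor == "RB")
            return s.interval_high - s.interval_low

        assert width(post2) > width(post1)


class TestKernelOffEquivalence:
    def test_posterior_means_match_independent_map_optimizer(self):
        """With the kernel off and no missing data the model is a
        measurement-error regression; posterior means should sit near the
        MAP of an independently coded objective."""
        from scipy.optimize import minimize

        truth = default_truth(
            80, tree_seed=19, missing_fractions={}, size_bias=0.0,
            kernel_params=__import__("phylospan").KernelParams(
                eta_sq=0.0, rho=1.0, sigma_ind=0.6))
        ds = simulate_dataset(80, seed=41, truth=truth)
        spec = SEMSpec(model_id=1, phylo=False)
        bundle = build_design(ds.traits_observed, spec, ds.tree)
        post = fit_sem(bundle, spec,
                       SEMSamplerConfig(n_chains=2, n_iter=4000, max_rerun=0),
                       seed=11)

        # independent MAP: per-species 3x3 Gaussian marginal + same priors
        b = bundle
        diet_score = (b.diet_level - 1) / 3.0
        la = b.covariates["LA"]

        def neglogpost(v):
            (c0, bI, bBO, bRB, bLA, bD, mu, al, ba,
             ls_bo, ls_br, ls_le) = v
            s_bo, s_br, s_le = np.exp([ls_bo, ls_br, ls_le])
            nll = 0.0
            for i in range(b.n):
                # latent (BO, uBR, LE-resid) integrate to a 3x3 normal over
                # the observed triple
                m_bo = mu
                m_br = al + ba * mu
                m_le = (c0 + bI * b.insularity[i] + bLA * la[i]
                        + bD * diet_score[i] + bBO * mu)
                cov = np.array([
                    [s_bo**2 + b.body_se[i]**2, ba * s_bo**2, bBO * s_bo**2],
                    [ba * s_bo**2, ba**2 * s_bo**2 + s_br**2
                     + b.brain_se[i]**2, ba * bBO * s_bo**2 + bRB * s_br**2],
                    [bBO * s_bo**2, ba * bBO * s_bo**2 + bRB * s_br**2,
                     bBO**2 * s_bo**2 + bRB**2 * s_br**2 + s_le**2
                     + b.le_se[i]**2],
                ])
                y = np.array([b.body[i], b.brain[i], b.le[i]])
                m = np.array([m_bo, m_br, m_le])
                sign, logdet = np.linalg.slogdet(cov)
                nll += 0.5 * (logdet
                              + (y - m) @ np.linalg.solve(cov, y - m))
            # priors: N(0,1) on linear terms, Exponential(1)+Jacobian on scales
            for x in (c0, bI, bBO, bRB, bLA, bD, mu, al, ba):
                nll += 0.5 * x**2
            for ls in (ls_bo, ls_br, ls_le):
                nll += np.exp(ls) - ls
            return nll

        x0 = np.zeros(12)
        x0[-3:] = np.log(0.5)
        opt = minimize(neglogpost, x0, method="BFGS",
                       options={"maxiter": 2000})
        assert opt.fun < neglogpost(x0)
        names = ["c0", "beta_I", "beta_BO", "beta_RB", "beta_LA", "beta_D"]
        map_vals = dict(zip(names, opt.x[:6]))
        from phylospan.diagnostics import effective_sample_size
        for nm in ("beta_BO", "beta_LA", "beta_I"):
            draws = post.scalar_draws(nm)
            per_chain = post.chains[:, :, post.layout.slices[nm].start]
            mcse = draws.std(ddof=1) / np.sqrt(
                max(effective_sample_size(per_chain), 4.0))
            assert abs(draws.mean() - map_vals[nm]) < max(
                2 * mcse, 0.1 * draws.std(ddof=1))


class TestImputeReport:
    def test_no_missing_cells_gives_empty_report(self):
        truth = default_truth(40, tree_seed=29, missing_fractions={},
                              size_bias=0.0)
        ds = simulate_dataset(40, seed=51, truth=truth)
        spec = SEMSpec(model_id=1)
        bundle = build_design(ds.traits_observed, spec, ds.tree)
        post = fit_sem(bundle, spec,
                       SEMSamplerConfig(n_chains=2, n_iter=800, max_rerun=0),
                       seed=2)
        assert len(impute_report(post)) == 0

    def test_report_covers_missing_le_cells_with_truth(self, small_fit):
        ds, bundle, post = small_fit
        rep = impute_report(post, ds.traits_true)
        le_rows = rep[rep.variable == "le_mean"]
        assert len(le_rows) == int(np.isnan(bundle.le).sum())
        assert {"mean", "sd", "low89", "high89", "truth", "covered",
                "error"} <= set(rep.columns)
        # most intervals should cover the truth for a well-specified model
        assert le_rows.covered.mean() > 0.5


class TestCompareModels:
    @staticmethod
    def _summary(pred, mean, ovl):
        return CoefficientSummary(pred, mean, 0.05, mean - 0.1, mean + 0.1,
                                  ovl)

    def _summaries(self, rb, ovl, dt=0.0, dt_ovl=0.5):
        base = {1: [], 2: [], 3: []}
        for mid in (1, 2, 3):
            preds = {1: ["I", "BO", "RB", "LA", "D"],
                     2: ["I", "BO", "RB", "LA", "D", "DT", "CS"],
                     3: ["I", "BO", "RB", "LA", "D", "DT", "CS", "AFR"]}[mid]
            for p in preds:
                if p == "RB":
                    base[mid].append(self._summary("RB", rb[mid - 1],
                                                   ovl[mid - 1]))
                elif p == "DT":
                    base[mid].append(self._summary("DT", dt, dt_ovl))
                else:
                    base[mid].append(self._summary(p, 0.0, 0.5))
        return base

    def test_direct_effect_pattern(self):
        out = compare_models(self._summaries(
            (0.22, 0.18, 0.16), (0.01, 0.02, 0.02)))
        assert out["pattern"] == "direct-effect"

    def test_indirect_pattern(self):
        out = compare_models(self._summaries(
            (0.22, 0.00, 0.00), (0.01, 0.5, 0.5), dt=0.3, dt_ovl=0.01))
        assert out["pattern"] == "indirect"

    def test_no_effect_pattern(self):
        out = compare_models(self._summaries(
            (0.01, 0.0, -0.01), (0.45, 0.5, 0.48)))
        assert out["pattern"] == "no-effect"

    def test_missing_model_rejected(self):
        s = self._summaries((0.2, 0.2, 0.2), (0.01, 0.01, 0.01))
        del s[2]
        with pytest.raises(ValueError):
            compare_models(s)
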