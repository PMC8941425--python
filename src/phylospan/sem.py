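"""Bayesian phylogenetic structural-equation models linking life expectancy
to relative brain size and life-history covariates.

Model structure (all continuous variables standardized; LE, body and brain
on the log scale before standardization):

    BO_true ~ MVN(mu_BO, S_BO)                       S_v = eta_v^2 E + sigma_v^2 I
    BR_true = alpha + beta_allo * BO_true + u_BR,    u_BR ~ MVN(0, S_BR)
    RB      = BR_true - pBR = u_BR                   (pBR = alpha + beta_allo*BO_true)
    LE_true = c0 + b_I*I + b_BO*BO_true + b_RB*u_BR + b_LA*LA + b_D*D(+...)
              + u_LE,                                u_LE ~ MVN(0, S_LE)

    observed LE/BO/BR = true value + Normal(0, SE)   (per-species SE)

where E_ij = exp(-rho * d_ij^2) is the phylogenetic correlation from the
L2-norm kernel on patristic distances. The allometry submodel runs
simultaneously with the outcome model, so relative brain size is a latent
residual, not a pre-computed regression residual, and information flows in
both directions.

Because every latent quantity is Gaussian conditional on the coefficients
and scales, the latent true values (and any missing LE/BO/BR cells) are
marginalized analytically; MCMC therefore runs on the ~20 hyperparameters
with a joint adaptive Metropolis block, plus random-walk blocks for missing
continuous covariate cells. Latent values and imputations are recovered
exactly per posterior draw from the Gaussian conditional, which is how
missing cells are "sampled from their conditional multinormal given observed
data, kernel covariance and the structural means".

The diet ordinal predictor uses a monotonic ordered effect: the effect at
level k is beta_D times the cumulative sum of simplex-constrained
increments (level 1 -> 0, top level -> 1). Dummy coding is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .diagnostics import effective_sample_size, gelman_rubin
from .phylo import PhyloDistanceMatrix, match_species, patristic_distances
from .traits import SpeciesTraitTable, Standardizer, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "SEMSpec",
    "SEMSamplerConfig",
    "DesignBundle",
    "SEMPosterior",
    "CoefficientSummary",
    "build_design",
    "fit_sem",
    "summarize_coefficients",
    "impute_report",
    "compare_models",
]

MODEL_PREDICTORS = {
    1: ["I", "BO", "RB", "LA", "D"],
    2: ["I", "BO", "RB", "LA", "D", "DT", "CS"],
    3: ["I", "BO", "RB", "LA", "D", "DT", "CS", "AFR"],
}


@dataclass(frozen=True)
class SEMSpec:
    """Which model to fit (1, 2 or 3) and its structural options."""

    model_id: int = 1
    diet_levels: int = 4
    diet_monotonic: bool = True
    phylo: bool = True   # False switches the kernel off (eta_sq = 0)
    priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")

    @property
    def predictors(self) -> list[str]:
        return list(MODEL_PREDICTORS[self.model_id])

    @property
    def complete_case_afr(self) -> bool:
        return self.model_id == 3


@dataclass
class SEMSamplerConfig:
    n_chains: int = 2
    n_iter: int = 4000
    burn_in: int | None = None
    thin_store: int = 5
    n_impute_draws: int = 200
    rhat_threshold: float = 1.05
    adapt_start: int = 300
    max_rerun: int = 1
    jitter: float = 1e-9


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

_COV_OF_PRED = {"LA": "max_latitude_range", "DT": "dev_time",
                "CS": "clutch_size", "AFR": "afr"}
_LOG_COVS = {"DT", "CS", "AFR"}


@dataclass
class DesignBundle:
    """Model-ready aligned arrays for one SEM fit."""

    spec: SEMSpec
    species: list[str]
    dist: PhyloDistanceMatrix
    # standardized y variables with per-species SEs; NaN marks missing
    le: np.ndarray
    le_se: np.ndarray
    body: np.ndarray
    body_se: np.ndarray
    brain: np.ndarray
    brain_se: np.ndarray
    insularity: np.ndarray
    diet_level: np.ndarray            # integer levels 1..K
    covariates: dict[str, np.ndarray]  # standardized LA/DT/CS/AFR, NaN missing
    standardizers: dict[str, Standardizer]
    dropped_species: list[str]
    cov_priors: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict)  # predictor -> (missing idx, cond mean, cond chol)

    @property
    def n(self) -> int:
        return len(self.species)


def _empirical_phylo_conditional(
    x: np.ndarray, d2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical-Bayes phylogenetic Gaussian prior for a covariate's missing
    cells: grid-ML over signal fraction and decay, then the conditional
    N(mean, cov) of missing given observed (unit marginal variance)."""
    miss = np.isnan(x)
    obs = ~miss
    xo = x[obs]
    best = (-np.inf, 0.0, 1.0)
    for h2 in (0.0, 0.2, 0.4, 0.6, 0.8):
        for rho in (0.5, 1.0, 2.0, 4.0):
            corr = h2 * np.exp(-rho * d2[np.ix_(obs, obs)])
            corr[np.diag_indices_from(corr)] = 1.0
            try:
                cf = sla.cho_factor(corr + 1e-9 * np.eye(obs.sum()))
            except (sla.LinAlgError, ValueError):
                continue
            quad = xo @ sla.cho_solve(cf, xo)
            ll = -0.5 * quad - np.log(np.diag(cf[0])).sum()
            if ll > best[0]:
                best = (ll, h2, rho)
    _, h2, rho = best
    corr = h2 * np.exp(-rho * d2)
    corr[np.diag_indices_from(corr)] = 1.0
    coo = corr[np.ix_(obs, obs)] + 1e-9 * np.eye(obs.sum())
    cmo = corr[np.ix_(miss, obs)]
    cmm = corr[np.ix_(miss, miss)]
    cf = sla.cho_factor(coo)
    mean = cmo @ sla.cho_solve(cf, xo)
    cov = cmm - cmo @ sla.cho_solve(cf, cmo.T)
    chol = np.linalg.cholesky(cov + 1e-9 * np.eye(miss.sum()))
    return np.flatnonzero(miss), mean, chol


def build_design(
    traits: SpeciesTraitTable,
    spec: SEMSpec,
    tree,
) -> DesignBundle:
    """Align trait table, tree and missingness into model-ready arrays.

    Species with at least one observed variable are retained (all-missing
    species are dropped with a logged count); for model 3 only species with
    observed AFR enter, and at least 10 are required. Binary insularity and
    ordinal diet must be observed (they are not imputed); missing cells are
    filled by their most common level with a logged warning.
    """
    frame = traits.frame
    dist_full = patristic_distances(tree)
    common = match_species(list(dist_full.species), list(frame.index))
    frame = frame.loc[common]

    core_cols = ["le_mean", "body_mean", "brain_mean", "insularity",
                 "max_latitude_range", "diet", "clutch_size", "dev_time",
                 "afr"]
    all_missing = frame[core_cols].isna().all(axis=1)
    dropped = list(frame.index[all_missing])
    if dropped:
        logger.info("dropping %d species with no observed variable: %s",
                    len(dropped), dropped[:5])
    frame = frame.loc[~all_missing]

    if spec.complete_case_afr:
        has_afr = frame["afr"].notna()
        frame = frame.loc[has_afr]
        if len(frame) < 10:
            raise ValueError(
                f"model 3 requires >= 10 AFR-observed species, got {len(frame)}"
            )

    species = list(frame.index)
    dist = dist_full.subset(species)
    d2 = dist.distances ** 2

    standardizers: dict[str, Standardizer] = {}

    def _std(values, key):
        z, st = standardize(values)
        standardizers[key] = st
        return z, st

    le, st_le = _std(frame["le_mean"].to_numpy(float), "le")
    body, st_bo = _std(frame["body_mean"].to_numpy(float), "body")
    brain, st_br = _std(frame["brain_mean"].to_numpy(float), "brain")
    le_se = st_le.scale_se(frame["le_se"].to_numpy(float))
    body_se = st_bo.scale_se(frame["body_se"].to_numpy(float))
    brain_se = st_br.scale_se(frame["brain_se"].to_numpy(float))

    insularity = frame["insularity"].to_numpy(float)
    if np.isnan(insularity).any():
        fill = float(pd.Series(insularity).mode().iloc[0])
        logger.warning("filling %d missing insularity cells with %s",
                       int(np.isnan(insularity).sum()), fill)
        insularity = np.where(np.isnan(insularity), fill, insularity)
    diet = frame["diet"].to_numpy(float)
    if np.isnan(diet).any():
        fill = float(pd.Series(diet).mode().iloc[0])
        logger.warning("filling %d missing diet cells with level %s",
                       int(np.isnan(diet).sum()), fill)
        diet = np.where(np.isnan(diet), fill, diet)
    if np.nanmax(diet) > spec.diet_levels or np.nanmin(diet) < 1:
        raise ValueError("diet levels outside declared ordinal range")

    covariates: dict[str, np.ndarray] = {}
    for pred in spec.predictors:
        if pred not in _COV_OF_PRED:
            continue
        col = _COV_OF_PRED[pred]
        vals = frame[col].to_numpy(float)
        if pred in _LOG_COVS:
            vals = np.log(vals)
        z, _ = _std(vals, pred)
        covariates[pred] = z

    bundle = DesignBundle(
        spec=spec, species=species, dist=dist,
        le=le, le_se=np.nan_to_num(le_se, nan=1.0),
        body=body, body_se=np.nan_to_num(body_se, nan=1.0),
        brain=brain, brain_se=np.nan_to_num(brain_se, nan=1.0),
        insularity=insularity, diet_level=diet.astype(int),
        covariates=covariates, standardizers=standardizers,
        dropped_species=dropped,
    )
    for pred, z in covariates.items():
        if np.isnan(z).any():
            bundle.cov_priors[pred] = _empirical_phylo_conditional(z, d2)
    return bundle


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------

class _Layout:
    """Maps named parameters to slices of the flat unconstrained vector."""

    def __init__(self, spec: SEMSpec, bundle: DesignBundle):
        self.names: list[str] = []
        self.slices: dict[str, slice] = {}
        pos = 0

        def add(name, size=1):
            nonlocal pos
            self.slices[name] = slice(pos, pos + size)
            self.names.append(name)
            pos += size

        add("c0")
        for p in spec.predictors:
            add(f"beta_{p}")
        if spec.diet_monotonic and spec.diet_levels > 2:
            add("diet_raw", spec.diet_levels - 1)
        add("mu_BO")
        add("alpha")
        add("beta_allo")
        if spec.phylo:
            add("log_rho")
        for v in ("BO", "BR", "LE"):
            if spec.phylo:
                add(f"log_eta2_{v}")
            add(f"log_sigma_{v}")
        for pred in bundle.cov_priors:
            add(f"zmiss_{pred}", bundle.cov_priors[pred][0].size)
        self.dim = pos

    def get(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[self.slices[name]]


def _diet_score(theta, lay: _Layout, spec: SEMSpec, levels: np.ndarray):
    """Cumulative monotonic score in [0,1] per species."""
    k = spec.diet_levels
    if not spec.diet_monotonic or k <= 2:
        return (levels - 1) / max(k - 1, 1)
    raw = lay.get(theta, "diet_raw")
    w = np.exp(raw - raw.max())
    w = w / w.sum()
    cum = np.concatenate([[0.0], np.cumsum(w)])
    return cum[levels - 1]


class _Model:
    """Marginal Gaussian likelihood of observed LE/BO/BR given parameters."""

    def __init__(self, bundle: DesignBundle, spec: SEMSpec,
                 jitter: float = 1e-9):
        self.b = bundle
        self.spec = spec
        self.lay = _Layout(spec, bundle)
        self.jitter = jitter
        n = bundle.n
        self.n = n
        self.d2 = bundle.dist.distances ** 2
        self.obs_le = ~np.isnan(bundle.le)
        self.obs_bo = ~np.isnan(bundle.body)
        self.obs_br = ~np.isnan(bundle.brain)
        # order of the stacked latent vector T = [BO; BR; LE]
        self.obs_idx = np.concatenate([
            np.flatnonzero(self.obs_bo),
            n + np.flatnonzero(self.obs_br),
            2 * n + np.flatnonzero(self.obs_le),
        ])
        self.y_obs = np.concatenate([
            bundle.body[self.obs_bo], bundle.brain[self.obs_br],
            bundle.le[self.obs_le],
        ])
        self.se2_obs = np.concatenate([
            bundle.body_se[self.obs_bo] ** 2,
            bundle.brain_se[self.obs_br] ** 2,
            bundle.le_se[self.obs_le] ** 2,
        ])

    # -- mean and covariance of T = [BO; BR; LE] ---------------------------

    def fixed_predictor(self, theta) -> np.ndarray:
        """LE-mean contribution of the directly observed covariates."""
        lay, b, spec = self.lay, self.b, self.spec
        out = np.full(self.n, float(lay.get(theta, "c0")[0]))
        out += float(lay.get(theta, "beta_I")[0]) * b.insularity
        out += float(lay.get(theta, "beta_D")[0]) * _diet_score(
            theta, lay, spec, b.diet_level)
        for pred in spec.predictors:
            if pred not in _COV_OF_PRED:
                continue
            z = b.covariates[pred].copy()
            if pred in b.cov_priors:
                idx = b.cov_priors[pred][0]
                z[idx] = lay.get(theta, f"zmiss_{pred}")
            out += float(lay.get(theta, f"beta_{pred}")[0]) * z
        return out

    def mean_T(self, theta) -> np.ndarray:
        lay = self.lay
        mu_bo = float(lay.get(theta, "mu_BO")[0])
        alpha = float(lay.get(theta, "alpha")[0])
        b_allo = float(lay.get(theta, "beta_allo")[0])
        b_bo = float(lay.get(theta, "beta_BO")[0])
        m_bo = np.full(self.n, mu_bo)
        m_br = alpha + b_allo * m_bo
        m_le = self.fixed_predictor(theta) + b_bo * m_bo
        return np.concatenate([m_bo, m_br, m_le])

    def cov_T(self, theta) -> np.ndarray:
        lay, n = self.lay, self.n
        clip = lambda x: min(max(x, -30.0), 30.0)
        if self.spec.phylo:
            rho = math.exp(clip(float(lay.get(theta, "log_rho")[0])))
            e = np.exp(-rho * self.d2)
        sig = {}
        for v in ("BO", "BR", "LE"):
            s2 = math.exp(2 * clip(float(lay.get(theta, f"log_sigma_{v}")[0])))
            if self.spec.phylo:
                eta2 = math.exp(clip(float(lay.get(theta, f"log_eta2_{v}")[0])))
                sig[v] = eta2 * e + s2 * np.eye(n)
            else:
                sig[v] = s2 * np.eye(n)
        b_allo = float(lay.get(theta, "beta_allo")[0])
        b_bo = float(lay.get(theta, "beta_BO")[0])
        b_rb = float(lay.get(theta, "beta_RB")[0])
        s1, s2m, s3 = sig["BO"], sig["BR"], sig["LE"]
        c = np.empty((3 * n, 3 * n))
        c[:n, :n] = s1
        c[n:2*n, n:2*n] = b_allo ** 2 * s1 + s2m
        c[2*n:, 2*n:] = b_bo ** 2 * s1 + b_rb ** 2 * s2m + s3
        c[:n, n:2*n] = b_allo * s1
        c[n:2*n, :n] = c[:n, n:2*n].T
        c[:n, 2*n:] = b_bo * s1
        c[2*n:, :n] = c[:n, 2*n:].T
        c[n:2*n, 2*n:] = b_allo * b_bo * s1 + b_rb * s2m
        c[2*n:, n:2*n] = c[n:2*n, 2*n:].T
        return c

    # -- log density --------------------------------------------------------

    def log_prior(self, theta) -> float:
        lay = self.lay
        lp = 0.0
        for name in lay.names:
            v = lay.get(theta, name)
            if name.startswith(("beta", "c0", "mu_BO", "alpha", "diet_raw")):
                lp += float(-0.5 * (v ** 2).sum())
            elif name.startswith(("log_eta2", "log_rho")):
                # Exponential(1) on the natural scale with log-Jacobian
                x = np.exp(v)
                lp += float((v - x).sum())
            elif name.startswith("log_sigma"):
                x = np.exp(v)
                lp += float((v - x).sum())
            elif name.startswith("zmiss_"):
                pred = name[6:]
                _, mean, chol = self.b.cov_priors[pred]
                r = sla.solve_triangular(chol, v - mean, lower=True)
                lp += float(-0.5 * (r ** 2).sum())
        return lp

    def marginal_loglik(self, theta, cov_factor=None):
        """Gaussian marginal over observed cells.

        Returns (loglik, cho_factor). Pass a cached ``cov_factor`` when only
        the mean changed (missing-covariate updates) to skip factorization.
        """
        m = self.mean_T(theta)[self.obs_idx]
        if cov_factor is None:
            c = self.cov_T(theta)[np.ix_(self.obs_idx, self.obs_idx)]
            c[np.diag_indices_from(c)] += self.se2_obs + self.jitter
            try:
                cov_factor = sla.cho_factor(c, lower=True)
            except (sla.LinAlgError, ValueError):
                return -np.inf, None
        r = self.y_obs - m
        alpha = sla.cho_solve(cov_factor, r)
        ll = (
            -0.5 * float(r @ alpha)
            - np.log(np.diag(cov_factor[0])).sum()
            - 0.5 * len(r) * math.log(2 * math.pi)
        )
        return ll, cov_factor

    def conditional_latent_draw(self, theta, rng) -> np.ndarray:
        """One exact draw of T = [BO_true; BR_true; LE_true] given data."""
        m = self.mean_T(theta)
        c = self.cov_T(theta)
        c_obs = c[np.ix_(self.obs_idx, self.obs_idx)].copy()
        c_obs[np.diag_indices_from(c_obs)] += self.se2_obs + self.jitter
        cf = sla.cho_factor(c_obs, lower=True)
        k = c[:, self.obs_idx]
        resid = self.y_obs - m[self.obs_idx]
        cond_mean = m + k @ sla.cho_solve(cf, resid)
        cond_cov = c - k @ sla.cho_solve(cf, k.T)
        chol = np.linalg.cholesky(
            cond_cov + 1e-8 * np.eye(cond_cov.shape[0]))
        return cond_mean + chol @ rng.standard_normal(cond_cov.shape[0])

    def init_theta(self, rng) -> np.ndarray:
        theta = 0.1 * rng.standard_normal(self.lay.dim)
        for name in self.lay.names:
            if name.startswith(("log_eta2", "log_sigma")):
                theta[self.lay.slices[name]] = (
                    math.log(0.5) + 0.2 * rng.standard_normal()
                )
            elif name == "log_rho":
                theta[self.lay.slices[name]] = 0.0 + 0.2 * rng.standard_normal()
            elif name.startswith("zmiss_"):
                pred = name[6:]
                _, mean, _ = self.b.cov_priors[pred]
                theta[self.lay.slices[name]] = mean
        return theta


# ---------------------------------------------------------------------------
# posterior containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoefficientSummary:
    predictor: str
    mean: float
    sd: float
    interval_low: float
    interval_high: float
    overlap_with_zero: float


@dataclass
class SEMPosterior:
    spec: SEMSpec
    bundle: DesignBundle
    param_names: list[str]
    chains: np.ndarray                # (m, kept, dim) unconstrained scale
    layout: _Layout
    rhat: dict[str, float]
    n_effective: dict[str, float]
    converged: bool
    latent_draws: np.ndarray          # (n_impute, 3n) of [BO;BR;LE]_true
    imputed: dict[tuple[str, str], np.ndarray]  # (species, var) -> draws
    rb_per_sd_draws: np.ndarray = None  # beta_RB per sd of realized RB
    rb_latent_draws: np.ndarray = None  # (n_impute, n) latent residuals u_BR

    def beta_draws(self, predictor: str) -> np.ndarray:
        """Posterior draws of a structural coefficient.

        RB is reported per sd of realized relative brain size (the draws
        are rescaled by the sample sd of the latent allometric residual);
        all other predictors are data-standardized, so their raw draws are
        already per-sd effects.
        """
        if predictor == "RB" and self.rb_per_sd_draws is not None:
            return self.rb_per_sd_draws
        sl = self.layout.slices[f"beta_{predictor}"]
        return self.chains[:, :, sl].reshape(-1)

    def scalar_draws(self, name: str) -> np.ndarray:
        sl = self.layout.slices[name]
        return self.chains[:, :, sl].reshape(-1)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

class _AdaptiveBlock:
    """Adaptive random-walk Metropolis state for one parameter block."""

    def __init__(self, idx: np.ndarray, scale0: float = 0.05):
        self.idx = idx
        d = idx.size
        self.cov_scale = scale0
        self.run_mean = None
        self.run_cov = np.eye(d) * 0.01
        self.chol = np.linalg.cholesky(self.run_cov * self.cov_scale)
        self.accepts = 0
        self.window = 0

    def propose(self, theta, rng):
        prop = theta.copy()
        prop[self.idx] += self.chol @ rng.standard_normal(self.idx.size)
        return prop

    def adapt(self, theta, it, burn, adapt_start):
        if it >= burn:
            return
        x = theta[self.idx]
        if self.run_mean is None:
            self.run_mean = x.copy()
        w = max(1.0 / (it + 2), 2e-3)
        delta = x - self.run_mean
        self.run_mean = self.run_mean + w * delta
        self.run_cov = (1 - w) * self.run_cov + w * np.outer(delta, delta)
        if it >= adapt_start and it % 50 == 0 and self.window > 0:
            rate = self.accepts / self.window
            if rate < 0.15:
                self.cov_scale *= 0.7
            elif rate > 0.40:
                self.cov_scale *= 1.3
            self.accepts = self.window = 0
            d = self.idx.size
            self.chol = np.linalg.cholesky(
                self.run_cov * self.cov_scale * (2.38 ** 2 / d)
                + 1e-10 * np.eye(d))


def _run_sem_chain(model: _Model, cfg: SEMSamplerConfig, n_iter, burn, rng):
    """Metropolis-within-Gibbs with three adaptive blocks: covariance-
    affecting parameters (fresh Cholesky per proposal), mean-only
    parameters (cached factor, cheap), and missing-covariate cells."""
    lay = model.lay
    theta = model.init_theta(rng)
    ll, cf = model.marginal_loglik(theta)
    while not np.isfinite(ll):
        theta = model.init_theta(rng)
        ll, cf = model.marginal_loglik(theta)
    lp = model.log_prior(theta)

    cov_names = {"beta_allo", "beta_BO", "beta_RB", "log_rho"} | {
        f"log_eta2_{v}" for v in ("BO", "BR", "LE")} | {
        f"log_sigma_{v}" for v in ("BO", "BR", "LE")}
    cov_idx, mean_idx = [], []
    for nm in lay.names:
        sl = lay.slices[nm]
        target = cov_idx if nm in cov_names else mean_idx
        if not nm.startswith("zmiss_"):
            target.extend(range(sl.start, sl.stop))
    adapt_start = max(50, min(cfg.adapt_start, burn // 5))
    block_cov = _AdaptiveBlock(np.array(cov_idx))
    block_mean = _AdaptiveBlock(np.array(mean_idx))
    zmiss_names = [nm for nm in lay.names if nm.startswith("zmiss_")]
    zscale = {nm: 0.2 for nm in zmiss_names}
    zacc = {nm: 0 for nm in zmiss_names}

    kept = np.empty((n_iter - burn, lay.dim))
    for it in range(n_iter):
        # covariance block: needs a fresh factorization
        prop = block_cov.propose(theta, rng)
        ll_p, cf_p = model.marginal_loglik(prop)
        lp_p = model.log_prior(prop)
        if np.isfinite(ll_p) and math.log(rng.uniform()) < (ll_p + lp_p) - (ll + lp):
            theta, ll, lp, cf = prop, ll_p, lp_p, cf_p
            block_cov.accepts += 1
        block_cov.window += 1
        block_cov.adapt(theta, it, burn, adapt_start)

        # mean-only block: reuse the cached factor
        prop = block_mean.propose(theta, rng)
        ll_p, _ = model.marginal_loglik(prop, cov_factor=cf)
        lp_p = model.log_prior(prop)
        if np.isfinite(ll_p) and math.log(rng.uniform()) < (ll_p + lp_p) - (ll + lp):
            theta, ll, lp = prop, ll_p, lp_p
            block_mean.accepts += 1
        block_mean.window += 1
        block_mean.adapt(theta, it, burn, adapt_start)

        # missing-covariate blocks: mean-only as well
        for nm in zmiss_names:
            sl = lay.slices[nm]
            prop = theta.copy()
            prop[sl] = theta[sl] + zscale[nm] * rng.standard_normal(
                sl.stop - sl.start)
            ll_p, _ = model.marginal_loglik(prop, cov_factor=cf)
            lp_p = model.log_prior(prop)
            if math.log(rng.uniform()) < (ll_p + lp_p) - (ll + lp):
                theta, ll, lp = prop, ll_p, lp_p
                zacc[nm] += 1
            if it < burn and it % 100 == 99:
                rate = zacc[nm] / 100
                zscale[nm] *= 0.7 if rate < 0.15 else (1.3 if rate > 0.4 else 1.0)
                zacc[nm] = 0

        if it >= burn:
            kept[it - burn] = theta
    return kept


def fit_sem(
    bundle: DesignBundle,
    spec: SEMSpec | None = None,
    config: SEMSamplerConfig | None = None,
    seed: int = 0,
) -> SEMPosterior:
    """Fit the structural-equation model by adaptive Metropolis MCMC.

    Non-convergence (any split-chain Rhat above threshold) triggers one
    automatic rerun with doubled burn-in and iterations; a still
    non-converged posterior is returned with ``converged=False`` and a
    warning.
    """
    spec = spec or bundle.spec
    cfg = config or SEMSamplerConfig()
    model = _Model(bundle, spec, jitter=cfg.jitter)
    n_iter = cfg.n_iter
    burn = cfg.burn_in if cfg.burn_in is not None else cfg.n_iter // 2

    monitor = [nm for nm in model.lay.names if not nm.startswith("zmiss_")]
    for attempt in range(cfg.max_rerun + 1):
        ss = np.random.SeedSequence([seed, attempt, spec.model_id])
        rngs = [np.random.default_rng(s) for s in ss.spawn(cfg.n_chains + 1)]
        chains = np.stack([
            _run_sem_chain(model, cfg, n_iter, burn, rngs[i])
            for i in range(cfg.n_chains)
        ])
        thin = max(1, cfg.thin_store)
        chains_t = chains[:, ::thin, :]
        rhat = {}
        for nm in monitor:
            sl = model.lay.slices[nm]
            for j in range(sl.stop - sl.start):
                key = nm if sl.stop - sl.start == 1 else f"{nm}[{j}]"
                rhat[key] = gelman_rubin(chains[:, :, sl.start + j])
        converged = all(v < cfg.rhat_threshold for v in rhat.values())
        if converged or attempt == cfg.max_rerun:
            break
        n_iter *= 2
        burn *= 2
    if not converged:
        import warnings
        warnings.warn("SEM did not converge after automatic rerun",
                      stacklevel=2)

    n_eff = {}
    for nm in monitor:
        sl = model.lay.slices[nm]
        if sl.stop - sl.start == 1:
            n_eff[nm] = effective_sample_size(chains[:, :, sl.start])

    # exact conditional draws of latent true values / imputations
    rng_imp = rngs[-1]
    flat = chains_t.reshape(-1, model.lay.dim)
    take = min(cfg.n_impute_draws, flat.shape[0])
    idx = np.linspace(0, flat.shape[0] - 1, take).astype(int)
    latent = np.stack([
        model.conditional_latent_draw(flat[i], rng_imp) for i in idx
    ])

    # beta_RB on the per-sd scale of relative brain size: the coefficient
    # applies to the latent residual u_BR, whose realized spread across
    # species (not its weakly identified marginal prior sd) is what
    # "standardized relative brain size" refers to
    n_sp = bundle.n
    alpha_d = flat[idx, model.lay.slices["alpha"].start]
    ballo_d = flat[idx, model.lay.slices["beta_allo"].start]
    u_br = (latent[:, n_sp:2 * n_sp]
            - alpha_d[:, None] - ballo_d[:, None] * latent[:, :n_sp])
    rb_sd = u_br.std(axis=1, ddof=1)
    rb_per_sd = flat[idx, model.lay.slices["beta_RB"].start] * rb_sd

    n = bundle.n
    imputed: dict[tuple[str, str], np.ndarray] = {}
    for var, offset, obs in [
        ("body_mean", 0, model.obs_bo), ("brain_mean", n, model.obs_br),
        ("le_mean", 2 * n, model.obs_le),
    ]:
        for i in np.flatnonzero(~obs):
            imputed[(bundle.species[i], var)] = latent[:, offset + i]
    for pred, (midx, _, _) in bundle.cov_priors.items():
        sl = model.lay.slices[f"zmiss_{pred}"]
        for j, i in enumerate(midx):
            imputed[(bundle.species[i], _COV_OF_PRED[pred])] = (
                flat[idx, sl.start + j])

    return SEMPosterior(
        spec=spec, bundle=bundle, param_names=monitor,
        chains=chains_t, layout=model.lay, rhat=rhat, n_effective=n_eff,
        converged=converged, latent_draws=latent, imputed=imputed,
        rb_per_sd_draws=rb_per_sd, rb_latent_draws=u_br,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _overlap_with_zero(draws: np.ndarray) -> float:
    mean = draws.mean()
    if mean >= 0:
        return float((draws < 0).mean())
    return float((draws > 0).mean())


def summarize_coefficients(post: SEMPosterior) -> list[CoefficientSummary]:
    """Posterior mean, sd, equal-tailed 89% interval and overlap-with-zero
    (posterior mass on the opposite side of zero from the mean) for each
    structural coefficient."""
    if post.chains.shape[0] * post.chains.shape[1] < 100:
        raise ValueError("need at least 100 post-burn-in draws")
    out = []
    for pred in post.spec.predictors:
        draws = post.beta_draws(pred)
        lo, hi = np.percentile(draws, [5.5, 94.5])
        out.append(CoefficientSummary(
            predictor=pred,
            mean=float(draws.mean()),
            sd=float(draws.std(ddof=1)),
            interval_low=float(lo),
            interval_high=float(hi),
            overlap_with_zero=_overlap_with_zero(draws),
        ))
    return out


def summaries_frame(summaries: list[CoefficientSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries]).set_index("predictor")


def impute_report(
    post: SEMPosterior,
    truth: SpeciesTraitTable | None = None,
) -> pd.DataFrame:
    """Per imputed cell: posterior mean, sd and 89% interval (standardized
    model scale); with a ground-truth table, adds the true value, whether
    the interval covers it, and the cell error (mean - truth)."""
    rows = []
    st = post.bundle.standardizers
    key_of = {"le_mean": "le", "body_mean": "body", "brain_mean": "brain",
              "max_latitude_range": "LA", "dev_time": "DT",
              "clutch_size": "CS", "afr": "AFR"}
    for (species, var), draws in post.imputed.items():
        lo, hi = np.percentile(draws, [5.5, 94.5])
        row = {
            "species": species, "variable": var,
            "mean": float(draws.mean()), "sd": float(draws.std(ddof=1)),
            "low89": float(lo), "high89": float(hi),
        }
        if truth is not None:
            tv = truth.frame.loc[species, var]
            if var in ("dev_time", "clutch_size", "afr"):
                tv = np.log(tv)
            tz = st[key_of[var]].transform(tv)
            row["truth"] = float(tz)
            row["covered"] = bool(lo <= tz <= hi)
            row["error"] = row["mean"] - float(tz)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(
    summaries: dict[int, list[CoefficientSummary]],
    *,
    effect_floor: float = 0.05,
    overlap_cut: float = 0.10,
) -> dict:
    """Tabulate the relative-brain-size effect across models 1-3 and flag
    which causal pattern the posterior supports.

    direct-effect pattern: beta_RB positive, similar, and clearly nonzero in
    all three models (cognitive-buffer prediction); indirect pattern:
    beta_RB present in model 1 but attenuated to ~0 once developmental
    covariates enter (expensive-brain prediction); otherwise no effect /
    inconclusive.
    """
    for mid in (1, 2, 3):
        if mid not in summaries:
            raise ValueError(f"missing summary for model {mid}")
    rb = {mid: next(s for s in summaries[mid] if s.predictor == "RB")
          for mid in (1, 2, 3)}
    betas = np.array([rb[m].mean for m in (1, 2, 3)])
    overlaps = np.array([rb[m].overlap_with_zero for m in (1, 2, 3)])
    nonzero = (np.abs(betas) > effect_floor) & (overlaps < overlap_cut)
    dev_effects = {}
    for mid, pred in [(2, "DT"), (2, "CS"), (3, "AFR")]:
        s = next((x for x in summaries[mid] if x.predictor == pred), None)
        if s is not None:
            dev_effects[f"model{mid}_{pred}"] = (s.mean, s.overlap_with_zero)
    if nonzero.all() and np.sign(betas).min() == np.sign(betas).max():
        similar = betas.max() - betas.min() < max(0.5 * np.abs(betas).mean(), 0.1)
        pattern = "direct-effect" if similar else "inconclusive"
    elif nonzero[0] and not nonzero[1:].any():
        pattern = "indirect"
    elif not nonzero.any():
        pattern = "no-effect"
    else:
        pattern = "inconclusive"
    return {
        "beta_RB": {m: rb[m].mean for m in (1, 2, 3)},
        "overlap_with_zero": {m: rb[m].overlap_with_zero for m in (1, 2, 3)},
        "developmental_effects": dev_effects,
        "pattern": pattern,
    }
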