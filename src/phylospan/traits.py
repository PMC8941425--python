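"""Species-level trait summaries: hierarchical species means with standard
errors, age at first reproduction, and standardization utilities.

Body and brain mass measurements arrive as repeated observations per species
from heterogeneous sources; a Bayesian multi-level normal model on the log
scale partially pools species means toward a grand mean, so that species
with a single measurement inherit uncertainty from the population of
species rather than reporting a spuriously exact value.

Age at first possible reproduction (AFR) is estimated as the 5th percentile
of recorded breeding ages, restricted to species with at least 30 breeding
individuals; species below the threshold are marked excluded (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementTable",
    "SpeciesTraitTable",
    "Standardizer",
    "fit_species_means",
    "estimate_afr",
    "standardize",
]


TRAIT_COLUMNS = [
    "le_mean", "le_se", "body_mean", "body_se", "brain_mean", "brain_se",
    "insularity", "max_latitude_range", "diet", "clutch_size", "dev_time",
    "afr",
]


@dataclass
class MeasurementTable:
    """Long-format measurements: one row per (species, variable, value)."""

    frame: pd.DataFrame  # columns: species, variable, value, source

    def __post_init__(self) -> None:
        required = {"species", "variable", "value"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"measurement table needs columns {required}")
        if (self.frame["value"] <= 0).any():
            raise ValueError("measurement values must be strictly positive")

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        return cls(frame=pd.read_csv(path))


def read_breeding_records(path) -> dict[str, list[float]]:
    """Breeding-age CSV (columns: species, age_years) -> per-species ages."""
    df = pd.read_csv(path)
    if not {"species", "age_years"}.issubset(df.columns):
        raise ValueError("breeding CSV needs columns species, age_years")
    return {
        sp: grp["age_years"].astype(float).tolist()
        for sp, grp in df.groupby("species")
    }


@dataclass
class SpeciesTraitTable:
    """Per-species trait means, standard errors and covariates.

    The underlying frame is indexed by species; NaN marks a missing cell.
    le/body/brain means are on the natural-log scale (log years / log grams)
    with standard errors on the same scale; standardization to zero mean and
    unit sd happens when the design matrix is built, with the constants kept
    for back-conversion.
    """

    frame: pd.DataFrame
    standardizers: dict[str, "Standardizer"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_cols = [c for c in TRAIT_COLUMNS if c not in self.frame.columns]
        for c in missing_cols:
            self.frame[c] = np.nan
        for mean_col, se_col in [
            ("le_mean", "le_se"), ("body_mean", "body_se"),
            ("brain_mean", "brain_se"),
        ]:
            bad = self.frame[mean_col].notna() & ~(self.frame[se_col] > 0)
            if bad.any():
                raise ValueError(
                    f"{se_col} must be strictly positive where {mean_col} "
                    f"is present (offending species: "
                    f"{list(self.frame.index[bad])[:5]})"
                )

    @property
    def species(self) -> list[str]:
        return list(self.frame.index)

    def missing_mask(self) -> pd.DataFrame:
        return self.frame[TRAIT_COLUMNS].isna()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="species", na_rep="NA")

    @classmethod
    def from_csv(cls, path) -> "SpeciesTraitTable":
        frame = pd.read_csv(path, index_col="species", na_values=["NA"])
        return cls(frame=frame)


# ---------------------------------------------------------------------------
# hierarchical species means
# ---------------------------------------------------------------------------

def fit_species_means(
    measurements: MeasurementTable,
    seed: int = 0,
    *,
    variable: str | None = None,
    n_iter: int = 3000,
    burn_in: int = 1000,
) -> pd.DataFrame:
    """Partial-pooling normal model on log measurements.

    Model: log v_ij ~ Normal(theta_s, sigma); theta_s ~ Normal(mu, tau);
    mu ~ Normal(data mean, 10); sigma, tau ~ half-Normal(0, 1) on the log
    scale of the measurements. Sampled by Gibbs (conjugate theta, mu) with
    random-walk MH on log sigma and log tau.

    Returns a frame indexed by species with columns ``mean`` and ``se``
    (posterior mean and sd of theta_s, log scale).
    """
    df = measurements.frame
    if variable is not None:
        df = df[df["variable"] == variable]
    if len(df) == 0:
        raise ValueError("no measurements")
    y = np.log(df["value"].to_numpy(dtype=float))
    codes, species = pd.factorize(df["species"])
    n_sp = len(species)
    n_s = np.bincount(codes, minlength=n_sp).astype(float)
    ybar_s = np.bincount(codes, weights=y, minlength=n_sp) / n_s

    rng = np.random.default_rng(seed)
    mu = y.mean()
    m0, s0 = y.mean(), 10.0
    log_sigma, log_tau = np.log(max(y.std(), 0.05) + 1e-6), 0.0
    theta = ybar_s.copy()

    keep_sum = np.zeros(n_sp)
    keep_sq = np.zeros(n_sp)
    kept = 0

    def scale_logpost(ls: float, resid_sq: float, n: float) -> float:
        s = np.exp(ls)
        # half-Normal(0,1) prior + log-Jacobian of the log transform
        return -n * ls - 0.5 * resid_sq / s ** 2 - 0.5 * s ** 2 + ls

    for it in range(n_iter):
        sigma2, tau2 = np.exp(2 * log_sigma), np.exp(2 * log_tau)
        # theta_s | rest (conjugate, vectorized)
        prec = n_s / sigma2 + 1.0 / tau2
        mean = (n_s * ybar_s / sigma2 + mu / tau2) / prec
        theta = mean + rng.standard_normal(n_sp) / np.sqrt(prec)
        # mu | theta
        prec_mu = n_sp / tau2 + 1.0 / s0 ** 2
        mean_mu = (theta.sum() / tau2 + m0 / s0 ** 2) / prec_mu
        mu = mean_mu + rng.standard_normal() / np.sqrt(prec_mu)
        # sigma, tau via RW-MH on log scale
        resid_sq = float(((y - theta[codes]) ** 2).sum())
        prop = log_sigma + 0.15 * rng.standard_normal()
        if (np.log(rng.uniform()) <
                scale_logpost(prop, resid_sq, len(y))
                - scale_logpost(log_sigma, resid_sq, len(y))):
            log_sigma = prop
        theta_sq = float(((theta - mu) ** 2).sum())
        prop = log_tau + 0.3 * rng.standard_normal()
        if (np.log(rng.uniform()) <
                scale_logpost(prop, theta_sq, n_sp)
                - scale_logpost(log_tau, theta_sq, n_sp)):
            log_tau = prop
        if it >= burn_in:
            keep_sum += theta
            keep_sq += theta ** 2
            kept += 1

    post_mean = keep_sum / kept
    post_var = np.maximum(keep_sq / kept - post_mean ** 2, 1e-12)
    return pd.DataFrame(
        {"mean": post_mean, "se": np.sqrt(post_var)},
        index=pd.Index(species, name="species"),
    )


# ---------------------------------------------------------------------------
# age at first reproduction
# ---------------------------------------------------------------------------

def estimate_afr(
    breeding_records: Mapping[str, Sequence[float]],
    min_n: int = 30,
    *,
    percentile: float = 5.0,
    method: str = "linear",
) -> dict[str, float | None]:
    """5th percentile of breeding ages per species; None below ``min_n``.

    The percentile uses linear interpolation between closest order
    statistics by default (switchable via ``method``, passed to numpy).
    """
    out: dict[str, float | None] = {}
    for sp, ages in breeding_records.items():
        ages = np.asarray(list(ages), dtype=float)
        if ages.size and np.any(ages <= 0):
            raise ValueError(f"breeding ages must be positive ({sp})")
        if ages.size < min_n:
            out[sp] = None
        else:
            out[sp] = float(np.percentile(ages, percentile, method=method))
    return out


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardizer:
    """Affine transform to sample mean 0 / sd 1 with stored constants."""

    mean: float
    sd: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean

    def scale_se(self, se):
        """Standard errors transform by the scale only."""
        return np.asarray(se, dtype=float) / self.sd


def standardize(values) -> tuple[np.ndarray, Standardizer]:
    """Center/scale to mean 0, sd 1 over non-missing cells (NaN preserved)."""
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError("need at least 2 non-missing values")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: cannot standardize")
    st = Standardizer(mean=mean, sd=sd)
    return st.transform(x), st
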