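"""Country-year covariates for the hierarchical model.

Three ingredients: the 14 FAO diet-composition variables in log-percent form
reduced to four principal-component factor scores; lag-distributed income
(log of a geometric distributed-lag average of past income); and mean years
of education. One covariate record per country-year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOG_PERCENT_OFFSET = 0.01  # percentage points added before the log so zeros stay finite
N_FACTORS = 4

COVARIATE_COLUMNS = ["ldi", "education", "factor_1", "factor_2", "factor_3", "factor_4"]


@dataclass(frozen=True)
class FAOCountryYear:
    """One country-year food balance sheet record."""

    country: str
    year: int
    availability: dict  # food -> g/capita/day
    composition: tuple  # 14 variables, % of total kcal

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.availability.values()):
            raise ValueError("availability must be >= 0")
        if any(v < 0 for v in self.composition):
            raise ValueError("composition percentages must be >= 0")


@dataclass(frozen=True)
class CovariateSet:
    """Standardized covariate vector for one country-period."""

    ldi: float
    education: float
    fao_factors: tuple[float, ...]
    log_availability: float | None = None

    def vector(self) -> np.ndarray:
        base = [self.ldi, self.education, *self.fao_factors]
        if self.log_availability is not None:
            base.append(self.log_availability)
        return np.asarray(base, dtype=float)


def composition_log_percent(percents, offset: float = LOG_PERCENT_OFFSET) -> np.ndarray:
    """ln(percent-of-energy + offset) for the 14 composition variables."""
    x = np.asarray(percents, dtype=float)
    if np.any(x < 0):
        raise ValueError("composition percentages must be >= 0")
    return np.log(x + offset)


@dataclass
class FactorModel:
    """Principal-component reduction of the standardized composition matrix.

    ``loadings`` columns are orthonormal; each column's largest-magnitude
    entry is forced positive so factor signs are reproducible.
    """

    loadings: np.ndarray        # p x k
    column_means: np.ndarray
    column_sds: np.ndarray
    explained_variance: np.ndarray  # k fractions, non-increasing

    def transform(self, matrix) -> np.ndarray:
        z = (np.asarray(matrix, dtype=float) - self.column_means) / self.column_sds
        return z @ self.loadings


def fit_fao_factors(matrix, n_factors: int = N_FACTORS) -> tuple[FactorModel, np.ndarray]:
    """Fit a PCA factor model on the correlation scale; returns (model, scores).

    Columns are z-scored (PCA on the correlation matrix — the variables are on
    heterogeneous percent scales) and the top ``n_factors`` components kept.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (country-years x variables)")
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows for a stable factor fit, got {n}")
    if np.isnan(X).any():
        raise ValueError("missing cells must be imputed before factor fitting")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("constant composition column; cannot standardize")
    Z = (X - means) / sds
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    if np.sum(svals > 1e-10 * svals[0]) < n_factors:
        raise ValueError(f"composition matrix has rank < {n_factors}")
    loadings = vt[:n_factors].T.copy()
    # sign convention: dominant entry of each loading column positive
    for j in range(n_factors):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    var = svals ** 2 / np.sum(svals ** 2)
    model = FactorModel(loadings=loadings, column_means=means, column_sds=sds,
                        explained_variance=var[:n_factors])
    return model, Z @ loadings


def lag_distributed_income(income: pd.Series, decay: float = 0.9, window: int = 10) -> pd.Series:
    """Log of a geometric distributed-lag average of income.

    For year t the smoothed income is sum_k w_k * income[t-k] over the prior
    ``window`` years (k = 0..window-1) with w_k proportional to decay**k,
    renormalised over whatever prefix of the series is available. Input must
    be a contiguous annual series indexed by year.
    """
    income = income.sort_index()
    years = income.index.to_numpy()
    if len(years) > 1 and np.any(np.diff(years) != 1):
        raise ValueError("income series must be contiguous in year")
    vals = income.to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("income must be positive")
    weights = decay ** np.arange(window)
    out = np.empty_like(vals)
    for i in range(len(vals)):
        k = min(i + 1, window)
        w = weights[:k] / weights[:k].sum()
        out[i] = np.dot(w, vals[i::-1][:k])
    return pd.Series(np.log(out), index=income.index, name="ldi")


def build_covariates(fao: pd.DataFrame, raw: pd.DataFrame,
                     n_factors: int = N_FACTORS) -> tuple[pd.DataFrame, FactorModel]:
    """Assemble the country-year covariate table.

    ``fao`` is the long availability table carrying comp_1..comp_14 columns;
    ``raw`` has country, year, income, education_years. Returns one row per
    country-year with ldi, education and factor_1..factor_4, plus the fitted
    factor model.
    """
    comp_cols = [c for c in fao.columns if c.startswith("comp_")]
    comp = fao.drop_duplicates(["country", "year"])[["country", "year"] + comp_cols]
    comp = comp.sort_values(["country", "year"]).reset_index(drop=True)
    logged = composition_log_percent(comp[comp_cols].to_numpy())
    model, scores = fit_fao_factors(logged, n_factors=n_factors)
    out = comp[["country", "year"]].copy()
    for j in range(n_factors):
        out[f"factor_{j + 1}"] = scores[:, j]

    ldi_parts = []
    for country, block in raw.sort_values("year").groupby("country"):
        s = lag_distributed_income(block.set_index("year")["income"])
        part = s.reset_index()
        part["country"] = country
        ldi_parts.append(part)
    ldi = pd.concat(ldi_parts, ignore_index=True)
    out = out.merge(ldi, on=["country", "year"])
    out = out.merge(raw[["country", "year", "education_years"]], on=["country", "year"])
    out = out.rename(columns={"education_years": "education"})
    return out[["country", "year"] + COVARIATE_COLUMNS], model
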