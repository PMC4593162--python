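"""The age-integrating Bayesian hierarchical intake model.

For one food, the latent log mean intake of stratum (country c, period t,
age band a, sex s) is::

    eta = mu0 + u_region(c) + u_country(c) + gamma * (t - 2000)/10
          + age_knots[a] + phi_sex * 1[s = F] + beta' x(c, t)

with sum-to-zero age knots and z-scored country-period covariates x (income,
education, four FAO composition factors). Observations enter on the log scale:

* survey arm: log observed mean ~ Normal(log(sum_k w_k exp(eta_k)) + biases,
  (se/mean)^2 + tau^2), where w_k are population weights over the strata the
  grouped observation averages (age integration), and the bias terms
  delta_hb/delta_sub/delta_met apply to household-budget, subnational and
  secondary-metric sources. Nationally representative individual-level
  primary-metric surveys carry no bias term — they are the reference standard.
* FAO arm: log availability ~ Normal(log(all-adult population mean) +
  delta_fao, floor_cv^2 + tau^2). The crosswalk delta_fao is the systematic
  log overestimation of availability relative to true intake; the floored
  measurement CV keeps surveys dominant where both sources exist.

Hierarchy: u_region ~ N(0, sigma_region^2), u_country ~ N(0, sigma_country^2).
Weak priors: Normal(0, 10^2) on fixed effects and biases, Half-Normal(1) on
the three SDs (sampled on the log scale with the Jacobian included). The
posterior is explored with a single adaptive Metropolis chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .covariates import COVARIATE_COLUMNS
from .grids import ANCHOR_YEARS, SEXES, AgeGrid, StratumKey
from .mcmc import ChainResult, MCMCSettings, adaptive_metropolis
from .standardize import METHOD_HOUSEHOLD, SurveyObservation, map_to_strata

logger = logging.getLogger(__name__)

FAO_FLOOR_CV = 0.25


@dataclass
class ModelParams:
    """Structured view of the full parameter vector (natural-log intake scale)."""

    mu0: float
    u_region: np.ndarray
    u_country: np.ndarray
    gamma: float
    age_knots: np.ndarray          # sum-to-zero
    phi_sex: float
    beta_cov: np.ndarray
    delta_fao: float
    delta_hb: float
    delta_sub: float
    delta_met: float
    sigma_region: float
    sigma_country: float
    tau: float

    def __post_init__(self) -> None:
        if min(self.sigma_region, self.sigma_country, self.tau) <= 0:
            raise ValueError("sigma_region, sigma_country and tau must be positive")
        if abs(float(np.sum(self.age_knots))) > 1e-8:
            raise ValueError("age_knots must sum to zero")


@dataclass(frozen=True)
class ParamSpace:
    """Index map between ModelParams and the flat sampling vector.

    Age knots use A-1 free coordinates (the last knot is minus their sum) so
    the sum-to-zero constraint holds exactly; the three SDs are sampled as
    logs.
    """

    regions: tuple[str, ...]
    countries: tuple[str, ...]
    region_of: Mapping[str, str]
    n_bands: int
    cov_names: tuple[str, ...] = tuple(COVARIATE_COLUMNS)

    @property
    def dim(self) -> int:
        return (1 + len(self.regions) + len(self.countries) + 1 + (self.n_bands - 1)
                + 1 + len(self.cov_names) + 4 + 3)

    def slices(self) -> dict[str, slice]:
        out, i = {}, 0

        def take(name, k):
            nonlocal i
            out[name] = slice(i, i + k)
            i += k

        take("mu0", 1)
        take("u_region", len(self.regions))
        take("u_country", len(self.countries))
        take("gamma", 1)
        take("age", self.n_bands - 1)
        take("phi_sex", 1)
        take("beta", len(self.cov_names))
        take("delta_fao", 1)
        take("delta_hb", 1)
        take("delta_sub", 1)
        take("delta_met", 1)
        take("log_sigma_region", 1)
        take("log_sigma_country", 1)
        take("log_tau", 1)
        return out

    def unpack(self, vec: np.ndarray) -> ModelParams:
        s = self.slices()
        age_free = vec[s["age"]]
        return ModelParams(
            mu0=float(vec[s["mu0"]][0]),
            u_region=vec[s["u_region"]].copy(),
            u_country=vec[s["u_country"]].copy(),
            gamma=float(vec[s["gamma"]][0]),
            age_knots=np.concatenate([age_free, [-age_free.sum()]]),
            phi_sex=float(vec[s["phi_sex"]][0]),
            beta_cov=vec[s["beta"]].copy(),
            delta_fao=float(vec[s["delta_fao"]][0]),
            delta_hb=float(vec[s["delta_hb"]][0]),
            delta_sub=float(vec[s["delta_sub"]][0]),
            delta_met=float(vec[s["delta_met"]][0]),
            sigma_region=float(np.exp(vec[s["log_sigma_region"]][0])),
            sigma_country=float(np.exp(vec[s["log_sigma_country"]][0])),
            tau=float(np.exp(vec[s["log_tau"]][0])),
        )

    def pack(self, p: ModelParams) -> np.ndarray:
        vec = np.empty(self.dim)
        s = self.slices()
        vec[s["mu0"]] = p.mu0
        vec[s["u_region"]] = p.u_region
        vec[s["u_country"]] = p.u_country
        vec[s["gamma"]] = p.gamma
        vec[s["age"]] = p.age_knots[:-1]
        vec[s["phi_sex"]] = p.phi_sex
        vec[s["beta"]] = p.beta_cov
        vec[s["delta_fao"]] = p.delta_fao
        vec[s["delta_hb"]] = p.delta_hb
        vec[s["delta_sub"]] = p.delta_sub
        vec[s["delta_met"]] = p.delta_met
        vec[s["log_sigma_region"]] = np.log(p.sigma_region)
        vec[s["log_sigma_country"]] = np.log(p.sigma_country)
        vec[s["log_tau"]] = np.log(p.tau)
        return vec


def predict_stratum(params: ModelParams, key: StratumKey, cov, space: ParamSpace) -> float:
    """Posterior-mean intake surface at one stratum (g/day); strictly positive.

    ``cov`` supplies the standardized covariate vector for the stratum's
    country-period (object with ``.vector()`` or an array-like).
    """
    x = cov.vector() if hasattr(cov, "vector") else np.asarray(cov, dtype=float)
    if x.shape != (len(space.cov_names),) or not np.all(np.isfinite(x)):
        raise ValueError(f"missing/invalid covariates for {key.country}-{key.year}")
    r = space.regions.index(space.region_of[key.country])
    c = space.countries.index(key.country)
    eta = (params.mu0 + params.u_region[r] + params.u_country[c]
           + params.gamma * (key.year - 2000.0) / 10.0
           + float(params.age_knots[key.age_band])
           + (params.phi_sex if key.sex == "F" else 0.0)
           + float(params.beta_cov @ x))
    return float(np.exp(eta))


def expected_observation(params: ModelParams, obs, grid: AgeGrid,
                         populations: Mapping[tuple[int, str], float], cov,
                         space: ParamSpace, period: int | None = None,
                         at_actual_year: bool = False) -> float:
    """Model expectation of one observed mean (g/day).

    Survey arm: population-weighted mean of stratum predictions over the
    observation's age range (and sexes for 'both'), times the exp of the
    applicable source biases. FAO arm (any object with an ``availability``
    attribute or key): all-adult population mean times exp(delta_fao).
    """
    if isinstance(obs, SurveyObservation):
        pairs = map_to_strata(obs, grid, populations, period=period)
        value = sum(w * predict_stratum(params, key, cov, space) for key, w in pairs)
        if obs.method == METHOD_HOUSEHOLD:
            value *= float(np.exp(params.delta_hb))
        if not obs.representative:
            value *= float(np.exp(params.delta_sub))
        if obs.metric == "secondary":
            value *= float(np.exp(params.delta_met))
        if at_actual_year:
            anchor = period if period is not None else obs.year
            value *= float(np.exp(params.gamma * (obs.year - anchor) / 10.0))
        return value
    # FAO arm
    country = obs.country if hasattr(obs, "country") else obs["country"]
    year = period if period is not None else int(obs.year if hasattr(obs, "year") else obs["year"])
    total = wsum = 0.0
    for (band, sex), w in populations.items():
        if w <= 0:
            continue
        total += w * predict_stratum(params, StratumKey(country, year, band, sex), cov, space)
        wsum += w
    if wsum == 0:
        raise ValueError(f"no populated strata for FAO record {country}-{year}")
    return total / wsum * float(np.exp(params.delta_fao))


@dataclass(frozen=True)
class PriorConfig:
    fixed_sd: float = 10.0      # Normal(0, fixed_sd^2) on fixed effects and biases
    sd_scale: float = 1.0       # Half-Normal(sd_scale) on the three SDs
    age_smooth_sd: float = 0.05  # N(0, sd^2) on first differences of the age curve



@dataclass
class FitData:
    """Pre-assembled arrays for the vectorized log-posterior of one food."""

    space: ParamSpace
    strata: list[StratumKey]
    X: np.ndarray              # S x dim design (delta/sigma columns zero)
    W: sp.csr_matrix           # N x S age/sex integration weights
    B: np.ndarray              # N x 4 bias design: [hb, sub, met, fao]
    year_offset: np.ndarray    # (obs year - anchor)/10, multiplies gamma
    log_y: np.ndarray
    se_rel2: np.ndarray        # (se/mean)^2 per observation
    is_fao: np.ndarray
    cov_means: np.ndarray      # standardization constants of the covariates
    cov_sds: np.ndarray
    populations: np.ndarray    # aligned to strata

    @property
    def n_obs(self) -> int:
        return len(self.log_y)

    def stratum_index(self) -> dict[StratumKey, int]:
        return {k: i for i, k in enumerate(self.strata)}


def _stratum_design_row(space: ParamSpace, key: StratumKey, x_cov: np.ndarray) -> np.ndarray:
    s = space.slices()
    row = np.zeros(space.dim)
    row[s["mu0"]] = 1.0
    row[s["u_region"].start + space.regions.index(space.region_of[key.country])] = 1.0
    row[s["u_country"].start + space.countries.index(key.country)] = 1.0
    row[s["gamma"]] = (key.year - 2000.0) / 10.0
    if key.age_band < space.n_bands - 1:
        row[s["age"].start + key.age_band] = 1.0
    else:
        row[s["age"]] = -1.0
    row[s["phi_sex"]] = 1.0 if key.sex == "F" else 0.0
    row[s["beta"]] = x_cov
    return row


def build_fit_data(std_obs: pd.DataFrame, fao: pd.DataFrame, covariates: pd.DataFrame,
                   populations: pd.DataFrame, grid: AgeGrid, food: str,
                   fao_mode: str = "likelihood", fao_floor_cv: float = FAO_FLOOR_CV,
                   anchor_years: Sequence[int] = ANCHOR_YEARS) -> FitData:
    """Assemble strata, design matrices and observation arrays for one food.

    ``std_obs`` is the standardized per-period survey table, ``fao`` the long
    availability table, ``covariates`` the country-year covariate table and
    ``populations`` carries country, region, age_band, sex, population.
    ``fao_mode='likelihood'`` adds FAO rows as crosswalked pseudo-observations;
    ``'covariate'`` instead appends log availability of the food to the
    covariate vector.
    """
    pop = populations.drop_duplicates(["country", "age_band", "sex"])
    countries = tuple(sorted(pop.country.unique()))
    region_of = dict(pop.drop_duplicates("country")[["country", "region"]].values)
    regions = tuple(sorted(set(region_of.values())))

    cov = covariates[covariates.year.isin(anchor_years)].copy()
    cov_names = list(COVARIATE_COLUMNS)
    if fao_mode == "covariate":
        fa = fao[(fao.food == food) & fao.year.isin(anchor_years)]
        fa = fa[["country", "year", "availability_g_day"]].copy()
        fa["log_avail"] = np.log(fa.availability_g_day)
        cov = cov.merge(fa[["country", "year", "log_avail"]], on=["country", "year"])
        cov_names.append("log_avail")
    elif fao_mode != "likelihood":
        raise ValueError(f"unknown fao_mode {fao_mode!r}")

    means = cov[cov_names].mean().to_numpy()
    sds = cov[cov_names].std(ddof=0).replace(0.0, 1.0).to_numpy()
    for j, name in enumerate(cov_names):
        cov[name] = (cov[name] - means[j]) / sds[j]
    cov_lookup = {(r.country, int(r.year)): np.array([getattr(r, n) for n in cov_names])
                  for r in cov.itertuples()}

    space = ParamSpace(regions=regions, countries=countries, region_of=region_of,
                       n_bands=grid.n_bands, cov_names=tuple(cov_names))

    strata: list[StratumKey] = []
    pops: list[float] = []
    pop_lookup: dict[str, dict[tuple[int, str], float]] = {}
    for c in countries:
        block = pop[pop.country == c]
        pop_lookup[c] = {(int(r.age_band), r.sex): float(r.population) for r in block.itertuples()}
        for year in anchor_years:
            for a in range(grid.n_bands):
                for s in SEXES:
                    strata.append(StratumKey(c, int(year), a, s))
                    pops.append(pop_lookup[c].get((a, s), 0.0))
    index = {k: i for i, k in enumerate(strata)}

    X = np.vstack([_stratum_design_row(space, k, cov_lookup[(k.country, k.year)])
                   for k in strata])

    w_rows, w_cols, w_vals = [], [], []
    b_rows, log_y, se_rel2, is_fao, year_offset = [], [], [], [], []
    n = 0

    obs_food = std_obs[std_obs.food == food]
    for row in obs_food.itertuples():
        if row.mean_intake <= 0:
            logger.warning("skipping non-positive observed mean in survey %s", row.survey_id)
            continue
        obs = SurveyObservation(
            survey_id=str(row.survey_id), country=str(row.country), year=int(row.year),
            age_lo=float(row.age_lo), age_hi=float(row.age_hi), sex=str(row.sex),
            mean_intake=float(row.mean_intake), se=float(row.se), n=int(row.n),
            representative=bool(int(row.representative)), method=str(row.method),
            metric=str(row.metric), food=food)
        pairs = map_to_strata(obs, grid, pop_lookup[obs.country], period=int(row.period))
        for key, w in pairs:
            w_rows.append(n)
            w_cols.append(index[key])
            w_vals.append(w)
        b_rows.append([float(obs.method == METHOD_HOUSEHOLD),
                       float(not obs.representative),
                       float(obs.metric == "secondary"), 0.0])
        log_y.append(np.log(obs.mean_intake))
        se_rel2.append((obs.se / obs.mean_intake) ** 2)
        is_fao.append(False)
        year_offset.append((obs.year - int(row.period)) / 10.0)
        n += 1

    if fao_mode == "likelihood":
        fa = fao[(fao.food == food) & fao.year.isin(anchor_years)]
        for row in fa.itertuples():
            if row.availability_g_day <= 0:
                continue
            total = sum(pop_lookup[row.country].values())
            for (band, sex), w in pop_lookup[row.country].items():
                if w <= 0:
                    continue
                w_rows.append(n)
                w_cols.append(index[StratumKey(str(row.country), int(row.year), band, sex)])
                w_vals.append(w / total)
            b_rows.append([0.0, 0.0, 0.0, 1.0])
            log_y.append(np.log(row.availability_g_day))
            se_rel2.append(fao_floor_cv ** 2)
            is_fao.append(True)
            year_offset.append(0.0)
            n += 1

    W = sp.csr_matrix((w_vals, (w_rows, w_cols)), shape=(n, len(strata)))
    return FitData(space=space, strata=strata, X=X, W=W,
                   B=np.asarray(b_rows, dtype=float),
                   year_offset=np.asarray(year_offset), log_y=np.asarray(log_y),
                   se_rel2=np.asarray(se_rel2), is_fao=np.asarray(is_fao, dtype=bool),
                   cov_means=means, cov_sds=sds, populations=np.asarray(pops))


class LogPosterior:
    """Vectorized log posterior density over the flat parameter vector."""

    def __init__(self, data: FitData, priors: PriorConfig | None = None):
        self.data = data
        self.priors = priors or PriorConfig()
        s = data.space.slices()
        self._s = s
        self._delta_idx = np.array([s["delta_hb"].start, s["delta_sub"].start,
                                    s["delta_met"].start, s["delta_fao"].start])
        fixed = []
        for name in ("mu0", "gamma", "age", "phi_sex", "beta",
                     "delta_fao", "delta_hb", "delta_sub", "delta_met"):
            fixed.extend(range(s[name].start, s[name].stop))
        self._fixed_idx = np.array(fixed)

    def expected_log_means(self, vec: np.ndarray) -> np.ndarray:
        """log expected observed mean per observation.

        Includes the source-bias terms and the trend offset carrying each
        survey from its anchor period to its actual field year (exact under
        the log-linear trend).
        """
        eta = self.data.X @ vec
        agg = self.data.W @ np.exp(eta)
        gamma = vec[self._s["gamma"].start]
        return np.log(agg) + self.data.B @ vec[self._delta_idx] + gamma * self.data.year_offset

    def __call__(self, vec: np.ndarray) -> float:
        d = self.data
        s = self._s
        log_sig_r = vec[s["log_sigma_region"]][0]
        log_sig_c = vec[s["log_sigma_country"]][0]
        log_tau = vec[s["log_tau"]][0]
        # keep the SDs in a numerically sane range
        if max(abs(log_sig_r), abs(log_sig_c), abs(log_tau)) > 20:
            return -np.inf
        tau2 = np.exp(2.0 * log_tau)

        mu = self.expected_log_means(vec)
        if not np.all(np.isfinite(mu)):
            return -np.inf
        v = d.se_rel2 + tau2
        resid = d.log_y - mu
        loglik = -0.5 * float(np.sum(resid ** 2 / v + np.log(2.0 * np.pi * v)))

        u_r = vec[s["u_region"]]
        u_c = vec[s["u_country"]]
        sig_r2 = np.exp(2.0 * log_sig_r)
        sig_c2 = np.exp(2.0 * log_sig_c)
        hier = (-0.5 * float(np.sum(u_r ** 2)) / sig_r2 - len(u_r) * log_sig_r
                - 0.5 * float(np.sum(u_c ** 2)) / sig_c2 - len(u_c) * log_sig_c)

        fx = vec[self._fixed_idx]
        prior = -0.5 * float(np.sum(fx ** 2)) / self.priors.fixed_sd ** 2
        # smoothness of the age curve: first differences shrunk toward zero
        age_free = vec[s["age"]]
        knots = np.concatenate([age_free, [-age_free.sum()]])
        prior += -0.5 * float(np.sum(np.diff(knots) ** 2)) / self.priors.age_smooth_sd ** 2
        # Half-Normal(scale) on sigma with log-parameterization Jacobian (+log sigma)
        for ls in (log_sig_r, log_sig_c, log_tau):
            prior += -0.5 * np.exp(2.0 * ls) / self.priors.sd_scale ** 2 + ls
        return loglik + hier + prior


@dataclass
class PosteriorDraws:
    """Stratum x draw intake matrix; draw d is one coherent world."""

    strata: list[StratumKey]
    draws: np.ndarray  # S x n_draws

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[0] != len(self.strata):
            raise ValueError("draws must be (n_strata, n_draws)")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def index(self) -> dict[StratumKey, int]:
        return {k: i for i, k in enumerate(self.strata)}

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, k in enumerate(self.strata):
            for dnum, v in enumerate(self.draws[i]):
                recs.append({"country": k.country, "year": k.year, "age_band": k.age_band,
                             "sex": k.sex, "draw": dnum, "value": v})
        return pd.DataFrame(recs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorDraws":
        keys = df[["country", "year", "age_band", "sex"]].drop_duplicates()
        strata = [StratumKey(r.country, int(r.year), int(r.age_band), r.sex)
                  for r in keys.itertuples()]
        pivot = df.pivot_table(index=["country", "year", "age_band", "sex"],
                               columns="draw", values="value", sort=False)
        mat = np.vstack([pivot.loc[tuple(k)].to_numpy() for k in strata])
        return cls(strata=strata, draws=mat)


def posterior_draws(result: ChainResult, data: FitData, settings: MCMCSettings) -> PosteriorDraws:
    """Map retained chain states through the stratum predictor.

    Exactly ``settings.target_draws`` evenly thinned post-burn-in states are
    kept; draw ordering is shared across strata so draw-level arithmetic
    propagates uncertainty coherently.
    """
    retained = result.retained(settings)       # n_draws x dim
    draws = np.exp(data.X @ retained.T)        # S x n_draws
    return PosteriorDraws(strata=list(data.strata), draws=draws)


@dataclass
class FitResult:
    data: FitData
    chain: ChainResult
    settings: MCMCSettings
    draws: PosteriorDraws

    def param_draws(self, name: str) -> np.ndarray:
        """Retained draws of one parameter block (SDs returned on natural scale)."""
        retained = self.chain.retained(self.settings)
        s = self.data.space.slices()
        if name.startswith("log_"):
            return retained[:, s[name]].squeeze()
        if name in ("sigma_region", "sigma_country", "tau"):
            return np.exp(retained[:, s[f"log_{name}" if name == "tau" else f"log_{name}"]]).squeeze()
        block = retained[:, s[name]]
        return block.squeeze() if block.shape[1] == 1 else block

    def posterior_mean_params(self) -> ModelParams:
        retained = self.chain.retained(self.settings)
        return self.data.space.unpack(retained.mean(axis=0))


def initial_vector(data: FitData) -> np.ndarray:
    """Data-driven start: global intercept at the mean of the survey logs."""
    space = data.space
    vec = np.zeros(space.dim)
    s = space.slices()
    surveys = data.log_y[~data.is_fao]
    if len(surveys):
        vec[s["mu0"]] = surveys.mean()
    elif len(data.log_y):
        vec[s["mu0"]] = data.log_y.mean()
    else:
        vec[s["mu0"]] = np.log(50.0)  # no data: a generic adult intake scale
    vec[s["log_sigma_region"]] = np.log(0.3)
    vec[s["log_sigma_country"]] = np.log(0.2)
    vec[s["log_tau"]] = np.log(0.1)
    return vec


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; cheap at this dimension and posterior cost."""
    d = x.size
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            fij = f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            hess[i, j] = hess[j, i] = fij / (4 * h[i] * h[j])
    return hess


def map_estimate(logpost, x0: np.ndarray,
                 fixed_idx: Sequence[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Approximate posterior mode and Laplace covariance for chain initialisation.

    ``fixed_idx`` marks coordinates held at their ``x0`` values during the
    optimisation. The hierarchical SDs are held fixed this way: the joint
    density of a centered hierarchical model diverges as an SD and its random
    effects go to zero together, so an unconstrained optimum can run into the
    degenerate spike at sigma = 0 — profiling at an interior value yields a
    useful interior starting point instead. The covariance comes from an
    explicit finite-difference Hessian of the negative log posterior (BFGS's
    internal approximation is unreliable when its line search stops early),
    with eigenvalues clipped to keep the proposal positive-definite and
    bounded.
    """
    from scipy.optimize import minimize

    fixed_idx = np.asarray(fixed_idx if fixed_idx is not None else [], dtype=int)
    free_idx = np.setdiff1d(np.arange(x0.size), fixed_idx)

    def embed(v_free):
        v = x0.copy()
        v[free_idx] = v_free
        return v

    def objective(v):
        val = logpost(v)
        return -val if np.isfinite(val) else 1e12

    res = minimize(lambda vf: objective(embed(vf)), x0[free_idx],
                   method="BFGS", options={"maxiter": 500, "gtol": 1e-5})
    x_map = embed(res.x)
    if not np.isfinite(logpost(x_map)):
        x_map = x0

    neg_hess = _numerical_hessian(objective, x_map)
    neg_hess = 0.5 * (neg_hess + neg_hess.T)
    evals, evecs = np.linalg.eigh(neg_hess)
    # curvature floored at 1e-2 (marginal prior scale) so flat/indefinite
    # directions get a bounded, not exploding, proposal variance
    evals = np.clip(evals, 1e-2, None)
    cov = (evecs / evals) @ evecs.T
    return x_map, cov


def fit_food(std_obs: pd.DataFrame, fao: pd.DataFrame, covariates: pd.DataFrame,
             populations: pd.DataFrame, grid: AgeGrid, food: str,
             settings: MCMCSettings | None = None, priors: PriorConfig | None = None,
             fao_mode: str = "likelihood") -> FitResult:
    """End-to-end fit of one food: assemble data, run the chain, map draws."""
    settings = settings or MCMCSettings()
    data = build_fit_data(std_obs, fao, covariates, populations, grid, food, fao_mode=fao_mode)
    logpost = LogPosterior(data, priors)
    s = data.space.slices()
    sd_idx = [s["log_sigma_region"].start, s["log_sigma_country"].start, s["log_tau"].start]
    x_map, laplace_cov = map_estimate(logpost, initial_vector(data), fixed_idx=sd_idx)
    result = adaptive_metropolis(logpost, x_map, settings, initial_cov=laplace_cov)
    logger.info("fit %s: %d obs, %d strata, acceptance %.3f",
                food, data.n_obs, len(data.strata), result.acceptance_rate)
    return FitResult(data=data, chain=result, settings=settings,
                     draws=posterior_draws(result, data, settings))
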