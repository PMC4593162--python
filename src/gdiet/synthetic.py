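"""Synthetic evidence base with known truth.

Generates a miniature world — regions, countries, populations, true intake
surfaces — together with the two kinds of evidence the estimation model
consumes: grouped dietary survey observations (with method, representativeness
and metric biases plus sampling noise) and complete FAO-style availability
series that multiplicatively overestimate true intake. Everything is
deterministic given one seed, so every downstream stage can be tested against
the planted truth.

True mean intake for food f in stratum (country c, age band a, sex s, year t)
is built on the natural-log scale::

    log theta = mu0_f + region_r(c) + country_c + agecurve_f(a)
                + phi_f * 1[s = F] + gamma_f * (t - 2000) / 10

Age curves are monotone non-decreasing for healthful foods and non-increasing
for harmful ones, mirroring the empirical pattern of more healthful intakes at
older ages. Intakes are strictly positive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import ANCHOR_YEARS, SEXES, AgeGrid, StratumKey

DEFAULT_FOODS = (
    "fruits",
    "vegetables",
    "nuts_seeds",
    "whole_grains",
    "seafood",
    "red_meats",
    "processed_meats",
)

HARMFUL_FOODS = frozenset({"red_meats", "processed_meats"})

#: Plausible 2000-era global mean intakes (g/day) used as generative intercepts.
BASE_INTAKE = {
    "fruits": 81.0,
    "vegetables": 209.0,
    "legumes": 60.0,
    "nuts_seeds": 9.0,
    "whole_grains": 38.0,
    "seafood": 28.0,
    "red_meats": 42.0,
    "processed_meats": 14.0,
}

from .standardize import METHOD_HOUSEHOLD, METHOD_INDIVIDUAL  # noqa: E402

#: The 14 diet-composition variables derived from food balance sheets, with
#: the planted 4-factor block structure (meats/animal fats; unsaturated fats,
#: whole grains, nuts, vegetables; fruits, legumes, nuts; sugars, stimulants,
#: saturated fats).
COMPOSITION_VARS = (
    "red_meats",
    "animal_fats",
    "pig_meats",
    "n3_pufa",
    "n6_pufa",
    "whole_grains",
    "nuts",
    "vegetables",
    "fruits",
    "legumes",
    "sugars",
    "stimulants",
    "saturated_fats",
    "seafood",
)

COMPOSITION_FACTOR_BLOCKS = (
    ("red_meats", "animal_fats", "pig_meats"),
    ("n3_pufa", "n6_pufa", "whole_grains", "nuts", "vegetables"),
    ("fruits", "legumes", "nuts"),
    ("sugars", "stimulants", "saturated_fats"),
)


@dataclass(frozen=True)
class SurveyPlan:
    """Sampling schedule for the synthetic survey corpus.

    ``p_survey`` is the probability that any given country-year fields a
    survey; the fractions split surveys by instrument (household budget vs
    individual-level), coverage (subnational vs nationally representative)
    and metric (secondary vs primary).
    """

    p_survey: float = 0.10
    frac_household: float = 0.33
    frac_subnational: float = 0.17
    frac_secondary: float = 0.20

    def __post_init__(self) -> None:
        for name in ("p_survey", "frac_household", "frac_subnational", "frac_secondary"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions of the synthetic world.

    Defaults give 4 regions x 5 countries over 1980-2010, 8 age bands x 2
    sexes (16 strata per country-year) and 7 foods — small enough for
    minutes-scale fitting while keeping every structural feature the
    estimation model assumes.
    """

    n_regions: int = 4
    countries_per_region: int = 5
    years: tuple[int, int] = (1980, 2010)
    age_grid: AgeGrid = field(default_factory=AgeGrid)
    foods: tuple[str, ...] = DEFAULT_FOODS
    rng_seed: int = 20100
    survey_plan: SurveyPlan = field(default_factory=SurveyPlan)
    fao_bias_range: tuple[float, float] = (1.1, 1.8)
    # log-scale heterogeneity / noise
    region_sd: float = 0.30
    country_sd: float = 0.20
    fao_noise_sd: float = 0.10
    nonsampling_sd: float = 0.05
    survey_cv: float = 0.50           # within-person CV -> SE = cv*mean/sqrt(n)
    # structural effects (log scale)
    age_amplitude: float = 0.30       # total rise/fall of the age curve
    trend_per_decade: float = 0.05    # signed by food direction
    sex_multiplier_healthful: float = 1.05
    sex_multiplier_harmful: float = 0.95
    sex_multipliers: Mapping[str, float] | None = None
    # planted survey-source biases (multiplicative)
    bias_household: float = 1.2
    bias_subnational: float = 0.9
    bias_secondary: float = 1.1
    # individual-record generator
    energy_mean: float = 2000.0
    energy_sd: float = 400.0
    intake_energy_corr: float = 0.3

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.countries_per_region < 1:
            raise ValueError("counts must be >= 1")
        if self.years[0] > self.years[1]:
            raise ValueError("years range must be increasing")
        lo, hi = self.fao_bias_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("fao_bias_range must be a positive interval")
        for name in ("region_sd", "country_sd", "fao_noise_sd", "nonsampling_sd",
                     "survey_cv", "age_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def sex_multiplier(self, food: str) -> float:
        if self.sex_multipliers is not None and food in self.sex_multipliers:
            return float(self.sex_multipliers[food])
        return self.sex_multiplier_harmful if food in HARMFUL_FOODS else self.sex_multiplier_healthful

    def food_sign(self, food: str) -> float:
        return -1.0 if food in HARMFUL_FOODS else 1.0


@dataclass
class WorldTruth:
    """The planted truth: everything the estimation pipeline tries to recover."""

    config: WorldConfig
    regions: list[str]
    countries: list[str]
    region_assignment: dict[str, str]
    mu0: dict[str, float]
    region_eff: dict[str, dict[str, float]]
    country_eff: dict[str, dict[str, float]]
    age_curve: dict[str, np.ndarray]          # centered, monotone per direction
    sex_eff: dict[str, float]                 # log female offset
    trend: dict[str, float]                   # log change per decade
    true_fao_multiplier: dict[str, float]     # country -> availability/intake
    true_bias: dict[str, float]               # flag -> multiplicative bias
    populations: pd.DataFrame                 # country, age_band, sex, population
    income: pd.DataFrame                      # country, year, income
    education: pd.DataFrame                   # country, year, education_years

    def log_theta(self, food: str, country: str, age_band: int, sex: str, year: float) -> float:
        region = self.region_assignment[country]
        return (
            self.mu0[food]
            + self.region_eff[food][region]
            + self.country_eff[food][country]
            + float(self.age_curve[food][age_band])
            + (self.sex_eff[food] if sex == "F" else 0.0)
            + self.trend[food] * (year - 2000.0) / 10.0
        )

    def theta(self, food: str, country: str, age_band: int, sex: str, year: float) -> float:
        return float(np.exp(self.log_theta(food, country, age_band, sex, year)))

    def true_theta(self, food: str) -> dict[StratumKey, float]:
        """Truth at the anchor periods, keyed by stratum."""
        grid = self.config.age_grid
        out: dict[StratumKey, float] = {}
        for c in self.countries:
            for year in ANCHOR_YEARS:
                for a in range(grid.n_bands):
                    for s in SEXES:
                        out[StratumKey(c, year, a, s)] = self.theta(food, c, a, s, year)
        return out

    def stratum_population(self, country: str, age_band: int, sex: str) -> float:
        pop = self.populations
        row = pop[(pop.country == country) & (pop.age_band == age_band) & (pop.sex == sex)]
        return float(row.population.iloc[0])

    def _pop_slice(self, country: str) -> pd.DataFrame:
        return self.populations[self.populations.country == country]

    def population_mean(self, food: str, country: str, year: float,
                        age_lo: float | None = None, age_hi: float | None = None,
                        sexes: Sequence[str] = SEXES) -> float:
        """Population-weighted mean true intake over an age range and sexes."""
        grid = self.config.age_grid
        if age_lo is None:
            age_lo = grid.edges[0]
        if age_hi is None:
            age_hi = grid.upper
        pop = self._pop_slice(country)
        total = 0.0
        wsum = 0.0
        for _, row in pop.iterrows():
            if row.sex not in sexes:
                continue
            frac = grid.overlap_fraction(int(row.age_band), age_lo, age_hi)
            if frac <= 0:
                continue
            w = row.population * frac
            total += w * self.theta(food, country, int(row.age_band), row.sex, year)
            wsum += w
        if wsum == 0:
            raise ValueError(f"age range [{age_lo}, {age_hi}) overlaps no populated band in {country}")
        return total / wsum


def _monotone_age_curve(rng: np.random.Generator, n_bands: int, amplitude: float, sign: float) -> np.ndarray:
    """Centered, monotone (per sign) piecewise-constant age curve on log scale."""
    if n_bands == 1:
        return np.zeros(1)
    inc = rng.uniform(0.2, 1.0, size=n_bands - 1)
    curve = np.concatenate([[0.0], np.cumsum(inc)])
    if curve[-1] > 0:
        curve = curve / curve[-1] * amplitude
    curve = sign * curve
    return curve - curve.mean()


def generate_world(config: WorldConfig) -> WorldTruth:
    """Draw a world truth surface; deterministic given ``config.rng_seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), 0]))
    grid = config.age_grid

    regions = [f"R{r + 1}" for r in range(config.n_regions)]
    countries: list[str] = []
    region_assignment: dict[str, str] = {}
    for r, region in enumerate(regions):
        for c in range(config.countries_per_region):
            name = f"{region}C{c + 1}"
            countries.append(name)
            region_assignment[name] = region

    mu0, region_eff, country_eff, age_curve, sex_eff, trend = {}, {}, {}, {}, {}, {}
    for food in config.foods:
        base = BASE_INTAKE.get(food, 50.0)
        mu0[food] = float(np.log(base))
        region_eff[food] = {g: float(rng.normal(0.0, config.region_sd)) for g in regions}
        country_eff[food] = {c: float(rng.normal(0.0, config.country_sd)) for c in countries}
        age_curve[food] = _monotone_age_curve(rng, grid.n_bands, config.age_amplitude,
                                              config.food_sign(food))
        sex_eff[food] = float(np.log(config.sex_multiplier(food)))
        trend[food] = config.trend_per_decade * config.food_sign(food)

    lo, hi = config.fao_bias_range
    true_fao_multiplier = {c: float(rng.uniform(lo, hi)) for c in countries}
    true_bias = {
        "household_budget": config.bias_household,
        "subnational": config.bias_subnational,
        "secondary": config.bias_secondary,
    }

    # Static adult populations: country size lognormal, age shares declining,
    # even sex split. One adult cohort per (country, band, sex).
    age_share = np.exp(-0.25 * np.arange(grid.n_bands))
    age_share = age_share / age_share.sum()
    pop_rows = []
    for c in countries:
        size = float(rng.lognormal(np.log(5e6), 0.8))
        for a in range(grid.n_bands):
            for s in SEXES:
                pop_rows.append({"country": c, "region": region_assignment[c],
                                 "age_band": a, "sex": s,
                                 "population": round(size * age_share[a] * 0.5)})
    populations = pd.DataFrame(pop_rows)

    years = np.arange(config.years[0], config.years[1] + 1)
    inc_rows, edu_rows = [], []
    for c in countries:
        inc0 = float(rng.lognormal(np.log(8000.0), 0.9))
        growth = float(rng.normal(0.02, 0.01))
        edu0 = float(rng.uniform(4.0, 12.0))
        edu_slope = float(rng.uniform(0.02, 0.10))
        for i, y in enumerate(years):
            inc_rows.append({"country": c, "year": int(y),
                             "income": inc0 * float(np.exp(growth * i + rng.normal(0.0, 0.02)))})
            edu_rows.append({"country": c, "year": int(y),
                             "education_years": edu0 + edu_slope * i})

    return WorldTruth(
        config=config, regions=regions, countries=countries,
        region_assignment=region_assignment, mu0=mu0, region_eff=region_eff,
        country_eff=country_eff, age_curve=age_curve, sex_eff=sex_eff, trend=trend,
        true_fao_multiplier=true_fao_multiplier, true_bias=true_bias,
        populations=populations, income=pd.DataFrame(inc_rows),
        education=pd.DataFrame(edu_rows),
    )


def _survey_age_ranges(grid: AgeGrid) -> list[tuple[float, float]]:
    """Coarse reporting ranges: adjacent bands paired (typical survey tables)."""
    bands = list(range(grid.n_bands))
    ranges = []
    for i in range(0, len(bands), 2):
        chunk = bands[i:i + 2]
        lo = grid.nominal_bounds(chunk[0])[0]
        hi = grid.nominal_bounds(chunk[-1])[1]
        ranges.append((lo, hi))
    return ranges


def simulate_surveys(world: WorldTruth, config: WorldConfig | None = None) -> pd.DataFrame:
    """Simulate the grouped survey corpus over the configured year range.

    Individual-level surveys report age-sex specific rows over coarse age
    ranges; household-budget surveys report a single all-adult, both-sex row.
    Each observed mean is the population-weighted truth over its age range,
    times the product of applicable planted biases, times lognormal sampling
    plus non-sampling noise. The reported SE is cv*mean/sqrt(n).
    """
    config = config or world.config
    rng = np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), 1]))
    grid = config.age_grid
    plan = config.survey_plan
    years = range(config.years[0], config.years[1] + 1)

    rows = []
    sid = 0
    for country in world.countries:
        for year in years:
            if rng.random() >= plan.p_survey:
                continue
            sid += 1
            survey_id = f"S{sid:04d}"
            household = rng.random() < plan.frac_household
            subnational = rng.random() < plan.frac_subnational
            secondary = (not household) and rng.random() < plan.frac_secondary
            bias = 1.0
            if household:
                bias *= world.true_bias["household_budget"]
            if subnational:
                bias *= world.true_bias["subnational"]
            if secondary:
                bias *= world.true_bias["secondary"]
            if household:
                cells = [(grid.edges[0], grid.upper, "both")]
            else:
                cells = [(lo, hi, s) for lo, hi in _survey_age_ranges(grid) for s in SEXES]
            for food in config.foods:
                for lo, hi, sex in cells:
                    sexes = SEXES if sex == "both" else (sex,)
                    expect = world.population_mean(food, country, year, lo, hi, sexes) * bias
                    n = int(rng.integers(200, 800)) if sex != "both" else int(rng.integers(1000, 5000))
                    sd_log = np.sqrt(config.survey_cv ** 2 / n + config.nonsampling_sd ** 2)
                    observed = expect * float(np.exp(rng.normal(0.0, sd_log)))
                    rows.append({
                        "survey_id": survey_id, "country": country, "year": int(year),
                        "age_lo": lo, "age_hi": hi, "sex": sex,
                        "mean_intake": observed,
                        "se": config.survey_cv * observed / np.sqrt(n), "n": n,
                        "representative": 0 if subnational else 1,
                        "method": METHOD_HOUSEHOLD if household else METHOD_INDIVIDUAL,
                        "metric": "secondary" if secondary else "primary",
                        "food": food,
                    })
    columns = ["survey_id", "country", "year", "age_lo", "age_hi", "sex", "mean_intake",
               "se", "n", "representative", "method", "metric", "food"]
    return pd.DataFrame(rows, columns=columns)


def _composition_matrix(rng: np.random.Generator, n_rows: int, noise_sd: float = 0.15) -> np.ndarray:
    """14 positive composition variables driven by 4 latent factors (planted blocks)."""
    k = len(COMPOSITION_FACTOR_BLOCKS)
    loadings = np.zeros((len(COMPOSITION_VARS), k))
    for j, block in enumerate(COMPOSITION_FACTOR_BLOCKS):
        for name in block:
            loadings[COMPOSITION_VARS.index(name), j] = 1.0
    factors = rng.normal(0.0, 1.0, size=(n_rows, k))
    base = rng.uniform(0.5, 2.0, size=len(COMPOSITION_VARS))
    logs = np.log(base)[None, :] + 0.5 * factors @ loadings.T
    logs = logs + rng.normal(0.0, noise_sd, size=logs.shape)
    return np.exp(logs)  # percent of total kcal, strictly positive


def simulate_fao(world: WorldTruth, config: WorldConfig | None = None) -> pd.DataFrame:
    """Simulate complete FAO-style availability for every country-year.

    Availability = all-adult population-mean true intake x the country's
    multiplicative overestimation factor x lognormal noise; the 14
    composition variables carry a planted 4-factor correlation structure.
    """
    config = config or world.config
    rng = np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), 2]))
    years = list(range(config.years[0], config.years[1] + 1))
    index = [(c, y) for c in world.countries for y in years]
    comp = _composition_matrix(rng, len(index))

    rows = []
    for i, (country, year) in enumerate(index):
        m = world.true_fao_multiplier[country]
        comp_cols = {f"comp_{j + 1}": comp[i, j] for j in range(len(COMPOSITION_VARS))}
        for food in config.foods:
            avail = (world.population_mean(food, country, year) * m
                     * float(np.exp(rng.normal(0.0, config.fao_noise_sd))))
            rows.append({"country": country, "year": int(year), "food": food,
                         "availability_g_day": avail, **comp_cols})
    return pd.DataFrame(rows)


def simulate_individuals(world: WorldTruth, stratum: StratumKey, n: int, food: str = "fruits",
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Individual intake/energy records for one stratum.

    Energy is Normal(energy_mean, energy_sd) truncated above 500 kcal; intake
    is linear in energy with the configured intake-energy correlation around
    the stratum's true mean at the reference energy.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    config = world.config
    if stratum.country not in world.countries or not 0 <= stratum.age_band < config.age_grid.n_bands:
        raise KeyError(f"unknown stratum {stratum}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), 3]))
    if n == 0:
        return pd.DataFrame(columns=["intake", "energy"])
    theta = world.theta(food, stratum.country, stratum.age_band, stratum.sex, stratum.year)
    energy = rng.normal(config.energy_mean, config.energy_sd, size=n)
    energy = np.clip(energy, 500.0, None)
    sd_intake = config.survey_cv * theta
    rho = config.intake_energy_corr
    slope = rho * sd_intake / config.energy_sd if config.energy_sd > 0 else 0.0
    resid_sd = sd_intake * np.sqrt(max(1.0 - rho ** 2, 0.0))
    intake = theta + slope * (energy - config.energy_mean) + rng.normal(0.0, resid_sd, size=n)
    intake = np.clip(intake, 0.0, None)
    return pd.DataFrame({"intake": intake, "energy": energy})


# ---------------------------------------------------------------------------
# table writers (all plain CSV; one run directory per world)

def world_truth_table(world: WorldTruth) -> pd.DataFrame:
    rows = []
    for food in world.config.foods:
        for key, value in world.true_theta(food).items():
            rows.append({"food": food, "country": key.country, "year": key.year,
                         "age_band": key.age_band, "sex": key.sex, "theta_true": value})
    return pd.DataFrame(rows)


def populations_table(world: WorldTruth) -> pd.DataFrame:
    rows = []
    for year in ANCHOR_YEARS:
        block = world.populations.copy()
        block.insert(1, "year", year)
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def raw_covariates_table(world: WorldTruth) -> pd.DataFrame:
    return world.income.merge(world.education, on=["country", "year"])


def write_world(world: WorldTruth, outdir) -> dict[str, str]:
    """Write world_truth/surveys/fao/populations/covariates CSVs; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    tables = {
        "world_truth.csv": world_truth_table(world),
        "surveys.csv": simulate_surveys(world),
        "fao.csv": simulate_fao(world),
        "populations.csv": populations_table(world),
        "covariates.csv": raw_covariates_table(world),
    }
    paths = {}
    for name, df in tables.items():
        path = os.path.join(outdir, name)
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
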