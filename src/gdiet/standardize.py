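"""Survey ingestion and standardisation.

Energy-adjusts intakes to a 2000 kcal/day reference via the residual method,
assigns calendar years to the two anchor periods (1990, 2010), and maps
grouped age-range observations onto model strata with population weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import SEXES, AgeGrid, StratumKey

logger = logging.getLogger(__name__)

REFERENCE_ENERGY = 2000.0
PERIOD_BOUNDARY = 1997

METHOD_INDIVIDUAL = "individual_recall_record_ffq"
METHOD_HOUSEHOLD = "household_budget"

SURVEY_COLUMNS = ["survey_id", "country", "year", "age_lo", "age_hi", "sex",
                  "mean_intake", "se", "n", "representative", "method", "metric", "food"]


@dataclass(frozen=True)
class SurveyObservation:
    """One grouped survey datum (already energy-adjusted, g/day)."""

    survey_id: str
    country: str
    year: int
    age_lo: float
    age_hi: float
    sex: str  # F, M or both
    mean_intake: float
    se: float
    n: int
    representative: bool
    method: str
    metric: str
    food: str = ""

    def __post_init__(self) -> None:
        if self.mean_intake < 0:
            raise ValueError("mean_intake must be >= 0")
        if self.age_lo >= self.age_hi:
            raise ValueError("age_lo must be < age_hi")
        if self.se <= 0 and self.n <= 0:
            raise ValueError("need a positive se or a sample size")
        if self.sex not in ("F", "M", "both"):
            raise ValueError(f"bad sex flag {self.sex!r}")


def energy_adjust_residual(intake: Sequence[float], energy: Sequence[float],
                           reference_energy: float = REFERENCE_ENERGY) -> np.ndarray:
    """Residual-method energy adjustment of individual intakes.

    Each adjusted intake is the residual from the least-squares fit of intake
    on total energy, plus the fitted intake at the reference energy. The
    adjusted values are uncorrelated with energy and have mean equal to the
    fitted value at the reference. With fewer than 3 records or constant
    energy the regression is degenerate and the function falls back to ratio
    adjustment (with a warning).
    """
    intake = np.asarray(intake, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if intake.shape != energy.shape:
        raise ValueError("intake and energy must have the same length")
    if np.any(energy <= 0):
        raise ValueError("energy must be positive")
    if intake.size < 3 or np.ptp(energy) == 0:
        warnings.warn("residual method degenerate (n < 3 or constant energy); "
                      "falling back to ratio adjustment", stacklevel=2)
        return np.array([energy_adjust_ratio(x, e, reference_energy)
                         for x, e in zip(intake, energy)])
    X = np.column_stack([np.ones_like(energy), energy])
    coef, *_ = np.linalg.lstsq(X, intake, rcond=None)
    fitted_ref = coef[0] + coef[1] * reference_energy
    residuals = intake - X @ coef
    return residuals + fitted_ref


def energy_adjust_ratio(mean_intake: float, mean_energy: float,
                        reference_energy: float = REFERENCE_ENERGY) -> float:
    """Proportional energy adjustment for summary-level (e.g. household) data."""
    if mean_energy <= 0:
        raise ValueError("mean_energy must be positive")
    return mean_intake * reference_energy / mean_energy


def assign_period(year: int) -> tuple[int, ...]:
    """Map a survey year to its anchor period(s).

    Surveys from 1980-1996 inform 1990, 1998-2010 inform 2010, and the
    boundary year 1997 lies in both spans so it contributes to both anchors.
    """
    if not 1980 <= year <= 2010:
        raise ValueError(f"survey year {year} outside 1980-2010")
    if year < PERIOD_BOUNDARY:
        return (1990,)
    if year > PERIOD_BOUNDARY:
        return (2010,)
    return (1990, 2010)


def map_to_strata(obs: SurveyObservation, grid: AgeGrid,
                  populations: Mapping[tuple[int, str], float],
                  period: int | None = None) -> list[tuple[StratumKey, float]]:
    """Population weights of the strata an observation averages over.

    ``populations`` maps (age_band, sex) to adult counts for the
    observation's country. Partial band overlap uses linear-in-age
    interpolation of the band population. ``sex='both'`` expands over both
    sexes with population weights; weights always sum to 1.
    """
    if period is None:
        periods = assign_period(obs.year)
        if len(periods) > 1:
            raise ValueError(f"survey year {obs.year} maps to both periods; pass `period`")
        period = periods[0]
    sexes = SEXES if obs.sex == "both" else (obs.sex,)
    pairs: list[tuple[StratumKey, float]] = []
    for band in range(grid.n_bands):
        frac = grid.overlap_fraction(band, obs.age_lo, obs.age_hi)
        if frac <= 0:
            continue
        for sex in sexes:
            w = populations[(band, sex)] * frac
            if w > 0:
                pairs.append((StratumKey(obs.country, period, band, sex), w))
    total = sum(w for _, w in pairs)
    if total <= 0:
        raise ValueError(f"observation {obs.survey_id} ({obs.age_lo}-{obs.age_hi}, "
                         f"sex={obs.sex}) overlaps no populated stratum")
    return [(key, w / total) for key, w in pairs]


def read_surveys(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"surveys table missing columns {sorted(missing)}")
    return df


def write_surveys(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=SURVEY_COLUMNS)


def standardize_surveys(surveys: pd.DataFrame) -> pd.DataFrame:
    """Expand surveys into per-period standardized observations.

    Adds a ``period`` column (1997 surveys are duplicated into both periods)
    and drops rows with non-positive means, which the log-scale likelihood
    cannot use (logged as a warning).
    """
    rows = []
    n_dropped = 0
    for _, row in surveys.iterrows():
        if row.mean_intake <= 0:
            n_dropped += 1
            continue
        for period in assign_period(int(row.year)):
            out = row.to_dict()
            out["period"] = period
            rows.append(out)
    if n_dropped:
        logger.warning("dropped %d observations with non-positive mean intake", n_dropped)
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS + ["period"])


def observation_from_row(row) -> SurveyObservation:
    return SurveyObservation(
        survey_id=str(row["survey_id"]), country=str(row["country"]), year=int(row["year"]),
        age_lo=float(row["age_lo"]), age_hi=float(row["age_hi"]), sex=str(row["sex"]),
        mean_intake=float(row["mean_intake"]), se=float(row["se"]), n=int(row["n"]),
        representative=bool(int(row["representative"])), method=str(row["method"]),
        metric=str(row["metric"]), food=str(row.get("food", "")),
    )
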