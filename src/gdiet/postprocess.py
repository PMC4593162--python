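"""Draw-level summarisation and headline accounting.

All arithmetic (aggregation, differences, vegetable+legume summation) happens
per draw index before summarising, so uncertainty propagates through every
derived quantity. Point estimates are means over draws; 95% uncertainty
intervals are the empirical 2.5th and 97.5th centiles with linear
interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import SEXES, StratumKey
from .model import PosteriorDraws

MIN_DRAWS = 40
DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class ExposureEstimate:
    """Mean and 95% UI of one exposure (or draw-level derived quantity)."""

    label: str
    mean: float
    ui_lo: float
    ui_hi: float
    n_draws: int

    def __post_init__(self) -> None:
        if self.ui_lo > self.ui_hi:
            raise ValueError("ui_lo must be <= ui_hi")

    @property
    def significant(self) -> bool:
        """UI excludes zero (the draw-level notion of a certain change)."""
        return self.ui_lo > 0 or self.ui_hi < 0


@dataclass(frozen=True)
class OptimalIntake:
    """Recommended consumption level with its plausible spread.

    ``servings`` x ``serving_g`` gives the serving-scale amount; the SD is 10%
    of the mean on the serving scale. ``direction`` is 'protective' (attain by
    intake >= threshold) or 'harmful' (attain by intake <= threshold);
    ``unit`` is 'g/day' or 'g/week'.
    """

    food: str
    servings: float
    serving_g: float
    mean: float
    unit: str
    direction: str
    threshold: float | None = None

    @property
    def sd(self) -> float:
        return 0.1 * self.servings * self.serving_g

    @property
    def attain_threshold(self) -> float:
        return self.mean if self.threshold is None else self.threshold


#: Optimal population intakes used for the attainment accounting.
OPTIMAL_INTAKES = {
    "fruits": OptimalIntake("fruits", 3.0, 100.0, 300.0, "g/day", "protective"),
    "vegetables": OptimalIntake("vegetables", 4.0, 100.0, 400.0, "g/day", "protective"),
    "nuts_seeds": OptimalIntake("nuts_seeds", 4.0, 28.35, 113.4, "g/week", "protective"),
    "whole_grains": OptimalIntake("whole_grains", 2.5, 50.0, 100.0, "g/day", "protective"),
    "seafood": OptimalIntake("seafood", 3.5, 100.0, 350.0, "g/week", "protective"),
    "red_meats": OptimalIntake("red_meats", 1.0, 100.0, 100.0, "g/week", "harmful"),
    "processed_meats": OptimalIntake("processed_meats", 0.0, 50.0, 0.0, "g/week", "harmful"),
    # secondary processed-meat threshold: at most one 50 g serving per week
    "processed_meats_1swk": OptimalIntake("processed_meats", 1.0, 50.0, 50.0, "g/week", "harmful"),
}


def _centiles(draws: np.ndarray, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
    a, b = np.percentile(draws, [lo, hi], method="linear")
    return float(a), float(b)


def summarize_draws(draws: np.ndarray, label: str = "") -> ExposureEstimate:
    """Mean and 95% UI of one draw vector."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws to summarise, got {draws.size}")
    lo, hi = _centiles(draws)
    return ExposureEstimate(label=label, mean=float(draws.mean()), ui_lo=lo, ui_hi=hi,
                            n_draws=draws.size)


def summarize(draws: PosteriorDraws) -> list[ExposureEstimate]:
    """Per-stratum estimates from a stratum x draw matrix."""
    return [summarize_draws(draws.draws[i], label="|".join(map(str, k)))
            for i, k in enumerate(draws.strata)]


def summarize_frame(draws: PosteriorDraws) -> pd.DataFrame:
    rows = []
    for i, k in enumerate(draws.strata):
        est = summarize_draws(draws.draws[i])
        rows.append({"country": k.country, "year": k.year, "age_band": k.age_band,
                     "sex": k.sex, "mean": est.mean, "ui_lo": est.ui_lo, "ui_hi": est.ui_hi,
                     "unit": "g/day"})
    return pd.DataFrame(rows)


def _weights_for(draws: PosteriorDraws, populations: Mapping[StratumKey, float]) -> np.ndarray:
    w = np.empty(len(draws.strata))
    for i, k in enumerate(draws.strata):
        if k not in populations:
            raise KeyError(f"missing population for stratum {k}")
        w[i] = populations[k]
    return w


def aggregate(draws: PosteriorDraws, populations: Mapping[StratumKey, float],
              grouping: Mapping[StratumKey, str] | str = "global") -> PosteriorDraws:
    """Population-weighted aggregation at the draw level.

    ``grouping`` maps each stratum to a group label (or the single label
    'global'/'country'/... for one-group aggregation via a string, where
    'country' groups by country). Aggregation is associative: strata-to-global
    equals country-to-global of country aggregates.
    """
    if isinstance(grouping, str):
        if grouping == "global":
            labels = {k: "global" for k in draws.strata}
        elif grouping == "country":
            labels = {k: k.country for k in draws.strata}
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
    else:
        labels = {k: grouping[k] for k in draws.strata}

    w = _weights_for(draws, populations)
    groups = sorted(set(labels.values()))
    mats, keys = [], []
    for g in groups:
        idx = [i for i, k in enumerate(draws.strata) if labels[k] == g]
        wg = w[idx]
        if wg.sum() <= 0:
            raise ValueError(f"group {g} has zero population")
        mats.append((wg / wg.sum()) @ draws.draws[idx])
        year = draws.strata[idx[0]].year
        keys.append(StratumKey(country=g, year=year, age_band=-1, sex="all"))
    return PosteriorDraws(strata=keys, draws=np.vstack(mats))


def combine_vegetables_legumes(veg: PosteriorDraws, leg: PosteriorDraws) -> PosteriorDraws:
    """Element-wise draw sum of separately estimated vegetables and legumes."""
    if veg.strata != leg.strata or veg.n_draws != leg.n_draws:
        raise ValueError("vegetable and legume draws must share strata and draw count")
    return PosteriorDraws(strata=list(veg.strata), draws=veg.draws + leg.draws)


def change_between(draws_a: PosteriorDraws, draws_b: PosteriorDraws
                   ) -> tuple[list[ExposureEstimate], list[ExposureEstimate]]:
    """Draw-level absolute (b - a) and relative (b/a - 1) changes per stratum.

    Draws of a equal to zero make the relative change undefined for that draw;
    those draws are dropped from the relative summary with a warning.
    """
    import warnings

    if [k._replace(year=0) for k in draws_a.strata] != [k._replace(year=0) for k in draws_b.strata]:
        raise ValueError("change_between needs matching strata")
    if draws_a.n_draws != draws_b.n_draws:
        raise ValueError("change_between needs matching draw counts")
    abs_out, rel_out = [], []
    for i, k in enumerate(draws_a.strata):
        a, b = draws_a.draws[i], draws_b.draws[i]
        label = "|".join(map(str, k))
        abs_out.append(summarize_draws(b - a, label=label))
        ok = a != 0
        if not ok.all():
            warnings.warn(f"{(~ok).sum()} zero draws in stratum {k}; relative change "
                          "summarised over the remaining draws", stacklevel=2)
        rel_out.append(summarize_draws(b[ok] / a[ok] - 1.0, label=label))
    return abs_out, rel_out


def to_weekly(value_g_day: float) -> float:
    return value_g_day * DAYS_PER_WEEK


def attainment(country_means: Mapping[str, float], optimal: OptimalIntake,
               adult_populations: Mapping[str, float],
               estimate_unit: str = "g/day") -> tuple[int, float]:
    """Countries meeting the optimal level and their share of the adult population.

    ``country_means`` are all-adult mean intakes per country in
    ``estimate_unit``; comparisons are inclusive (>= for protective foods,
    <= for harmful), and units are converted explicitly (x7 between g/day and
    g/week).
    """
    if estimate_unit not in ("g/day", "g/week"):
        raise ValueError(f"unknown unit {estimate_unit!r}")
    thr = optimal.attain_threshold
    missing = set(country_means) - set(adult_populations)
    if missing:
        raise KeyError(f"missing adult populations for {sorted(missing)}")

    def in_threshold_unit(v: float) -> float:
        if estimate_unit == optimal.unit:
            return v
        return to_weekly(v) if optimal.unit == "g/week" else v / DAYS_PER_WEEK

    if optimal.direction == "protective":
        winners = [c for c, v in country_means.items() if in_threshold_unit(v) >= thr]
    else:
        winners = [c for c, v in country_means.items() if in_threshold_unit(v) <= thr]
    total = sum(adult_populations[c] for c in country_means)
    share = sum(adult_populations[c] for c in winners) / total if total > 0 else 0.0
    return len(winners), share


def fold_variation(means: Sequence[float], rounding: str = "one_decimal") -> float:
    """max/min of a set of positive means, rounded per the table convention."""
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("fold variation undefined for non-positive means")
    ratio = float(means.max() / means.min())
    if rounding == "integer":
        return float(round(ratio))
    if rounding == "one_decimal":
        return round(ratio, 1)
    raise ValueError(f"unknown rounding {rounding!r}")


def sex_contrast(draws: PosteriorDraws, populations: Mapping[StratumKey, float]
                 ) -> dict[str, ExposureEstimate]:
    """Per-country female minus male all-age mean difference (g/day), with UI."""
    w = _weights_for(draws, populations)
    out = {}
    for country in sorted({k.country for k in draws.strata}):
        per_sex = {}
        for sex in SEXES:
            idx = [i for i, k in enumerate(draws.strata)
                   if k.country == country and k.sex == sex]
            if not idx:
                raise ValueError(f"missing sex {sex} for country {country}")
            wg = w[idx]
            per_sex[sex] = (wg / wg.sum()) @ draws.draws[idx]
        out[country] = summarize_draws(per_sex["F"] - per_sex["M"], label=country)
    return out
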