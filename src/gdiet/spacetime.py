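"""Expand anchor-period draws into a full annual series.

Per draw index, log-linear interpolation between the 1990 and 2010 anchors,
plus a covariate tilt: the deviation of the country's log lag-distributed
income and education from their 1990-2010 chord, scaled by the fitted
covariate coefficients. Anchor years reproduce the inputs exactly, and the
tilt vanishes when covariates move linearly between the anchors.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .model import PosteriorDraws


def interpolate_series(draws_1990: PosteriorDraws, draws_2010: PosteriorDraws,
                       covariates: pd.DataFrame | None = None,
                       betas: Mapping[str, float] | None = None,
                       cov_sds: Mapping[str, float] | None = None,
                       years: range = range(1990, 2011)) -> dict[int, PosteriorDraws]:
    """Annual stratum x draw intake matrices for every requested year.

    ``covariates`` (country, year, ldi, education) and ``betas`` (coefficients
    on the model's standardized scale, keyed 'ldi'/'education') activate the
    covariate tilt; with either omitted or constant covariates the result is
    pure log-linear (geometric) interpolation. ``cov_sds`` are the
    standardization SDs used at fit time, so raw covariate deviations can be
    put on the coefficient scale.
    """
    keys_a = [k._replace(year=0) for k in draws_1990.strata]
    keys_b = [k._replace(year=0) for k in draws_2010.strata]
    if keys_a != keys_b:
        raise ValueError("anchor draws must cover identical strata in the same order")
    if draws_1990.n_draws != draws_2010.n_draws:
        raise ValueError("anchor draws must have equal draw counts")

    log_a = np.log(draws_1990.draws)
    log_b = np.log(draws_2010.draws)
    y0, y1 = 1990, 2010

    tilts: dict[tuple[str, int], float] = {}
    if covariates is not None and betas:
        cov = covariates.set_index(["country", "year"]).sort_index()
        for country in {k.country for k in draws_1990.strata}:
            for year in years:
                t = 0.0
                w = (year - y0) / (y1 - y0)
                for name, beta in betas.items():
                    try:
                        x_t = float(cov.loc[(country, year), name])
                        x_0 = float(cov.loc[(country, y0), name])
                        x_1 = float(cov.loc[(country, y1), name])
                    except KeyError as err:
                        raise ValueError(f"missing covariate {name} for {country}-{year}") from err
                    chord = (1 - w) * x_0 + w * x_1
                    sd = float(cov_sds[name]) if cov_sds and name in cov_sds else 1.0
                    t += float(beta) * (x_t - chord) / sd
                tilts[(country, year)] = t

    out: dict[int, PosteriorDraws] = {}
    for year in years:
        w = (year - y0) / (y1 - y0)
        log_y = (1 - w) * log_a + w * log_b
        if tilts:
            shift = np.array([tilts.get((k.country, year), 0.0) for k in draws_1990.strata])
            log_y = log_y + shift[:, None]
        strata = [k._replace(year=year) for k in draws_1990.strata]
        if year == y0:
            mat = draws_1990.draws.copy()
        elif year == y1:
            mat = draws_2010.draws.copy()
        else:
            mat = np.exp(log_y)
        out[year] = PosteriorDraws(strata=strata, draws=mat)
    return out


def series_to_frame(series: dict[int, PosteriorDraws]) -> pd.DataFrame:
    """Long-format (country, year, age_band, sex, draw, value) table."""
    return pd.concat([d.to_frame() for _, d in sorted(series.items())], ignore_index=True)
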