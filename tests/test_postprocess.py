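"""Draw-level summarisation, aggregation and the headline accounting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gdiet.grids import StratumKey
from gdiet.model import PosteriorDraws
from gdiet.postprocess import (OPTIMAL_INTAKES, aggregate, attainment, change_between,
                               combine_vegetables_legumes, fold_variation, sex_contrast,
                               summarize_draws)


def make_draws(matrix, country="A", year=2010):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    strata = [StratumKey(country, year, i, "M") for i in range(matrix.shape[0])]
    return PosteriorDraws(strata=strata, draws=matrix)


class TestSummarize:
    def test_degenerate_draws(self):
        est = summarize_draws(np.full(1000, 81.3))
        assert (est.mean, est.ui_lo, est.ui_hi) == pytest.approx((81.3, 81.3, 81.3))

    def test_sorted_array_centile_oracle(self):
        draws = np.arange(1.0, 1001.0)
        est = summarize_draws(np.random.default_rng(0).permutation(draws))
        assert est.mean == pytest.approx(500.5)
        # oracle: linear interpolation between order statistics of the sorted
        # array at positions 2.5%*(n-1) and 97.5%*(n-1)
        srt = np.sort(draws)
        for got, q in [(est.ui_lo, 0.025), (est.ui_hi, 0.975)]:
            pos = q * (len(srt) - 1)
            k = int(np.floor(pos))
            want = srt[k] + (pos - k) * (srt[k + 1] - srt[k])
            assert got == pytest.approx(want, abs=1e-10)

    @given(st.floats(-50, 50))
    def test_shift_equivariance(self, c):
        rng = np.random.default_rng(12)
        draws = rng.gamma(5.0, 10.0, 500)
        base, shifted = summarize_draws(draws), summarize_draws(draws + c)
        assert shifted.mean == pytest.approx(base.mean + c, abs=1e-9)
        assert shifted.ui_lo == pytest.approx(base.ui_lo + c, abs=1e-9)
        assert shifted.ui_hi == pytest.approx(base.ui_hi + c, abs=1e-9)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="40"):
            summarize_draws(np.ones(39))


class TestAggregate:
    def test_equal_population_average(self):
        draws = make_draws([[10.0] * 50, [30.0] * 50])
        pops = {k: 100.0 for k in draws.strata}
        agg = aggregate(draws, pops, "global")
        assert agg.draws == pytest.approx(np.full((1, 50), 20.0))

    def test_single_stratum_identity(self):
        draws = make_draws([[7.0] * 50])
        agg = aggregate(draws, {draws.strata[0]: 5.0}, "global")
        assert agg.draws == pytest.approx(draws.draws)

    def test_brute_force_weighted_mean_oracle(self):
        rng = np.random.default_rng(5)
        mat = rng.lognormal(3, 0.5, size=(6, 80))
        draws = make_draws(mat)
        w = rng.integers(1, 500, 6).astype(float)
        pops = dict(zip(draws.strata, w))
        agg = aggregate(draws, pops, "global")
        want = (w / w.sum()) @ mat
        assert agg.draws[0] == pytest.approx(want, abs=1e-12)

    def test_two_stage_aggregation_is_associative(self):
        rng = np.random.default_rng(8)
        strata = [StratumKey(c, 2010, a, "M") for c in "ABCD" for a in range(4)]
        draws = PosteriorDraws(strata=strata, draws=rng.lognormal(4, 0.3, (16, 60)))
        pops = {k: float(rng.integers(10, 1000)) for k in strata}
        one_stage = aggregate(draws, pops, "global")
        by_country = aggregate(draws, pops, "country")
        country_pops = {k: sum(pops[s] for s in strata if s.country == k.country)
                        for k in by_country.strata}
        two_stage = aggregate(by_country, country_pops, "global")
        assert two_stage.draws == pytest.approx(one_stage.draws, abs=1e-12)

    def test_missing_population_is_an_error(self):
        draws = make_draws([[1.0] * 50])
        with pytest.raises(KeyError):
            aggregate(draws, {}, "global")


class TestCombineAndChange:
    def test_zero_legumes_is_identity(self):
        veg = make_draws(np.random.default_rng(0).lognormal(5, 0.2, (3, 50)))
        leg = PosteriorDraws(strata=list(veg.strata), draws=np.zeros((3, 50)))
        assert combine_vegetables_legumes(veg, leg).draws == pytest.approx(veg.draws)

    def test_constant_sum_and_mean_linearity(self):
        veg = make_draws([[300.0] * 50])
        leg = PosteriorDraws(strata=list(veg.strata), draws=np.full((1, 50), 100.0))
        total = combine_vegetables_legumes(veg, leg)
        assert total.draws == pytest.approx(np.full((1, 50), 400.0))
        rng = np.random.default_rng(1)
        a = make_draws(rng.lognormal(5, 0.4, (2, 100)))
        b = PosteriorDraws(strata=list(a.strata), draws=rng.lognormal(4, 0.4, (2, 100)))
        s = combine_vegetables_legumes(a, b)
        assert s.draws.mean(axis=1) == pytest.approx(
            a.draws.mean(axis=1) + b.draws.mean(axis=1), abs=1e-12)

    def test_mismatch_rejected(self):
        veg = make_draws([[1.0] * 50])
        leg = make_draws([[1.0] * 50], country="B")
        with pytest.raises(ValueError):
            combine_vegetables_legumes(veg, leg)

    def test_identical_inputs_give_zero_change(self):
        a = make_draws(np.random.default_rng(2).lognormal(4, 0.3, (2, 64)), year=1990)
        b = PosteriorDraws(strata=[k._replace(year=2010) for k in a.strata],
                           draws=a.draws.copy())
        abs_c, rel_c = change_between(a, b)
        for est in abs_c + rel_c:
            assert (est.mean, est.ui_lo, est.ui_hi) == (0.0, 0.0, 0.0)
            assert not est.significant

    def test_constant_shift_recovered_at_draw_level(self):
        a = make_draws(np.random.default_rng(3).lognormal(4, 0.3, (1, 100)), year=1990)
        b = PosteriorDraws(strata=[k._replace(year=2010) for k in a.strata],
                           draws=a.draws + 5.3)
        abs_c, _ = change_between(a, b)
        assert abs_c[0].mean == pytest.approx(5.3, abs=1e-12)
        assert abs_c[0].ui_lo == pytest.approx(5.3, abs=1e-12)
        assert abs_c[0].significant

    def test_pairwise_ui_differs_from_ui_difference(self):
        # brute-force counterexample on 100 draws: the UI of the draw-level
        # difference is not the difference of the two UIs
        rng = np.random.default_rng(7)
        x = rng.normal(100, 10, 100)
        a = make_draws([x], year=1990)
        b = PosteriorDraws(strata=[a.strata[0]._replace(year=2010)],
                           draws=np.array([100 + 10 * rng.normal(size=100)]))
        abs_c, _ = change_between(a, b)
        naive_lo = np.percentile(b.draws[0], 2.5) - np.percentile(a.draws[0], 2.5)
        assert abs_c[0].ui_lo != pytest.approx(naive_lo, abs=0.5)


class TestAttainment:
    def test_inclusive_boundary(self):
        means = {f"C{i}": 300.0 for i in range(5)}
        pops = {f"C{i}": 10.0 for i in range(5)}
        n, share = attainment(means, OPTIMAL_INTAKES["fruits"], pops)
        assert (n, share) == (5, 1.0)

    def test_two_of_twenty_countries_with_small_population_share(self):
        means = {f"C{i}": 100.0 for i in range(18)}
        means.update({"W1": 320.0, "W2": 310.0})
        pops = {c: 1000.0 for c in means}
        pops["W1"] = pops["W2"] = 2.0  # the winners hold 0.4/0.6 of a percent
        n, share = attainment(means, OPTIMAL_INTAKES["fruits"], pops)
        assert n == 2
        assert share == pytest.approx(4.0 / 18004.0)

    def test_processed_meats_zero_optimal(self):
        means = {"A": 5.0, "B": 0.0, "C": 12.0}
        pops = {"A": 1.0, "B": 1.0, "C": 1.0}
        n, share = attainment(means, OPTIMAL_INTAKES["processed_meats"], pops)
        assert n == 1  # only exact zero attains a zero optimum
        n2, _ = attainment({"A": 5.0, "C": 12.0}, OPTIMAL_INTAKES["processed_meats"],
                           pops)
        assert n2 == 0

    def test_weekly_threshold_converts_daily_estimates(self):
        # red meats: <= 100 g/week means <= 14.29 g/day
        means = {"A": 14.0, "B": 15.0}
        pops = {"A": 1.0, "B": 3.0}
        n, share = attainment(means, OPTIMAL_INTAKES["red_meats"], pops)
        assert n == 1
        assert share == pytest.approx(0.25)

    @given(st.floats(50, 600))
    def test_share_monotone_in_protective_threshold(self, thr):
        from dataclasses import replace

        means = {f"C{i}": 20.0 * i for i in range(1, 20)}
        pops = {c: 1.0 for c in means}
        opt = replace(OPTIMAL_INTAKES["fruits"], threshold=thr)
        opt_hi = replace(OPTIMAL_INTAKES["fruits"], threshold=thr + 50)
        _, share = attainment(means, opt, pops)
        _, share_hi = attainment(means, opt_hi, pops)
        assert 0.0 <= share_hi <= share <= 1.0


class TestFoldVariation:
    @pytest.mark.parametrize("means, rounding, want", [
        ([27.6, 169.9], "integer", 6.0),       # regional fruit extremes
        ([86.1, 294.4], "one_decimal", 3.4),   # regional vegetable extremes
        ([5.0, 5.0], "one_decimal", 1.0),
    ])
    def test_values(self, means, rounding, want):
        assert fold_variation(means, rounding) == want

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_variation([0.0, 10.0])


class TestSexContrast:
    def two_sex_draws(self, f_level, m_level, n=100):
        strata = [StratumKey("A", 2010, a, s) for a in range(2) for s in ("F", "M")]
        rows = [np.full(n, f_level if k.sex == "F" else m_level) for k in strata]
        return PosteriorDraws(strata=strata, draws=np.vstack(rows))

    def test_planted_positive_difference(self):
        draws = self.two_sex_draws(105.0, 100.0)
        pops = {k: 10.0 for k in draws.strata}
        est = sex_contrast(draws, pops)["A"]
        assert est.mean == pytest.approx(5.0)
        assert est.significant

    def test_antisymmetry_and_null(self):
        rng = np.random.default_rng(0)
        strata = [StratumKey("A", 2010, a, s) for a in range(2) for s in ("F", "M")]
        draws = PosteriorDraws(strata=strata, draws=rng.lognormal(4, 0.3, (4, 200)))
        pops = {k: float(rng.integers(5, 50)) for k in strata}
        fm = sex_contrast(draws, pops)["A"]
        swapped = PosteriorDraws(
            strata=[k._replace(sex="M" if k.sex == "F" else "F") for k in strata],
            draws=draws.draws)
        mf = sex_contrast(swapped, {k._replace(sex="M" if k.sex == "F" else "F"): v
                                    for k, v in pops.items()})["A"]
        assert mf.mean == pytest.approx(-fm.mean, abs=1e-12)

    def test_missing_sex_is_an_error(self):
        strata = [StratumKey("A", 2010, 0, "F")]
        draws = PosteriorDraws(strata=strata, draws=np.ones((1, 50)))
        with pytest.raises(ValueError, match="sex M"):
            sex_contrast(draws, {strata[0]: 1.0})


def test_optimal_sd_is_ten_percent_on_the_serving_scale():
    # the serving-scale rule reproduces every printed SD, including the
    # whole-grain row where the gram mean and serving arithmetic disagree
    sds = {f: OPTIMAL_INTAKES[f].sd for f in
           ("fruits", "vegetables", "nuts_seeds", "whole_grains", "seafood", "red_meats")}
    assert sds["fruits"] == pytest.approx(30.0)
    assert sds["vegetables"] == pytest.approx(40.0)
    assert sds["nuts_seeds"] == pytest.approx(11.34)
    assert sds["whole_grains"] == pytest.approx(12.5)
    assert sds["seafood"] == pytest.approx(35.0)
    assert sds["red_meats"] == pytest.approx(10.0)
    assert OPTIMAL_INTAKES["processed_meats"].sd == 0.0


def test_weekly_rescaling_commutes_with_summaries():
    rng = np.random.default_rng(9)
    draws = make_draws(rng.lognormal(4, 0.3, (2, 200)))
    pops = {k: 1.0 for k in draws.strata}
    agg = aggregate(draws, pops, "global")
    weekly = PosteriorDraws(strata=agg.strata, draws=agg.draws * 7.0)
    a, b = summarize_draws(agg.draws[0]), summarize_draws(weekly.draws[0])
    assert (b.mean, b.ui_lo, b.ui_hi) == pytest.approx((7 * a.mean, 7 * a.ui_lo, 7 * a.ui_hi))


def test_global_mean_bounded_by_country_means():
    rng = np.random.default_rng(10)
    strata = [StratumKey(c, 2010, 0, "M") for c in "ABCDE"]
    draws = PosteriorDraws(strata=strata, draws=rng.lognormal(4, 0.6, (5, 150)))
    pops = {k: float(rng.integers(1, 100)) for k in strata}
    glob = aggregate(draws, pops, "global").draws[0]
    assert (glob >= draws.draws.min(axis=0) - 1e-12).all()
    assert (glob <= draws.draws.max(axis=0) + 1e-12).all()
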