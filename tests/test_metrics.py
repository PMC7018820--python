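"""dh4 windowing against brute-force oracles; IHA vector standardization and distance."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowcascade import (
    DischargeSeries,
    IHAVector,
    Period,
    dh4,
    dh4_annual,
    dh4_observed,
    euclidean_distance,
    standardize_iha,
)


def brute_force_dh4(flows):
    """Independent oracle: enumerate every contained 30-day window."""
    flows = np.asarray(flows, dtype=float)
    return max(flows[i : i + 30].mean() for i in range(len(flows) - 29))


def series_for(period: Period, flow, site="s1", model="m1"):
    return DischargeSeries(site_id=site, model_id=model, period_label=period.label,
                          start=period.start_date, flow=flow)


class TestDh4:
    def test_constant_series(self):
        assert dh4(np.full(365, 5.0)) == pytest.approx(5.0)

    def test_elevated_block_attains_max(self):
        flows = np.ones(365)
        flows[100:130] = 31.0  # one fully elevated 30-day window
        assert dh4(flows) == pytest.approx(31.0)

    def test_single_window_is_mean(self, rng):
        flows = rng.lognormal(size=30)
        assert dh4(flows) == pytest.approx(flows.mean())

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="30"):
            dh4(np.ones(29))

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(50):
            n = rng.integers(30, 400)
            flows = rng.lognormal(sigma=1.0, size=n)
            assert dh4(flows) == pytest.approx(brute_force_dh4(flows))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1e3), min_size=30, max_size=120))
    def test_oracle_equivalence_property(self, flows):
        assert dh4(flows) == pytest.approx(brute_force_dh4(flows))

    def test_additive_and_multiplicative_monotonicity(self, rng):
        flows = rng.lognormal(size=200)
        base = dh4(flows)
        assert dh4(flows + 2.5) == pytest.approx(base + 2.5)
        assert dh4(flows * 3.0) == pytest.approx(base * 3.0)


class TestDh4Annual:
    period = Period("baseline", 1998, 2017)

    def test_twenty_values_constant_series(self):
        s = series_for(self.period, np.full(self.period.n_days, 4.0))
        out = dh4_annual(s, period=self.period)
        assert len(out) == 20
        assert np.allclose(out["value"], 4.0)
        assert list(out["year"]) == list(range(1998, 2018))

    def test_elevated_year_stands_out(self):
        s = series_for(self.period, np.ones(self.period.n_days))
        # elevate a 30-day block inside calendar year 2005
        idx = s.day_index(dt.date(2005, 5, 1))
        flows = s.flow.copy()
        flows[idx : idx + 30] = 11.0
        out = dh4_annual(s.with_flow(flows), period=self.period).set_index("year")["value"]
        assert out.loc[2005] == pytest.approx(11.0)
        assert np.allclose(out.drop(2005), 1.0)

    def test_year_windows_match_observed_oracle(self, rng):
        """Each annual value equals dh4_observed anchored at that year end."""
        s = series_for(self.period, rng.lognormal(size=self.period.n_days))
        out = dh4_annual(s, period=self.period).set_index("year")["value"]
        for year in (1999, 2007, 2017):
            assert out.loc[year] == pytest.approx(
                dh4_observed(s, dt.date(year, 12, 31))
            )

    def test_anchor_shifts_window(self, rng):
        s = series_for(self.period, rng.lognormal(size=self.period.n_days))
        out = dh4_annual(s, period=self.period, anchor=(6, 30)).set_index("year")["value"]
        assert out.loc[2005] == pytest.approx(dh4_observed(s, dt.date(2005, 6, 30)))

    def test_insufficient_history_year_omitted(self):
        short = Period("p", 1998, 1999)
        s = series_for(short, np.ones(short.n_days))
        out = dh4_annual(s, period=short, anchor=(6, 30))
        # the 365-day window ending 1998-06-30 starts before the series
        assert list(out["year"]) == [1999]


class TestDh4Observed:
    def test_constant_history(self):
        p = Period("baseline", 1998, 2017)
        s = series_for(p, np.full(p.n_days, 2.0))
        assert dh4_observed(s, dt.date(2001, 6, 15)) == pytest.approx(2.0)
        # shifting the sampling date over a constant series changes nothing
        assert dh4_observed(s, dt.date(2001, 6, 16)) == pytest.approx(2.0)

    def test_equals_brute_force_on_trailing_window(self, rng):
        p = Period("baseline", 1998, 2017)
        s = series_for(p, rng.lognormal(size=p.n_days))
        date = dt.date(2003, 9, 10)
        end = s.day_index(date)
        window = s.flow[end - 364 : end + 1]
        assert dh4_observed(s, date) == pytest.approx(brute_force_dh4(window))

    def test_insufficient_history_rejected(self):
        p = Period("baseline", 1998, 2017)
        s = series_for(p, np.ones(p.n_days))
        with pytest.raises(ValueError, match="insufficient history"):
            dh4_observed(s, dt.date(1998, 6, 1))


class TestIHAVectors:
    def test_hand_zscore(self):
        vecs = [IHAVector("a", {"m": 0.0}), IHAVector("b", {"m": 2.0})]
        out = standardize_iha(vecs)
        assert out[0].values["m"] == pytest.approx(-0.7071, abs=1e-4)
        assert out[1].values["m"] == pytest.approx(+0.7071, abs=1e-4)
        assert all(v.standardized for v in out)

    def test_zero_spread_metric_dropped(self):
        vecs = [IHAVector("a", {"m": 1.0, "k": 3.0}), IHAVector("b", {"m": 1.0, "k": 5.0})]
        out = standardize_iha(vecs)
        assert out[0].metrics == frozenset({"k"})

    def test_standardized_moments(self, rng):
        vecs = [IHAVector(f"v{i}", {"m": float(x), "k": float(y)})
                for i, (x, y) in enumerate(rng.normal(size=(6, 2)))]
        out = standardize_iha(vecs)
        for key in ("m", "k"):
            vals = np.array([v.values[key] for v in out])
            assert vals.mean() == pytest.approx(0.0, abs=1e-12)
            assert vals.std(ddof=1) == pytest.approx(1.0)

    def test_distance_examples_and_symmetry(self):
        a = IHAVector("a", {"x": 0.0, "y": 3.0})
        b = IHAVector("b", {"x": 4.0, "y": 0.0})
        assert euclidean_distance(a, b) == pytest.approx(5.0)
        assert euclidean_distance(a, a) == 0.0
        assert euclidean_distance(a, b) == euclidean_distance(b, a)

    def test_key_and_flag_mismatch_rejected(self):
        a = IHAVector("a", {"x": 0.0})
        with pytest.raises(ValueError, match="keys differ"):
            euclidean_distance(a, IHAVector("b", {"z": 0.0}))
        with pytest.raises(ValueError, match="standardized"):
            euclidean_distance(a, IHAVector("b", {"x": 1.0}, standardized=True))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=3))
    def test_triangle_inequality(self, points):
        a, b, c = (IHAVector(f"v{i}", {"x": p[0], "y": p[1]}) for i, p in enumerate(points))
        d = euclidean_distance
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-9
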