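"""Crossing detection, site models, rates, per-crossing risk, extrapolation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from roadecol.crossings import (
    build_crossing_design,
    build_crossing_vs_roadkill_design,
    crossing_candidates,
    crossing_rate,
    detect_crossings,
    extrapolate_mortality,
    fit_crossing_models,
    fit_crossing_vs_roadkill,
    per_crossing_risk,
    risk_estimate,
    roadkill_candidates,
)


def _tel(rows):
    return pd.DataFrame(rows, columns=["individual", "time", "x", "y"])


class TestDetectCrossings:
    def test_single_transversal(self):
        hw = LineString([(-10_000, 0), (10_000, 0)])
        t0 = pd.Timestamp("2008-05-01 22:00")
        tel = _tel([("A", t0, 0.0, -200.0), ("A", t0 + pd.Timedelta(minutes=30), 0.0, 200.0)])
        ev = detect_crossings(tel, hw)
        assert len(ev) == 1
        assert ev[0].chainage == pytest.approx(10_000.0)
        assert ev[0].time == t0 + pd.Timedelta(minutes=15)

    def test_same_side_no_event(self):
        hw = LineString([(-10_000, 0), (10_000, 0)])
        t0 = pd.Timestamp("2008-05-01 22:00")
        tel = _tel([("A", t0, 0.0, 200.0), ("A", t0 + pd.Timedelta(minutes=30), 500.0, 300.0)])
        assert detect_crossings(tel, hw) == []

    def test_gap_of_an_hour_or_more_skipped(self):
        hw = LineString([(-10_000, 0), (10_000, 0)])
        t0 = pd.Timestamp("2008-05-01 22:00")
        tel = _tel([("A", t0, 0.0, -200.0), ("A", t0 + pd.Timedelta(minutes=60), 0.0, 200.0)])
        assert detect_crossings(tel, hw) == []

    def _brute_force(self, tel, hw, max_gap=60.0):
        """Exact segment-by-segment intersection scan over polyline edges."""
        verts = np.asarray(hw.coords)
        out = []
        for ind, grp in tel.groupby("individual"):
            grp = grp.sort_values("time")
            t = pd.to_datetime(grp["time"]).to_numpy()
            xy = grp[["x", "y"]].to_numpy()
            for i in range(len(grp) - 1):
                if (t[i + 1] - t[i]) / np.timedelta64(1, "m") >= max_gap:
                    continue
                p, q = xy[i], xy[i + 1]
                for j in range(len(verts) - 1):
                    a, b = verts[j], verts[j + 1]
                    d1, d2 = q - p, b - a
                    denom = d1[0] * d2[1] - d1[1] * d2[0]
                    if denom == 0:
                        continue
                    s = ((a - p)[0] * d2[1] - (a - p)[1] * d2[0]) / denom
                    u = ((a - p)[0] * d1[1] - (a - p)[1] * d1[0]) / denom
                    if 0 <= s <= 1 and 0 <= u <= 1:
                        pt = p + s * d1
                        out.append(float(hw.project(__import__("shapely").geometry.Point(pt))))
        return sorted(out)

    def test_matches_bruteforce_on_random_fixtures(self):
        """Event counts and chainages equal the exhaustive edge-scan oracle."""
        rng = np.random.default_rng(10)
        for rep in range(100):
            xs = np.linspace(0, 5_000, 12)
            ys = rng.normal(0, 150, 12)
            hw = LineString(np.column_stack([xs, ys]))
            t0 = pd.Timestamp("2008-05-01 20:00")
            n = 25
            tel = _tel([
                ("A", t0 + k * pd.Timedelta(minutes=30),
                 rng.uniform(0, 5_000), rng.normal(0, 400))
                for k in range(n)
            ])
            got = sorted(e.chainage for e in detect_crossings(tel, hw))
            want = self._brute_force(tel, hw)
            assert len(got) == len(want)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_time_reversal_invariance(self, telemetry, landscape):
        fwd = detect_crossings(telemetry, landscape.highway)
        rev = telemetry.iloc[::-1].reset_index(drop=True)
        bwd = detect_crossings(rev, landscape.highway)
        assert len(fwd) == len(bwd)
        np.testing.assert_allclose(
            sorted(e.chainage for e in fwd), sorted(e.chainage for e in bwd), atol=1e-6
        )


class TestCandidateLists:
    def test_owl_fourteen_with_winner(self):
        specs = crossing_candidates("barn_owl")
        assert len(specs) == 14
        assert ["verge_width", "d_above", "herb_pct"] in specs

    def test_marten_fifteen_with_winner(self):
        specs = crossing_candidates("stone_marten")
        assert len(specs) == 15
        assert ["d_flat", "verge_width"] in specs

    def test_roadkill_eleven_with_winners(self):
        specs = roadkill_candidates()
        assert len(specs) == 11
        assert ["total_traffic"] in specs  # owl winner
        assert ["total_traffic", "d_above", "d_allpassages"] in specs  # marten winner


class TestCrossingModels:
    def test_design_balanced_per_individual(self, landscape, traffic, telemetry):
        events = detect_crossings(telemetry, landscape.highway)
        assert len(events) >= 5
        design = build_crossing_design(events, landscape, traffic, seed=1)
        counts = design.groupby(["individual", "response"]).size().unstack()
        assert (counts[0] == counts[1]).all()

    def test_no_signal_favors_null(self, traffic):
        """Identical covariates at all sites leave the null model on top."""
        from roadecol.landscape import Landscape, VergeSegment
        from roadecol.crossings import CrossingEvent

        land = Landscape(
            highway=LineString([(0, 0), (20_000, 0)]),
            verge_segments=[
                VergeSegment(i * 100.0, (i + 1) * 100.0, 8.0, "flat", 40.0, 30.0)
                for i in range(200)
            ],
        )
        t0 = pd.Timestamp("2008-05-01 22:00")
        events = [
            CrossingEvent(f"I{k % 3}", t0, float(1_000 + 17 * k)) for k in range(30)
        ]
        design = build_crossing_design(events, land, traffic, seed=2)
        # traffic is read at one shared hour -> all traffic columns constant;
        # verge attributes constant by construction
        tab, fits = fit_crossing_models(design, "barn_owl")
        assert tab.iloc[0]["model"] == "null"


class TestRates:
    @pytest.mark.parametrize(
        "n,hours,expected",
        [(29, 1175.0, 0.2961), (70, 866.0, 0.9700), (0, 500.0, 0.0)],
    )
    def test_field_crossing_rates(self, n, hours, expected):
        """29 crossings/1175 h -> 0.30/day; 70/866 h -> 0.97/day at 12 h activity."""
        assert crossing_rate(n, hours, 12.0) == pytest.approx(expected, abs=5e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            crossing_rate(1, 0.0)
        with pytest.raises(ValueError):
            crossing_rate(1, 10.0, activity_hours=30.0)


class TestPerCrossingRisk:
    def test_zero_kills(self):
        assert per_crossing_risk(0, 0.5, 100.0) == 0.0

    def test_simple_arithmetic(self):
        assert per_crossing_risk(4, 0.01, 100_000.0) == pytest.approx(0.004)

    def test_tracking_period_reconstruction(self):
        """Summed owl tracking periods (~1338 d) with 4 kills give r ~ 0.010."""
        periods = [
            ("2008-05-05", "2009-03-07"), ("2008-06-07", "2009-10-15"),
            ("2008-08-08", "2009-01-26"), ("2009-02-02", "2009-05-13"),
            ("2009-09-03", "2009-10-16"), ("2008-05-07", "2008-08-06"),
            ("2008-05-09", "2008-06-02"), ("2008-08-05", "2008-09-02"),
            ("2009-02-17", "2009-03-20"), ("2009-03-31", "2009-05-02"),
            ("2008-05-12", "2008-05-29"),
        ]
        days = sum((pd.Timestamp(b) - pd.Timestamp(a)).days for a, b in periods)
        assert days == 1338
        rate = crossing_rate(29, 1175.0, 12.0)
        r = per_crossing_risk(4, rate, days)
        assert r == pytest.approx(0.0101, abs=0.0005)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            per_crossing_risk(1, 0.0, 100.0)


class TestExtrapolation:
    def test_zero_risk_zero_mortality(self):
        assert extrapolate_mortality(0.24, 2.0, 0.3, 0.0) == 0.0

    def test_owl_lower_bound_formula(self):
        """0.24 ind/km2 over a 2 km strip at 0.30 crossings/day and r=0.009."""
        m = extrapolate_mortality(0.24, 2.0, 0.30, 0.009, 100.0)
        assert m == pytest.approx(47.3, abs=0.05)

    def test_linearity(self):
        base = extrapolate_mortality(0.24, 2.0, 0.30, 0.009)
        assert extrapolate_mortality(0.48, 2.0, 0.30, 0.009) == pytest.approx(2 * base)
        assert extrapolate_mortality(0.24, 4.0, 0.30, 0.009) == pytest.approx(2 * base)

    def test_risk_estimate_two_scenarios(self):
        est = risk_estimate(
            crossings_observed=29, tracked_hours=1175.0, kills_confirmed=4,
            kills_disappeared=4, tracking_days_total=1338.0,
            density_ind_km2=0.24, strip_width_km=2.0,
        )
        assert est.rate_per_day == pytest.approx(0.2961, abs=5e-4)
        assert est.r_upper == pytest.approx(2 * est.r_confirmed)
        assert est.r_upper >= est.r_confirmed
        assert est.mortality_upper_per_road > est.mortality_confirmed_per_road


class TestCrossingVsRoadkill:
    def test_planted_high_traffic_kills_recovered(self, landscape, traffic):
        """Kills placed at high-traffic hours give a negative traffic slope."""
        from roadecol.crossings import CrossingEvent

        rng = np.random.default_rng(4)
        hours = traffic.frame
        night = hours[(hours["hour"].dt.hour >= 19) | (hours["hour"].dt.hour < 7)]
        low = night.nsmallest(200, "total")
        high = night.nlargest(60, "total")
        events = [
            CrossingEvent(f"I{k % 4}", low["hour"].iloc[k] + pd.Timedelta(minutes=20),
                          float(rng.uniform(0, 19_000)))
            for k in range(60)
        ]
        registry = pd.DataFrame({
            "species": "barn_owl",
            "chainage_m": rng.uniform(0, 19_000, 30),
            "date_iso": [str(h.date()) for h in high["hour"].iloc[:30]],
        })
        design = build_crossing_vs_roadkill_design(events, registry, landscape, traffic)
        tab, fits = fit_crossing_vs_roadkill(design)
        traffic_fit = next(f for f in fits if f.spec == "total_traffic")
        assert traffic_fit.beta[1] < 0

    def test_empty_class_rejected(self, landscape, traffic):
        with pytest.raises(ValueError, match="non-empty"):
            build_crossing_vs_roadkill_design([], pd.DataFrame(), landscape, traffic)
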