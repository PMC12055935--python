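"""Outcome-metric cascade: lumen gain, relative gain, influence
coefficients, Gamma/mu aggregates, and the full summary reproduction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lesionlab import (
    LambdaTable,
    LumenProfile,
    gamma,
    influence_coefficients,
    lumen_gain,
    mu,
    paper_lambda_table,
    relative_lumen_gain,
    reproduce_paper_summary,
)
from lesionlab.metrics import relative_lumen_gain_profiles, round_half_away


def make_profile(n=101, pre=2.0, post=3.0, window=(0.4, 0.6)):
    u = np.linspace(0.0, 1.0, n)
    return LumenProfile(u, np.full(n, pre), np.full(n, post), window)


class TestLumenGain:
    def test_identity_and_offset(self):
        p = make_profile(post=2.0)
        assert np.allclose(lumen_gain(p), 0.0)
        q = make_profile(post=3.0)
        assert np.allclose(lumen_gain(q), 1.0)

    def test_profile_validation(self):
        u = np.linspace(0, 1, 11)
        with pytest.raises(ValueError, match="increasing"):
            LumenProfile(u[::-1], np.ones(11), np.ones(11), (0.4, 0.6))
        with pytest.raises(ValueError, match="positive"):
            LumenProfile(u, np.zeros(11), np.ones(11), (0.4, 0.6))
        with pytest.raises(ValueError, match="window"):
            LumenProfile(u, np.ones(11), np.ones(11), (0.6, 0.4))


class TestRelativeLumenGain:
    def test_zero_when_equal(self):
        u = np.linspace(0, 1, 101)
        a = np.ones(101)
        assert relative_lumen_gain(a, a, u, (0.3, 0.7), "absolute") == 0.0
        assert relative_lumen_gain(a, a, u, (0.3, 0.7), "percent_of_baseline") == 0.0

    def test_twenty_percent_scaling(self):
        u = np.linspace(0, 1, 101)
        base = np.full(101, 2.5)
        assert relative_lumen_gain(1.2 * base, base, u, (0.2, 0.8)) == pytest.approx(20.0)

    def test_absolute_mode_units(self):
        u = np.linspace(0, 1, 101)
        base = np.full(101, 2.5)
        assert relative_lumen_gain(base + 0.7, base, u, (0.2, 0.8), "absolute") == pytest.approx(0.7)

    def test_zero_baseline_percent_undefined(self):
        u = np.linspace(0, 1, 11)
        with pytest.raises(ZeroDivisionError):
            relative_lumen_gain(np.ones(11), np.zeros(11), u, (0.2, 0.8))

    def test_grid_refinement_invariance(self):
        """Lambda is unchanged by uniform refinement of piecewise-constant
        profiles (the window average sees the same constant excess)."""
        for n in (41, 81, 161, 321):
            u = np.linspace(0, 1, n)
            base = np.where((u >= 0.375) & (u <= 0.625), 2.0, 0.5)
            alpha = np.where((u >= 0.375) & (u <= 0.625), 2.6, 0.5)
            lam = relative_lumen_gain(alpha, base, u, (0.375, 0.625))
            assert lam == pytest.approx(30.0, rel=1e-12)

    def test_mismatched_grids_rejected(self):
        p = make_profile(n=101)
        q = make_profile(n=51)
        with pytest.raises(ValueError, match="grid"):
            relative_lumen_gain_profiles(p, q)


def random_table(rng):
    rows = []
    for arc in (90.0, 270.0):
        for sub in ("sided", "centered"):
            for l in ("1/3", "2/3"):
                for w in ("1/3", "2/3"):
                    rows.append(dict(arc_deg=arc, submodel=sub, l=l, w=w,
                                     lambda_pct=rng.uniform(0, 50)))
        for w in ("1/3", "2/3"):
            rows.append(dict(arc_deg=arc, submodel="through", l="1", w=w,
                             lambda_pct=rng.uniform(0, 60)))
    return LambdaTable(pd.DataFrame(rows))


class TestInfluenceCoefficients:
    def test_through_coefficients_match_reference(self, paper_table):
        inf = influence_coefficients(paper_table)
        assert inf.delta_w[(90.0, "through")] == pytest.approx(75.0, abs=1e-9)
        assert inf.delta_w[(270.0, "through")] == pytest.approx(96.0, abs=1e-9)

    def test_sided_90_unrounded_values(self, paper_table):
        inf = influence_coefficients(paper_table)
        assert inf.delta_l[(90.0, "sided")] == pytest.approx(32.55, abs=1e-9)
        assert inf.delta_w[(90.0, "sided")] == pytest.approx(12.45, abs=1e-9)

    def test_constant_table_gives_zero(self):
        rng = np.random.default_rng(0)
        t = random_table(rng)
        t.frame["lambda_pct"] = 7.0
        inf = influence_coefficients(LambdaTable(t.frame))
        assert all(abs(v) < 1e-12 for v in inf.delta_l.values())
        assert all(abs(v) < 1e-12 for v in inf.delta_w.values())

    def test_brute_force_oracle_on_random_tables(self):
        """Explicit 2x2 enumeration of the averaged finite differences
        agrees with the implementation on 100 random tables."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = random_table(rng)
            inf = influence_coefficients(t)
            for arc in (90.0, 270.0):
                for sub in ("sided", "centered"):
                    g = lambda l, w: t.get(arc, sub, l, w)
                    dl = 0.5 * ((g(2 / 3, 1 / 3) - g(1 / 3, 1 / 3)) + (g(2 / 3, 2 / 3) - g(1 / 3, 2 / 3))) / (1 / 3)
                    dw = 0.5 * ((g(1 / 3, 2 / 3) - g(1 / 3, 1 / 3)) + (g(2 / 3, 2 / 3) - g(2 / 3, 1 / 3))) / (1 / 3)
                    assert inf.delta_l[(arc, sub)] == pytest.approx(dl, rel=1e-12, abs=1e-12)
                    assert inf.delta_w[(arc, sub)] == pytest.approx(dw, rel=1e-12, abs=1e-12)

    def test_shift_invariance(self):
        """Adding a constant to every Lambda leaves Delta (hence Gamma)
        unchanged: the operators are finite differences."""
        rng = np.random.default_rng(3)
        t = random_table(rng)
        shifted = t.frame.copy()
        shifted["lambda_pct"] = shifted["lambda_pct"] + 11.5
        a = influence_coefficients(t)
        b = influence_coefficients(LambdaTable(shifted))
        for k in a.delta_l:
            assert a.delta_l[k] == pytest.approx(b.delta_l[k], abs=1e-9)
        for k in a.delta_w:
            assert a.delta_w[k] == pytest.approx(b.delta_w[k], abs=1e-9)

    def test_missing_cell_is_keyed_error(self, paper_table):
        broken = paper_table.frame[~(
            (paper_table.frame.submodel == "sided")
            & (paper_table.frame.arc_deg == 90.0)
            & (np.abs(paper_table.frame.w - 2 / 3) < 1e-9)
            & (np.abs(paper_table.frame.l - 2 / 3) < 1e-9)
        )]
        with pytest.raises(KeyError, match="sided"):
            influence_coefficients(LambdaTable(broken))


class TestAggregates:
    def test_pythagorean_triple(self):
        assert gamma(3.0, 4.0) == 5.0

    def test_centered_270_from_rounded_deltas(self):
        assert gamma(43.0, 20.0) == pytest.approx(math.sqrt(2249.0))

    def test_single_coefficient_is_absolute_value(self):
        assert gamma(delta_w=-75.0) == 75.0

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_symmetry_and_triangle_bound(self, a, b):
        assert gamma(a, b) == pytest.approx(gamma(b, a))
        assert gamma(a, b) <= abs(a) + abs(b) + 1e-12

    def test_mu_conventions(self):
        gs = [math.sqrt(1233.0), math.sqrt(1130.0), 75.0]
        assert mu([0.0, 0.0, 0.0]) == 0.0
        assert round_half_away(mu(gs, "as_printed_numbers")) == 144.0
        assert mu(gs, "as_printed_formula") == pytest.approx(47.909857, abs=1e-4)


class TestPaperSummary:
    def test_all_ten_rounded_delta_cells(self, paper_summary):
        """The unrounded cascade reproduces every printed coefficient after
        half-away-from-zero rounding."""
        r = paper_summary.influence_rounded
        assert r.delta_l[(90.0, "sided")] == 33.0 and r.delta_w[(90.0, "sided")] == 12.0
        assert r.delta_l[(90.0, "centered")] == 29.0 and r.delta_w[(90.0, "centered")] == 17.0
        assert r.delta_l[(270.0, "sided")] == 46.0 and r.delta_w[(270.0, "sided")] == 17.0
        assert r.delta_l[(270.0, "centered")] == 43.0 and r.delta_w[(270.0, "centered")] == 20.0
        assert r.delta_w[(90.0, "through")] == 75.0 and r.delta_w[(270.0, "through")] == 96.0

    def test_through_row_average(self, paper_summary):
        assert paper_summary.through_average == pytest.approx(85.5)

    def test_cross_arc_average_row(self, paper_summary):
        c = paper_summary.cross_arc_averages
        assert (c["delta_l_sided"], c["delta_w_sided"]) == (39.5, 14.5)
        assert (c["delta_l_centered"], c["delta_w_centered"]) == (36.0, 18.5)

    def test_benefit_scores(self, paper_summary):
        assert paper_summary.mu_scores_rounded[90.0] == 144.0
        assert paper_summary.mu_scores_rounded[270.0] == 192.0

    def test_positional_aggregates(self, paper_summary):
        assert round_half_away(paper_summary.centered_aggregate) == 81.0
        # the sided aggregate lands near the centered one (location-independence)
        rel = abs(paper_summary.sided_aggregate - paper_summary.centered_aggregate) / paper_summary.sided_aggregate
        assert rel < 0.05

    def test_length_dominates_width(self, paper_summary):
        assert paper_summary.length_dominates_width
        assert paper_summary.mean_length_influence == pytest.approx((39.5 + 36.0) / 2)
        assert paper_summary.mean_width_influence == pytest.approx((14.5 + 18.5) / 2)

    def test_mean_convention_divides_by_three(self, paper_table):
        s = reproduce_paper_summary(paper_table, convention="as_printed_formula")
        assert s.mu_scores[90.0] == pytest.approx(143.7295723601021 / 3.0)


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected", [(32.55, 33.0), (12.45, 12.0), (28.5, 29.0), (-28.5, -29.0), (16.8, 17.0)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected

    def test_one_decimal(self):
        assert round_half_away(85.45, 1) == 85.5


class TestLambdaTableIO:
    def test_csv_round_trip(self, tmp_path, paper_table):
        path = tmp_path / "lam.csv"
        paper_table.to_csv(path)
        back = LambdaTable.from_csv(path)
        assert back.get(90.0, "through", 1.0, 2 / 3) == 45.0
        pd.testing.assert_frame_equal(back.frame, paper_table.frame)

    def test_validation(self, paper_table):
        dup = pd.concat([paper_table.frame, paper_table.frame.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            LambdaTable(dup)
        bad = paper_table.frame.copy()
        bad.loc[bad.submodel == "through", "l"] = 0.5
        with pytest.raises(ValueError, match="through"):
            LambdaTable(bad)

    def test_embedded_fixture_complete(self, paper_table):
        assert len(paper_table.frame) == 20
        assert set(paper_table.frame.submodel) == {"sided", "centered", "through"}
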