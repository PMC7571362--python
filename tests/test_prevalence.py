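"""Short/long split, durations, prevalence (ODE), YLDs and comorbidity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microgbd.draws import ID_COLS, draw_cols, make_draws
from microgbd.errors import ValidationError
from microgbd.prevalence import (
    DurationModel,
    attribute_combined_weight,
    average_duration,
    combine_disability_weights,
    comorbidity_adjust,
    comorbidity_factors,
    compute_ylds,
    long_term_prevalence,
    reconcile_streams,
    short_term_prevalence,
    solve_long_term_ode,
    split_short_long,
)
from microgbd.registries import build_nature_registry

REGISTRY = build_nature_registry()


def _cn_draws(value, nature, n_cells=1, n_draws=2, years=None):
    years = years or [2000]
    cells = pd.MultiIndex.from_product(
        [["L"], years, ["a0"], ["male"]], names=ID_COLS).to_frame(index=False)
    draws = make_draws(cells, np.full((len(cells), n_draws), value))
    draws.insert(0, "cause_id", "c")
    draws.insert(1, "nature_id", nature)
    return draws


class TestSplitShortLong:
    def test_amputations_entirely_long_term(self):
        st_s, lt_s = split_short_long(_cn_draws(10.0, "amp_lower_unilateral"), REGISTRY)
        assert (st_s[draw_cols(st_s)].to_numpy() == 0).all()
        assert np.allclose(lt_s[draw_cols(lt_s)], 10.0)

    def test_foreign_body_in_ear_entirely_short_term(self):
        st_s, lt_s = split_short_long(_cn_draws(10.0, "fb_ear"), REGISTRY)
        assert np.allclose(st_s[draw_cols(st_s)], 10.0)
        assert (lt_s[draw_cols(lt_s)].to_numpy() == 0).all()

    def test_fractional_split_conserves(self):
        st_s, lt_s = split_short_long(_cn_draws(10.0, "fx_hip"), REGISTRY,
                                      p_long_overrides={"fx_hip": 0.3})
        assert np.allclose(st_s[draw_cols(st_s)], 7.0)
        assert np.allclose(lt_s[draw_cols(lt_s)], 3.0)

    def test_invalid_p_long(self):
        with pytest.raises(ValidationError):
            split_short_long(_cn_draws(1.0, "fx_hip"), REGISTRY,
                             p_long_overrides={"fx_hip": 1.5})


class TestDurations:
    DUR = DurationModel(pd.DataFrame({
        "nature_id": ["fx_hip"], "d_treated": [0.1], "d_untreated": [0.5],
    }))

    def test_fully_treated(self):
        assert average_duration("fx_hip", self.DUR, haq=95.0) == pytest.approx(0.1)

    def test_partial_treatment(self):
        # haq=82 -> pi=0.8 -> 0.8*0.1 + 0.2*0.5 = 0.18
        assert average_duration("fx_hip", self.DUR, haq=82.0) == pytest.approx(0.18)

    def test_equal_durations_insensitive_to_access(self):
        dur = DurationModel(pd.DataFrame({
            "nature_id": ["x"], "d_treated": [0.2], "d_untreated": [0.2]}))
        for haq in (10.0, 60.0, 99.0):
            assert average_duration("x", dur, haq) == pytest.approx(0.2)

    def test_treatment_cannot_lengthen(self):
        with pytest.raises(ValidationError):
            DurationModel(pd.DataFrame({
                "nature_id": ["x"], "d_treated": [0.5], "d_untreated": [0.2]}))


class TestShortTermPrevalence:
    def test_product(self):
        out = short_term_prevalence(_cn_draws(0.05, "fx_hip"), 0.18)
        assert np.allclose(out[draw_cols(out)], 0.009)

    def test_zero_incidence(self):
        out = short_term_prevalence(_cn_draws(0.0, "fx_hip"), 0.18)
        assert (out[draw_cols(out)].to_numpy() == 0).all()

    def test_matches_steady_state_ode_for_low_prevalence(self):
        """Incidence x duration approximates the steady state of an ODE with
        remission 1/duration when i*d is small."""
        i, d = 0.05, 0.5
        # dP/dt = i(1-P) - P/d at steady state: P = i / (i + 1/d)
        ode = i / (i + 1 / d)
        product = i * d
        assert product == pytest.approx(ode, rel=0.05)


class TestLongTermODE:
    def test_steady_state(self):
        i, m, f = 0.01, 0.01, 0.02
        out = solve_long_term_ode(np.full(30, i), np.full(30, m), np.full(30, f))
        assert out[-1] == pytest.approx(i / (i + m + f), rel=0.005)

    def test_convergence_from_zero(self):
        i, m, f = 0.01, 0.01, 0.02
        out = solve_long_term_ode(np.full(300, i), np.full(300, m),
                                  np.full(300, f), initial=0.0)
        assert out[-1] == pytest.approx(0.25, rel=0.005)

    def test_zero_incidence_stays_zero(self):
        out = solve_long_term_ode(np.zeros(10), np.full(10, 0.01), np.zeros(10))
        assert np.allclose(out, 0.0)

    def test_pure_accumulation_closed_form(self):
        """With no mortality, P(t) = 1 - exp(-i t) from P(0)=0."""
        i = 0.05
        out = solve_long_term_ode(np.full(10, i), np.zeros(10), np.zeros(10),
                                  initial=0.0)
        assert out[9] == pytest.approx(1 - np.exp(-i * 10), rel=1e-6)

    def test_non_finite_hazard_rejected(self):
        with pytest.raises(ValidationError):
            solve_long_term_ode(np.array([np.nan]), np.zeros(1), np.zeros(1))

    def test_frame_interface_matches_scalar_solver(self):
        years = list(range(2000, 2010))
        draws = _cn_draws(0.01, "fx_hip", years=years)
        bg = draws[ID_COLS].copy()
        bg["rate"] = 0.01
        out = long_term_prevalence(draws, bg, {"fx_hip": 0.02})
        expected = solve_long_term_ode(np.full(10, 0.01), np.full(10, 0.01),
                                       np.full(10, 0.02))
        got = out.sort_values("year")["draw_0"].to_numpy()
        assert np.allclose(got, expected, rtol=1e-12)


class TestReconcile:
    def test_subtraction(self):
        st_p = _cn_draws(0.005, "fx_hip")
        lt_p = _cn_draws(0.02, "fx_hip")
        out = reconcile_streams(st_p, lt_p)
        assert np.allclose(out[draw_cols(out)], 0.015)

    def test_floor_at_zero_flagged(self):
        out = reconcile_streams(_cn_draws(0.03, "fx_hip"), _cn_draws(0.02, "fx_hip"))
        assert (out[draw_cols(out)].to_numpy() == 0).all()
        assert out.attrs["floored_cells"] == 1

    def test_zero_short_term_unchanged(self):
        lt_p = _cn_draws(0.02, "fx_hip")
        out = reconcile_streams(_cn_draws(0.0, "fx_hip"), lt_p)
        assert np.allclose(out[draw_cols(out)], 0.02)


class TestComputeYLDs:
    def _pop(self, cells, value=1.0):
        pop = cells[ID_COLS].drop_duplicates().copy()
        pop["population"] = value
        return pop

    @pytest.mark.parametrize("nature,dw", [("sci_neck", 0.7319), ("fx_pelvis", 0.2788)])
    def test_unit_short_term_prevalence_yld(self, nature, dw):
        """One person-year of short-term prevalence yields exactly the
        nature's short-term disability weight in YLDs."""
        st_p = _cn_draws(1.0, nature)
        lt_p = _cn_draws(0.0, nature)
        by_cause, by_nature = compute_ylds(st_p, lt_p, REGISTRY, self._pop(st_p))
        assert by_cause["draw_0"].iloc[0] == pytest.approx(dw)
        assert by_nature["draw_0"].iloc[0] == pytest.approx(dw)

    def test_zero_prevalence_zero_yld(self):
        st_p = _cn_draws(0.0, "fx_hip")
        by_cause, _ = compute_ylds(st_p, st_p, REGISTRY, self._pop(st_p))
        assert (by_cause[draw_cols(by_cause)].to_numpy() == 0).all()

    def test_marginals_agree(self, rng):
        frames_st, frames_lt = [], []
        for nature in ("fx_hip", "sci_neck", "contusion"):
            for cause in ("c1", "c2"):
                d = _cn_draws(rng.uniform(0.001, 0.01), nature)
                d["cause_id"] = cause
                frames_st.append(d)
                d2 = _cn_draws(rng.uniform(0.001, 0.01), nature)
                d2["cause_id"] = cause
                frames_lt.append(d2)
        st_p = pd.concat(frames_st, ignore_index=True)
        lt_p = pd.concat(frames_lt, ignore_index=True)
        by_cause, by_nature = compute_ylds(st_p, lt_p, REGISTRY, self._pop(st_p))
        total_c = by_cause[draw_cols(by_cause)].to_numpy().sum()
        total_n = by_nature[draw_cols(by_nature)].to_numpy().sum()
        assert total_c == pytest.approx(total_n, rel=1e-9)

    def test_monotone_in_prevalence(self):
        lo = _cn_draws(0.01, "fx_hip")
        hi = _cn_draws(0.02, "fx_hip")
        zero = _cn_draws(0.0, "fx_hip")
        y_lo, _ = compute_ylds(lo, zero, REGISTRY, self._pop(lo))
        y_hi, _ = compute_ylds(hi, zero, REGISTRY, self._pop(hi))
        assert (y_hi["draw_0"] > y_lo["draw_0"]).all()


class TestComorbidity:
    def test_closed_form_combination(self):
        """Weights 0.2 and 0.3 combine multiplicatively to 0.44, attributed
        proportionally as (0.176, 0.264)."""
        assert combine_disability_weights([0.2, 0.3]) == pytest.approx(0.44)
        attr = attribute_combined_weight([0.2, 0.3])
        assert attr == pytest.approx([0.176, 0.264])

    def test_single_condition_unadjusted(self):
        adj = comorbidity_adjust([0.1], [0.3], n_sim=5000, seed=0)
        assert adj[0] == pytest.approx(0.1 * 0.3, rel=1e-9)

    def test_rare_conditions_factor_to_one(self):
        p = np.array([1e-4, 1e-4])
        dw = np.array([0.2, 0.3])
        adj = comorbidity_adjust(p, dw, n_sim=50_000, seed=1)
        assert np.allclose(adj, p * dw, rtol=0.02)

    def test_adjusted_never_exceeds_unadjusted(self, rng):
        p = rng.uniform(0.05, 0.4, 5)
        dw = rng.uniform(0.05, 0.6, 5)
        adj = comorbidity_adjust(p, dw, n_sim=20_000, seed=2)
        assert (adj <= p * dw + 1e-12).all()

    def test_dw_of_one_rejected(self):
        with pytest.raises(ValidationError):
            comorbidity_adjust([0.1], [1.0])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.01, 0.95), min_size=1, max_size=6))
    def test_attribution_conserves_combined_weight(self, dws):
        """Per individual, attributed weights sum to the combined weight."""
        attr = attribute_combined_weight(dws)
        assert attr.sum() == pytest.approx(combine_disability_weights(dws), rel=1e-9)

    def test_factors_match_per_cell_adjustment(self):
        p = np.array([[0.2, 0.3]])
        dw = np.array([0.2, 0.3])
        factors = comorbidity_factors(p, dw, n_sim=200_000, seed=3)
        adj = comorbidity_adjust(p[0], dw, n_sim=200_000, seed=3)
        assert np.allclose(factors[0] * dw * p[0], adj, rtol=0.02)
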