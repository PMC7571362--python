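"""Life table construction, envelope rescaling and YLL computation."""

import numpy as np
import pandas as pd
import pytest

from microgbd.codcorrect import (
    LifeTable,
    build_reference_life_table,
    compute_yll,
    scale_to_envelope,
    yll_for_death,
)
from microgbd.draws import ID_COLS, draw_cols, make_draws
from microgbd.errors import ValidationError
from microgbd.registries import CauseHierarchy, CauseNode, default_age_groups

WORKED_LIFE_TABLE = LifeTable.from_pairs([(0.0, 80.0), (25.0, 60.0), (50.0, 38.0)])


class TestLifeTable:
    def test_constant_hazard_matches_exponential(self):
        """mu = 0.02 at every age gives e ~ 1/mu = 50 years within 2%."""
        ags = default_age_groups()
        rates = pd.DataFrame({
            "location_id": "A",
            "age_group_id": [a.age_group_id for a in ags],
            "rate": 0.02,
        })
        pops = pd.DataFrame({"location_id": ["A"], "population": [10_000_000]})
        lt = build_reference_life_table(rates, pops)
        for age in (0.0, 25.0, 60.0, 90.0):
            assert lt.ex_at(age)[0] == pytest.approx(50.0, rel=0.02)

    def test_pointwise_minimum_across_locations(self):
        ags = default_age_groups()
        frames = []
        for loc, r in (("A", 0.01), ("B", 0.02)):
            frames.append(pd.DataFrame({
                "location_id": loc,
                "age_group_id": [a.age_group_id for a in ags],
                "rate": r,
            }))
        rates = pd.concat(frames)
        pops = pd.DataFrame({"location_id": ["A", "B"],
                             "population": [10_000_000, 10_000_000]})
        lt = build_reference_life_table(rates, pops)
        # the envelope of minima is the 0.01 schedule -> e ~ 100 years
        assert lt.ex_at(40.0)[0] == pytest.approx(100.0, rel=0.02)

    def test_small_population_excluded(self):
        ags = default_age_groups()
        frames = []
        for loc, r, pop in (("big", 0.02, 10_000_000), ("small", 0.001, 4_000_000)):
            frames.append(pd.DataFrame({
                "location_id": loc,
                "age_group_id": [a.age_group_id for a in ags],
                "rate": r,
            }))
        rates = pd.concat(frames)
        pops = pd.DataFrame({"location_id": ["big", "small"],
                             "population": [10_000_000, 4_000_000]})
        lt = build_reference_life_table(rates, pops)
        # the low-mortality small location must not drive the minimum
        assert lt.ex_at(40.0)[0] == pytest.approx(50.0, rel=0.02)

    def test_no_eligible_location_errors(self):
        rates = pd.DataFrame({"location_id": ["A"], "age_group_id": ["enn"],
                              "rate": [0.01]})
        pops = pd.DataFrame({"location_id": ["A"], "population": [1_000_000]})
        with pytest.raises(ValidationError):
            build_reference_life_table(rates, pops)


class TestYLL:
    def test_worked_examples(self):
        """One death at 25 with 60 remaining years -> 60 YLLs; at 50 with
        38 remaining -> 38 YLLs."""
        assert yll_for_death(25.0, WORKED_LIFE_TABLE) == pytest.approx(60.0)
        assert yll_for_death(50.0, WORKED_LIFE_TABLE) == pytest.approx(38.0)

    def test_zero_deaths_zero_yll(self):
        cells = pd.DataFrame({"location_id": ["A"], "year": [2000],
                              "age_group_id": ["25-29"], "sex": ["male"]})
        deaths = make_draws(cells, np.zeros((1, 3)))
        out = compute_yll(deaths, WORKED_LIFE_TABLE)
        assert (out[draw_cols(out)].to_numpy() == 0).all()

    def test_linear_in_deaths(self):
        cells = pd.DataFrame({"location_id": ["A"], "year": [2000],
                              "age_group_id": ["25-29"], "sex": ["male"]})
        one = compute_yll(make_draws(cells, np.array([[1.0]])), WORKED_LIFE_TABLE)
        five = compute_yll(make_draws(cells, np.array([[5.0]])), WORKED_LIFE_TABLE)
        assert five["draw_0"].iloc[0] == pytest.approx(5 * one["draw_0"].iloc[0])

    def test_rate_form_divides_by_population(self):
        cells = pd.DataFrame({"location_id": ["A"], "year": [2000],
                              "age_group_id": ["25-29"], "sex": ["male"]})
        deaths = make_draws(cells, np.array([[10.0]]))
        pop = cells.copy()
        pop["population"] = 1000.0
        out = compute_yll(deaths, WORKED_LIFE_TABLE, population=pop)
        counts = compute_yll(deaths, WORKED_LIFE_TABLE)
        assert out["draw_0"].iloc[0] == pytest.approx(counts["draw_0"].iloc[0] / 1000)

    def test_age_outside_table_errors(self):
        lt = LifeTable.from_pairs([(20.0, 50.0)])
        with pytest.raises(ValidationError):
            lt.ex_at(5.0)


def _chain_hierarchy():
    return CauseHierarchy([
        CauseNode("root", "Root", 0, None, True, True),
        CauseNode("g", "Group", 1, "root", True, True),
        CauseNode("a", "A", 2, "g", True, True),
        CauseNode("b", "B", 2, "g", True, True),
    ])


def _cells(n=2):
    return pd.DataFrame({
        "location_id": ["L"] * n, "year": range(2000, 2000 + n),
        "age_group_id": ["a0"] * n, "sex": ["male"] * n,
    })


class TestScaleToEnvelope:
    def test_proportional_scaling(self):
        cells = _cells(1)
        draws = pd.concat([
            make_draws(cells.assign(cause_id="a"), np.array([[2.0]])),
            make_draws(cells.assign(cause_id="b"), np.array([[3.0]])),
        ])
        env = make_draws(cells, np.array([[10.0]]))
        out = scale_to_envelope(draws, _chain_hierarchy(), env)
        vals = out.set_index("cause_id")["draw_0"]
        assert vals["a"] == pytest.approx(4.0)
        assert vals["b"] == pytest.approx(6.0)
        assert vals["g"] == pytest.approx(10.0)

    def test_consistent_tree_unchanged(self):
        cells = _cells(1)
        draws = pd.concat([
            make_draws(cells.assign(cause_id="a"), np.array([[4.0]])),
            make_draws(cells.assign(cause_id="b"), np.array([[6.0]])),
        ])
        env = make_draws(cells, np.array([[10.0]]))
        out = scale_to_envelope(draws, _chain_hierarchy(), env)
        vals = out.set_index("cause_id")["draw_0"]
        assert vals["a"] == pytest.approx(4.0) and vals["b"] == pytest.approx(6.0)

    def test_idempotent(self, world):
        out1 = _random_scaled(world, seed=3)
        hierarchy = world.hierarchy
        env = _random_env(world, seed=3)
        leaves = out1[out1["cause_id"].isin(world.leaf_fatal)]
        out2 = scale_to_envelope(leaves, hierarchy, env)
        m = out1.merge(out2, on=["cause_id"] + ID_COLS, suffixes=("_1", "_2"))
        for d in draw_cols(leaves):
            assert np.allclose(m[f"{d}_1"], m[f"{d}_2"], rtol=1e-9)

    def test_conservation_on_random_fixture(self, world):
        """Brute-force sum check at every level for every draw."""
        out = _random_scaled(world, seed=5)
        env = _random_env(world, seed=5)
        dcols = draw_cols(out)
        by_cause = {c: g.sort_values(ID_COLS)[dcols].to_numpy()
                    for c, g in out.groupby("cause_id")}
        h = world.hierarchy
        for parent, arr in by_cause.items():
            kids = [k.cause_id for k in h.children(parent) if k.cause_id in by_cause]
            if kids:
                total = sum(by_cause[k] for k in kids)
                assert np.allclose(total, arr, rtol=1e-9)
        level1 = sum(by_cause[c] for c in by_cause if h[c].level == 1)
        env_vals = env.sort_values(ID_COLS)[dcols].to_numpy()
        assert np.allclose(level1, env_vals, rtol=1e-9)

    def test_zero_siblings_positive_parent_uniform(self):
        cells = _cells(1)
        draws = pd.concat([
            make_draws(cells.assign(cause_id="a"), np.array([[0.0]])),
            make_draws(cells.assign(cause_id="b"), np.array([[0.0]])),
        ])
        env = make_draws(cells, np.array([[10.0]]))
        out = scale_to_envelope(draws, _chain_hierarchy(), env)
        vals = out.set_index("cause_id")["draw_0"]
        assert vals["a"] == pytest.approx(5.0) and vals["b"] == pytest.approx(5.0)
        assert out.attrs["uniform_redistributed"] > 0

    def test_negative_draw_rejected(self):
        cells = _cells(1)
        draws = make_draws(cells.assign(cause_id="a"), np.array([[-1.0]]))
        env = make_draws(cells, np.array([[10.0]]))
        with pytest.raises(ValidationError):
            scale_to_envelope(draws, _chain_hierarchy(), env)


def _random_env(world, seed):
    rng = np.random.default_rng(seed)
    cells = world.grid.country_cells()
    cells = cells[cells["year"] < 1994]
    return make_draws(cells[ID_COLS], rng.uniform(50, 150, (len(cells), 3)))


def _random_scaled(world, seed):
    rng = np.random.default_rng(seed + 1)
    cells = world.grid.country_cells()
    cells = cells[cells["year"] < 1994]
    frames = [
        make_draws(cells[ID_COLS].assign(cause_id=c),
                   rng.uniform(0, 20, (len(cells), 3)))
        for c in world.leaf_fatal
    ]
    draws = pd.concat(frames, ignore_index=True)
    return scale_to_envelope(draws, world.hierarchy, _random_env(world, seed))
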