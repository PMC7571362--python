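"""Internal consistency of cause-specific mortality, and years of life lost.

Two jobs live here.  First, rescaling ("CoDCorrect"): independent
cause-of-death models do not automatically respect the rule that sub-causes
sum to their parent cause and all causes sum to the all-cause (here:
all-injury) envelope, so a top-down proportional rescale is applied per draw
and per demographic cell.  Second, YLLs: each death is valued at the
residual life expectancy of a reference life table built from the lowest
observed mortality rate at each age across large populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .draws import ID_COLS, draw_cols
from .errors import ValidationError
from .registries import AgeGroup, CauseHierarchy, default_age_groups


# ---------------------------------------------------------------------------
# Reference life table
# ---------------------------------------------------------------------------

@dataclass
class LifeTable:
    """Residual life expectancy e(a) by age interval.

    ``table`` has columns age_start, age_end, ex.  Lookup is by the interval
    containing the age; ages at or beyond the last interval's start use the
    last entry.
    """
    table: pd.DataFrame

    def __post_init__(self):
        t = self.table.sort_values("age_start").reset_index(drop=True)
        if (t["ex"] <= 0).any():
            raise ValidationError("residual life expectancy must be positive")
        self.table = t

    @classmethod
    def from_pairs(cls, pairs: list[tuple[float, float]]) -> "LifeTable":
        """Build from (age, e(age)) points; intervals run to the next age."""
        ages = [a for a, _ in pairs]
        ends = ages[1:] + [float("inf")]
        return cls(pd.DataFrame({
            "age_start": ages,
            "age_end": ends,
            "ex": [e for _, e in pairs],
        }))

    def ex_at(self, age: float | np.ndarray) -> np.ndarray:
        age = np.atleast_1d(np.asarray(age, dtype=float))
        starts = self.table["age_start"].to_numpy()
        if (age < starts[0]).any():
            raise ValidationError("age below the life table's first interval")
        idx = np.searchsorted(starts, age, side="right") - 1
        return self.table["ex"].to_numpy()[idx]

    def write_csv(self, path) -> None:
        self.table.rename(columns={"age_start": "age"})[["age", "ex"]].to_csv(
            path, index=False
        )


def build_reference_life_table(
    mortality_rates: pd.DataFrame,
    populations: pd.DataFrame,
    threshold_pop: float = 5_000_000,
    age_groups: list[AgeGroup] | None = None,
) -> LifeTable:
    """Life table from the per-age minimum mortality rate over large
    populations.

    *mortality_rates* has columns (location_id, age_group_id, rate);
    *populations* has (location_id, population).  Locations at or below
    *threshold_pop* are excluded before taking the per-age minimum.  The
    envelope of minima is turned into an abridged life table with the
    half-interval a(x) convention; the top age group is treated as open with
    e = 1/rate.
    """
    if age_groups is None:
        age_groups = default_age_groups()
    pop = populations.set_index("location_id")["population"]
    eligible = pop[pop > threshold_pop].index
    if len(eligible) == 0:
        raise ValidationError(
            f"no location exceeds the population threshold {threshold_pop:,.0f}"
        )
    rates = mortality_rates[mortality_rates["location_id"].isin(eligible)]
    min_rates = rates.groupby("age_group_id")["rate"].min()

    order = sorted(age_groups, key=lambda a: a.age_start)
    m = np.array([min_rates[a.age_group_id] for a in order])
    if (m <= 0).any():
        raise ValidationError("minimum mortality rates must be positive")
    n = np.array([a.age_end - a.age_start for a in order])

    # abridged life table: q = n*m / (1 + (n - a)*m) with a = n/2
    a = n / 2.0
    q = (n * m) / (1.0 + (n - a) * m)
    q[-1] = 1.0                               # open-ended top interval
    l = np.empty(len(order))
    l[0] = 1.0
    for i in range(1, len(order)):
        l[i] = l[i - 1] * (1.0 - q[i - 1])
    d = l * q
    L = n * l - (n - a) * d                          # deaths live a of the interval
    L[-1] = l[-1] / m[-1]                            # person-years above the top
    T = np.cumsum(L[::-1])[::-1]
    ex = T / l
    return LifeTable(pd.DataFrame({
        "age_start": [ag.age_start for ag in order],
        "age_end": [ag.age_end for ag in order],
        "ex": ex,
    }))


# ---------------------------------------------------------------------------
# Envelope scaling
# ---------------------------------------------------------------------------

def scale_to_envelope(
    cause_death_draws: pd.DataFrame,
    hierarchy: CauseHierarchy,
    envelope: pd.DataFrame,
) -> pd.DataFrame:
    """Top-down proportional rescale so causes sum to parents and parents to
    the all-injury envelope, per draw and cell.

    *cause_death_draws* is a long draw matrix with a cause_id column;
    *envelope* is a draw matrix over the same cells holding all-injury
    deaths.  Aggregate causes missing from the input are synthesised as the
    sum of their children before scaling and returned alongside.  Sibling
    sets summing to zero under a positive parent receive the parent
    uniformly; the count of such repairs is reported in
    ``result.attrs["uniform_redistributed"]``.
    """
    dcols = draw_cols(cause_death_draws)
    if not dcols or draw_cols(envelope) != dcols:
        raise ValidationError("draw columns must match between causes and envelope")

    key = ID_COLS
    env = envelope.sort_values(key).reset_index(drop=True)
    cells = env[key]
    env_vals = env[dcols].to_numpy(float)
    if (env_vals < 0).any():
        raise ValidationError("envelope draws must be non-negative")

    arrays: dict[str, np.ndarray] = {}
    for cause_id, g in cause_death_draws.groupby("cause_id"):
        g = g.sort_values(key).reset_index(drop=True)
        if not g[key].equals(cells):
            raise ValidationError(f"cause {cause_id!r} does not cover the envelope cells")
        vals = g[dcols].to_numpy(float)
        if (vals < 0).any():
            raise ValidationError(f"negative death draws for cause {cause_id!r}")
        arrays[cause_id] = vals

    input_causes = set(arrays)

    # synthesise missing aggregates bottom-up
    for level in sorted({hierarchy[c].level for c in arrays}, reverse=True):
        for cause_id in list(arrays):
            node = hierarchy[cause_id]
            if node.level != level or node.parent_id is None:
                continue
            if node.parent_id not in arrays and hierarchy[node.parent_id].level >= 1:
                sibs = [c.cause_id for c in hierarchy.children(node.parent_id)
                        if c.cause_id in arrays]
                arrays[node.parent_id] = sum(arrays[s] for s in sibs)

    uniform_repairs = 0

    def scale_siblings(sib_ids: list[str], parent_vals: np.ndarray) -> None:
        nonlocal uniform_repairs
        total = sum(arrays[s] for s in sib_ids)
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(total > 0, parent_vals / np.where(total > 0, total, 1.0), 0.0)
        zero_pos = (total == 0) & (parent_vals > 0)
        uniform_repairs += int(zero_pos.sum())
        for s in sib_ids:
            scaled = arrays[s] * factor
            if zero_pos.any():
                scaled = np.where(zero_pos, parent_vals / len(sib_ids), scaled)
            arrays[s] = scaled

    # level-1 siblings scale to the envelope, then cascade down
    level1 = [c for c in arrays if hierarchy[c].level == 1]
    if level1:
        scale_siblings(level1, env_vals)
        frontier = level1
    else:
        frontier = []
    while frontier:
        nxt = []
        for parent in frontier:
            kids = [c.cause_id for c in hierarchy.children(parent) if c.cause_id in arrays]
            if kids:
                scale_siblings(kids, arrays[parent])
                nxt.extend(kids)
        frontier = nxt

    frames = []
    for cause_id in sorted(arrays):
        if cause_id not in input_causes and hierarchy[cause_id].level < 1:
            continue
        f = cells.copy()
        f.insert(0, "cause_id", cause_id)
        f[dcols] = arrays[cause_id]
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["uniform_redistributed"] = uniform_repairs
    out.attrs["synthesised_aggregates"] = sorted(set(arrays) - input_causes)
    return out


# ---------------------------------------------------------------------------
# Years of life lost
# ---------------------------------------------------------------------------

def compute_yll(
    death_draws: pd.DataFrame,
    life_table: LifeTable,
    age_groups: list[AgeGroup] | None = None,
    population: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """YLL draws: deaths x residual life expectancy at the age of death.

    Age at death within an age group is taken at the group midpoint.  If
    *population* (columns ID_COLS + population) is given, the result is a
    YLL rate (divided by person-years); otherwise a count.
    """
    if age_groups is None:
        age_groups = default_age_groups()
    mid = {a.age_group_id: a.midpoint for a in age_groups}
    unknown = set(death_draws["age_group_id"]) - set(mid)
    if unknown:
        raise ValidationError(f"age groups missing from the grid: {sorted(unknown)}")
    ages = death_draws["age_group_id"].map(mid).to_numpy(float)
    ex = life_table.ex_at(ages)
    dcols = draw_cols(death_draws)
    out = death_draws.copy()
    out[dcols] = out[dcols].to_numpy(float) * ex[:, None]
    if population is not None:
        merged = out.merge(population, on=ID_COLS, how="left", validate="m:1")
        if merged["population"].isna().any():
            raise ValidationError("population missing for some cells")
        out[dcols] = out[dcols].to_numpy(float) / merged["population"].to_numpy(float)[:, None]
    return out


def yll_for_death(age_at_death: float, life_table: LifeTable, deaths: float = 1.0) -> float:
    """YLLs attributed to *deaths* deaths at an exact age."""
    return float(deaths * life_table.ex_at(age_at_death)[0])
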