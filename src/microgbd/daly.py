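"""DALY assembly, aggregation and draw summarisation.

DALY = YLL + YLD per draw and cell; causes with no fatal pathway
contribute YLDs alone.  Summaries report the draw mean and a 95%
uncertainty interval from the (2.5, 97.5) percentiles with linear
interpolation between order statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .draws import ID_COLS, draw_cols, summarize
from .errors import ValidationError


def assemble_dalys(yll_draws: pd.DataFrame | None, yld_draws: pd.DataFrame) -> pd.DataFrame:
    """DALY draws as the per-draw, per-cell sum of YLLs and YLDs.

    Indexed by cause_id + ID_COLS.  Causes present only in the YLD input
    (non-fatal-only) pass through with zero YLLs; causes present only in
    the YLL input pass through with zero YLDs.
    """
    keys = ["cause_id"] + ID_COLS
    dcols = draw_cols(yld_draws)
    if yll_draws is None or yll_draws.empty:
        return yld_draws.copy()
    if draw_cols(yll_draws) != dcols:
        raise ValidationError(
            f"draw counts differ: YLL has {len(draw_cols(yll_draws))}, "
            f"YLD has {len(dcols)}"
        )
    yll = yll_draws.set_index(keys)[dcols]
    yld = yld_draws.set_index(keys)[dcols]
    if yll.index.has_duplicates or yld.index.has_duplicates:
        raise ValidationError("duplicate (cause, cell) rows in DALY inputs")
    total = yll.add(yld, fill_value=0.0)
    return total.reset_index()


def summarise_draws(draws: pd.DataFrame, quantiles: tuple[float, float] = (2.5, 97.5)) -> pd.DataFrame:
    """Mean and percentile interval per cell (a BurdenSummary frame)."""
    if len(draw_cols(draws)) < 2:
        raise ValidationError("need at least two draws to summarise")
    lo, hi = quantiles
    return summarize(draws, lower=lo, upper=hi)


def age_standardise(
    rates: pd.DataFrame,
    standard_weights: pd.DataFrame | dict[str, float],
    value_cols: list[str] | None = None,
    group_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Weighted sum of age-specific rates with standard-population weights.

    *standard_weights* maps age_group_id -> weight on the simplex.  The
    result collapses the age dimension within *group_cols* (defaults to all
    non-age identifier columns).
    """
    if isinstance(standard_weights, pd.DataFrame):
        weights = standard_weights.set_index("age_group_id")["weight"].to_dict()
    else:
        weights = dict(standard_weights)
    total = sum(weights.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValidationError(f"standard weights sum to {total}, not 1")
    if value_cols is None:
        value_cols = draw_cols(rates)
        if not value_cols:
            value_cols = [c for c in ("mean", "lower", "upper", "value") if c in rates]
    missing = set(rates["age_group_id"]) - set(weights)
    if missing:
        raise ValidationError(f"no standard weight for age groups {sorted(missing)}")
    if group_cols is None:
        group_cols = [c for c in rates.columns
                      if c not in value_cols and c != "age_group_id"]
    w = rates["age_group_id"].map(weights).to_numpy(float)
    weighted = rates.copy()
    weighted[value_cols] = rates[value_cols].to_numpy(float) * w[:, None]
    return weighted.groupby(group_cols, as_index=False)[value_cols].sum()


def uniform_standard_weights(age_group_ids: list[str]) -> dict[str, float]:
    """Default standard population: equal weight per age group."""
    n = len(age_group_ids)
    return {a: 1.0 / n for a in age_group_ids}


def to_rates(count_draws: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Convert count draws to rates using cell populations."""
    dcols = draw_cols(count_draws)
    merged = count_draws.merge(population, on=ID_COLS, how="left", validate="m:1")
    if merged["population"].isna().any():
        raise ValidationError("population missing for some cells")
    out = count_draws.copy()
    out[dcols] = (count_draws[dcols].to_numpy(float)
                  / merged["population"].to_numpy(float)[:, None])
    return out
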