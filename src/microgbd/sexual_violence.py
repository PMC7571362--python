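"""Past-year sexual-violence prevalence and its short-term disability.

Sexual violence is a non-fatal-only cause: surveys measure the proportion
of the population experiencing at least one episode in the past year.
Surveys differ in case definition; those capturing penetrative violence
only understate the reference definition (any sexual violence), so a
study-level indicator enters the model as a bias covariate and flagged
observations are shifted up to the reference definition.  Prevalence is
modelled logit-linearly with per-capita alcohol consumption as a location
predictor to support data-sparse locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .draws import ID_COLS, draw_cols, make_draws
from .errors import CapabilityError, FitError, ValidationError


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SVPrevalenceFit:
    intercept: float
    alcohol_slope: float
    bias_penetrative: float            # downward shift of penetrative-only rows
    se: pd.Series                      # standard errors of the three params
    cov: np.ndarray                    # coefficient covariance (3 x 3)
    prevalence_draws: pd.DataFrame


def fit_sv_prevalence(
    survey_rows: pd.DataFrame,
    alcohol_covariate: pd.DataFrame,
    grid_cells: pd.DataFrame | None = None,
    n_draws: int = 100,
    seed: int = 0,
) -> SVPrevalenceFit:
    """Binomial logit model with a definition-bias covariate.

    *survey_rows* columns: ID_COLS + prevalence + sample_size +
    penetrative_only (0/1).  *alcohol_covariate* is keyed by
    (location_id, year) with an ``alcohol`` column.  Reference-definition
    rows enter unadjusted; penetrative-only rows are modelled as shifted by
    a bias coefficient, estimated jointly, so their adjusted values always
    sit at or above the raw values.  Predictions (reference definition,
    bias term off) are made on *grid_cells* or on the survey cells; draws
    propagate the coefficient covariance of the fit.
    """
    import statsmodels.api as sm

    rows = survey_rows.reset_index(drop=True)
    if rows.empty:
        raise ValidationError("need at least one survey row")
    if ((rows["prevalence"] < 0) | (rows["prevalence"] > 1)).any():
        raise ValidationError("prevalence must lie in [0, 1]")
    flags = rows["penetrative_only"].astype(int)
    if flags.all():
        raise FitError(
            "all survey rows are penetrative-only: the definition bias is "
            "unidentifiable; supply reference-definition rows or a prior"
        )

    merged = rows.merge(alcohol_covariate, on=["location_id", "year"],
                        how="left", validate="m:1")
    if merged["alcohol"].isna().any():
        raise ValidationError("alcohol covariate missing for some survey cells")

    n = merged["sample_size"].to_numpy(float)
    successes = merged["prevalence"].to_numpy(float) * n
    X = np.column_stack([
        np.ones(len(merged)),
        merged["alcohol"].to_numpy(float),
        -flags.to_numpy(float),        # bias enters as a downward shift
    ])
    res = sm.GLM(
        np.column_stack([successes, n - successes]), X,
        family=sm.families.Binomial(),
    ).fit()
    beta0, beta_alc, beta_bias = res.params
    se = pd.Series(res.bse, index=["intercept", "alcohol", "bias_penetrative"])
    cov = np.asarray(res.cov_params())

    cells = (grid_cells if grid_cells is not None else rows[ID_COLS]).reset_index(drop=True)
    cell_cov = cells.merge(alcohol_covariate, on=["location_id", "year"],
                           how="left", validate="m:1")
    if cell_cov["alcohol"].isna().any():
        raise ValidationError("alcohol covariate missing for some grid cells")
    rng = np.random.default_rng(seed)
    beta_draws = rng.multivariate_normal(res.params, cov, size=n_draws)
    Xp = np.column_stack([
        np.ones(len(cells)),
        cell_cov["alcohol"].to_numpy(float),
        np.zeros(len(cells)),          # reference definition
    ])
    draws = _expit(Xp @ beta_draws.T)
    return SVPrevalenceFit(
        intercept=float(beta0),
        alcohol_slope=float(beta_alc),
        bias_penetrative=float(beta_bias),
        se=se,
        cov=cov,
        prevalence_draws=make_draws(cells[ID_COLS], draws),
    )


def adjust_penetrative_only(
    survey_rows: pd.DataFrame, bias: float
) -> pd.DataFrame:
    """Shift penetrative-only rows up to the reference definition on the
    logit scale; never reduces an observation (negative estimated bias is
    floored at zero shift)."""
    out = survey_rows.copy()
    shift = max(bias, 0.0)
    mask = out["penetrative_only"].astype(bool)
    p = np.clip(out.loc[mask, "prevalence"].to_numpy(float), 1e-12, 1 - 1e-12)
    out.loc[mask, "prevalence"] = _expit(_logit(p) + shift)
    return out


def compute_sv_ylds(
    prevalence_draws: pd.DataFrame,
    dw_short: float,
    population: pd.DataFrame,
    output: str = "yld",
) -> pd.DataFrame:
    """YLD = prevalence x short-term disability weight x population.

    Sexual violence has no fatal estimation pathway: requesting deaths or
    YLLs raises a :class:`CapabilityError`.
    """
    if output in ("deaths", "yll", "csmr", "fatal"):
        raise CapabilityError(
            "sexual violence is non-fatal only: no deaths or YLLs are estimated"
        )
    if output != "yld":
        raise ValidationError(f"unknown output {output!r}")
    if not (0.0 <= dw_short < 1.0):
        raise ValidationError("short-term disability weight must lie in [0, 1)")
    dcols = draw_cols(prevalence_draws)
    merged = prevalence_draws.merge(population, on=ID_COLS, how="left", validate="m:1")
    if merged["population"].isna().any():
        raise ValidationError("population missing for some cells")
    out = prevalence_draws.copy()
    out[dcols] = (prevalence_draws[dcols].to_numpy(float) * dw_short
                  * merged["population"].to_numpy(float)[:, None])
    out.insert(0, "cause_id", "sexual_violence")
    return out
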