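"""Non-fatal observation crosswalks and incidence estimation.

The reference case definition for non-fatal injury incidence is "warranted
or received inpatient care".  Observations reported under other care
categories (outpatient, any formal care, any injury warranting medical
care) are converted to inpatient-equivalents by dividing by an empirically
measured category-to-inpatient incidence ratio; the inverse operation
re-expands inpatient incidence to a category (e.g. outpatient incidence =
ratio x inpatient incidence).

Incidence itself is fit with the same log-linear machinery as the mortality
models (age effects + covariates + nested location random effects).  The
excess-mortality hazard f among the injured is derived from the corrected
cause-specific mortality rate against an acute prevalence proxy, and is
then used to thin incident cases that die within the acute window.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .codem import SubmodelFit, SubmodelSpec, fit_submodel
from .draws import ID_COLS, draw_cols, make_draws
from .errors import CrosswalkError, ValidationError

CATEGORIES = ("inpatient", "outpatient", "formal_care", "warranted_care")

DEFAULT_ACUTE_WINDOW = 28.0 / 365.0      # years; the acute post-injury phase

EPS_PREVALENCE = 1e-8                    # floor for the prevalence proxy
F_MAX = 50.0                             # /year; cap on excess mortality


@dataclass(frozen=True)
class CrosswalkCoefficient:
    cause_id: str
    category: str
    ratio: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.category not in CATEGORIES[1:]:
            raise ValidationError(f"unknown crosswalk category {self.category!r}")
        if self.ratio <= 0:
            raise ValidationError("crosswalk ratio must be positive")
        if not (self.lower <= self.ratio <= self.upper):
            raise ValidationError(
                f"{self.cause_id}/{self.category}: ratio outside its interval"
            )


class CrosswalkTable:
    def __init__(self, coefficients: list[CrosswalkCoefficient]):
        self._by_key = {(c.cause_id, c.category): c for c in coefficients}

    def get(self, cause_id: str, category: str) -> CrosswalkCoefficient:
        try:
            return self._by_key[(cause_id, category)]
        except KeyError:
            raise CrosswalkError(
                f"no crosswalk coefficient for cause {cause_id!r}, "
                f"category {category!r}"
            ) from None

    def __len__(self) -> int:
        return len(self._by_key)


def load_crosswalk_table(config: str | Path | None = None) -> CrosswalkTable:
    """Bundled category-to-inpatient ratios by default."""
    path = (Path(str(resources.files("microgbd.data").joinpath("crosswalks.csv")))
            if config is None else Path(config))
    df = pd.read_csv(path)
    return CrosswalkTable([
        CrosswalkCoefficient(r.cause_id, r.category, float(r.ratio),
                             float(r.lower), float(r.upper))
        for r in df.itertuples()
    ])


def crosswalk_observation(obs: pd.Series | dict, table: CrosswalkTable) -> pd.Series:
    """Convert one observation to the inpatient reference definition.

    Non-inpatient values are divided by the (cause, category) ratio;
    inpatient rows pass through.  The multiplicative adjustment applied is
    recorded in an ``adjustment`` field.
    """
    row = pd.Series(obs).copy()
    category = row["category"]
    if category not in CATEGORIES:
        raise ValidationError(f"unknown care category {category!r}")
    if float(row["value"]) < 0:
        raise ValidationError("incidence value must be non-negative")
    if category == "inpatient":
        row["adjustment"] = 1.0
        return row
    coef = table.get(row["cause_id"], category)
    row["value"] = float(row["value"]) / coef.ratio
    row["adjustment"] = 1.0 / coef.ratio
    row["category"] = "inpatient"
    return row


def crosswalk_frame(observations: pd.DataFrame, table: CrosswalkTable) -> pd.DataFrame:
    """Vectorised :func:`crosswalk_observation` over a frame."""
    out = observations.copy()
    adj = np.ones(len(out))
    for cat in set(out["category"]) - {"inpatient"}:
        mask = out["category"] == cat
        for cause in out.loc[mask, "cause_id"].unique():
            coef = table.get(cause, cat)
            m = mask & (out["cause_id"] == cause)
            adj[m.to_numpy()] = 1.0 / coef.ratio
    out["value"] = out["value"].to_numpy(float) * adj
    out["adjustment"] = adj
    out["category"] = "inpatient"
    return out


def expand_to_category(
    inpatient_value: float | np.ndarray,
    cause_id: str,
    category: str,
    table: CrosswalkTable,
) -> float | np.ndarray:
    """Inverse crosswalk: category incidence = ratio x inpatient incidence."""
    if category == "inpatient":
        return inpatient_value
    return inpatient_value * table.get(cause_id, category).ratio


# ---------------------------------------------------------------------------
# Incidence fitting
# ---------------------------------------------------------------------------

@dataclass
class IncidenceFit:
    """Per-cell incidence and excess-mortality draws for one cause."""
    cause_id: str
    incidence_draws: pd.DataFrame      # events per person-year
    f_draws: pd.DataFrame              # excess mortality hazard per year
    submodel: SubmodelFit


def fit_incidence(
    crosswalked_obs: pd.DataFrame,
    csmr_draws: pd.DataFrame,
    covariates: pd.DataFrame,
    location_meta: pd.DataFrame,
    grid_cells: pd.DataFrame,
    n_draws: int = 100,
    seed: int = 0,
    acute_duration: float = DEFAULT_ACUTE_WINDOW,
    covariate_ids: tuple[str, ...] | None = None,
    kappa: float = 5.0,
) -> IncidenceFit:
    """Log-linear incidence model reconciled with corrected mortality.

    Incidence observations (inpatient-equivalent, columns ID_COLS + cause_id
    + value + sample_size) are fit in log space with age effects, covariates
    and nested location random effects.  Excess mortality is derived as
    f = csmr / max(i x acute_duration, eps), clamped to [0, F_MAX],
    which softly enforces the compartmental consistency between incidence,
    the short acute phase and cause-specific mortality.
    """
    if crosswalked_obs.empty:
        raise ValidationError("need at least one crosswalked observation")
    if (crosswalked_obs["value"] < 0).any():
        raise ValidationError("negative incidence observation")
    cause_id = crosswalked_obs["cause_id"].iloc[0]
    if covariate_ids is None:
        covariate_ids = tuple(
            c for c in covariates.columns if c not in ("location_id", "year")
        )

    # recast incidence observations into the deaths/sample_size schema the
    # shared fitter expects: value = events per person-year
    obs = crosswalked_obs.copy()
    obs["deaths"] = obs["value"].to_numpy(float) * obs["sample_size"].to_numpy(float)
    spec = SubmodelSpec(family="ln_rate", covariate_ids=covariate_ids)
    fit = fit_submodel(obs, covariates, spec, location_meta, kappa=kappa)

    rng = np.random.default_rng(seed)
    cells = grid_cells.reset_index(drop=True)
    mu = fit.predict_transform(cells)
    noise = rng.normal(0.0, np.sqrt(fit.sigma2), size=(len(cells), n_draws))
    i_vals = np.exp(mu[:, None] + noise)
    i_draws = make_draws(cells[ID_COLS], i_vals)

    csmr = csmr_draws.sort_values(ID_COLS).reset_index(drop=True)
    i_sorted = i_draws.sort_values(ID_COLS).reset_index(drop=True)
    if not csmr[ID_COLS].equals(i_sorted[ID_COLS]):
        raise ValidationError("csmr draws do not cover the incidence grid")
    dcols = draw_cols(i_sorted)
    csmr_vals = csmr[[c for c in draw_cols(csmr)]].to_numpy(float)
    if csmr_vals.shape[1] != len(dcols):
        # align draw counts by cycling csmr draws if needed
        reps = int(np.ceil(len(dcols) / csmr_vals.shape[1]))
        csmr_vals = np.tile(csmr_vals, (1, reps))[:, : len(dcols)]
    prev_proxy = np.maximum(i_sorted[dcols].to_numpy(float) * acute_duration,
                            EPS_PREVALENCE)
    f_vals = np.clip(csmr_vals / prev_proxy, 0.0, F_MAX)
    f_draws = make_draws(i_sorted[ID_COLS], f_vals)
    return IncidenceFit(cause_id=cause_id, incidence_draws=i_sorted,
                        f_draws=f_draws, submodel=fit)


def remove_early_deaths(
    incidence_draws: pd.DataFrame,
    f_draws: pd.DataFrame,
    acute_window: float = DEFAULT_ACUTE_WINDOW,
) -> pd.DataFrame:
    """Thin incident cases that die within the acute window:
    i_surv = i * exp(-f * window)."""
    if acute_window <= 0:
        raise ValidationError("acute_window must be positive")
    dcols = draw_cols(incidence_draws)
    i = incidence_draws.sort_values(ID_COLS).reset_index(drop=True)
    f = f_draws.sort_values(ID_COLS).reset_index(drop=True)
    if not i[ID_COLS].equals(f[ID_COLS]):
        raise ValidationError("incidence and excess-mortality draws misaligned")
    iv = i[dcols].to_numpy(float)
    fv = f[draw_cols(f)].to_numpy(float)
    if (iv < 0).any() or (fv < 0).any():
        raise ValidationError("negative incidence or hazard draws")
    out = i.copy()
    out[dcols] = iv * np.exp(-fv * acute_window)
    return out
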