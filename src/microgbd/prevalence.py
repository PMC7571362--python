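"""Short/long-term prevalence, disability weights and YLDs.

Incidence of each cause-nature combination is split into a short-term
stream (resolves within about a year) and a long-term stream (reduced
functional status one year post-injury) by a per-nature probability
p_long.  Short-term prevalence is incidence x average duration, where the
average duration blends treated and untreated durations by the fraction of
the population with access to care (driven by the Healthcare Access and
Quality index).  Long-term prevalence integrates a one-compartment ODE
dP/dt = i(t)(1 - P) - (m(t) + f_n(t)) P with background mortality m and
per-nature excess mortality f_n.  YLDs are prevalence x disability weight,
summed over natures per cause (and over causes per nature), then adjusted
for comorbidity by microsimulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .draws import ID_COLS, draw_cols
from .errors import ValidationError
from .registries import NatureRegistry


# ---------------------------------------------------------------------------
# Short/long split
# ---------------------------------------------------------------------------

def split_short_long(
    cn_incidence: pd.DataFrame,
    registry: NatureRegistry,
    p_long_overrides: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split cause-nature incidence into (short-term, long-term) streams.

    i_lt = p_long * i and i_st = (1 - p_long) * i, so the two streams sum
    back to the input exactly.  p_long comes from the nature registry
    (1 for amputations, 0 for natures with no long-term disability) unless
    overridden.
    """
    overrides = p_long_overrides or {}
    p_long = {}
    for nid in cn_incidence["nature_id"].unique():
        p = overrides.get(nid, registry.p_long(nid))
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"p_long for {nid!r} outside [0,1]: {p}")
        p_long[nid] = p
    dcols = draw_cols(cn_incidence)
    pl = cn_incidence["nature_id"].map(p_long).to_numpy(float)[:, None]
    short = cn_incidence.copy()
    long = cn_incidence.copy()
    vals = cn_incidence[dcols].to_numpy(float)
    short[dcols] = vals * (1.0 - pl)
    long[dcols] = vals * pl
    return short, long


# ---------------------------------------------------------------------------
# Durations and treatment access
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DurationModel:
    """Treated / untreated short-term durations (years) per nature."""
    durations: pd.DataFrame            # nature_id, d_treated, d_untreated

    def __post_init__(self):
        d = self.durations
        if ((d["d_treated"] <= 0) | (d["d_untreated"] <= 0)).any():
            raise ValidationError("durations must be positive")
        if (d["d_treated"] > d["d_untreated"]).any():
            raise ValidationError("treatment cannot lengthen duration")

    def get(self, nature_id: str) -> tuple[float, float]:
        m = self.durations[self.durations["nature_id"] == nature_id]
        if m.empty:
            raise ValidationError(f"no duration for nature {nature_id!r}")
        return float(m["d_treated"].iloc[0]), float(m["d_untreated"].iloc[0])


HAQ_LO, HAQ_HI = 30.0, 95.0


def fraction_treated(haq: float | np.ndarray, lo: float = HAQ_LO, hi: float = HAQ_HI) -> np.ndarray:
    """Fraction of cases with access to treatment: linear ramp in the HAQ
    index, clamped to [0, 1]."""
    haq = np.asarray(haq, dtype=float)
    return np.clip((haq - lo) / (hi - lo), 0.0, 1.0)


def average_duration(
    nature_id: str,
    durations: DurationModel,
    haq: float,
    haq_lo: float = HAQ_LO,
    haq_hi: float = HAQ_HI,
) -> float:
    """d-bar = pi * d_treated + (1 - pi) * d_untreated, pi from the HAQ."""
    d_t, d_u = durations.get(nature_id)
    pi = float(fraction_treated(haq, haq_lo, haq_hi))
    return pi * d_t + (1.0 - pi) * d_u


# ---------------------------------------------------------------------------
# Prevalence
# ---------------------------------------------------------------------------

PREVALENCE_CAP = 0.999


def short_term_prevalence(
    i_st_draws: pd.DataFrame,
    mean_duration: float | pd.Series | np.ndarray,
    cap: float = PREVALENCE_CAP,
) -> pd.DataFrame:
    """P_st = min(i_st x d-bar, cap).

    *mean_duration* may be a scalar or a per-row vector (years).
    """
    d = np.asarray(mean_duration, dtype=float)
    if (d <= 0).any() if d.ndim else d <= 0:
        raise ValidationError("mean duration must be positive")
    dcols = draw_cols(i_st_draws)
    out = i_st_draws.copy()
    vals = out[dcols].to_numpy(float)
    d_col = d[:, None] if d.ndim else d
    out[dcols] = np.minimum(vals * d_col, cap)
    return out


def _integrate_years(
    i: np.ndarray, m: np.ndarray, f: np.ndarray, P0: np.ndarray, step: float
) -> np.ndarray:
    """RK4 over years for dP/dt = i(1-P) - (m+f)P, piecewise-constant rates.

    Shapes: i, m, f are (years, ...) broadcastable to each other; P0 is the
    trailing shape.  Returns prevalence at the end of each year.
    """
    steps_per_year = max(int(round(1.0 / step)), 1)
    h = 1.0 / steps_per_year
    P = np.array(P0, dtype=float)
    out = np.empty(np.broadcast_shapes(i.shape, m.shape, f.shape), dtype=float)
    n_years = out.shape[0]
    for yr in range(n_years):
        iy = np.broadcast_to(i[yr], P.shape)
        hy = np.broadcast_to(m[yr] + f[yr], P.shape)

        def dP(p):
            return iy * (1.0 - p) - hy * p

        for _ in range(steps_per_year):
            k1 = dP(P)
            k2 = dP(P + 0.5 * h * k1)
            k3 = dP(P + 0.5 * h * k2)
            k4 = dP(P + h * k3)
            P = P + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        P = np.clip(P, 0.0, 1.0 - 1e-12)
        out[yr] = P
    return out


def solve_long_term_ode(
    incidence: np.ndarray,
    background_mortality: np.ndarray,
    excess_mortality: np.ndarray,
    step: float = 0.1,
    initial: float | None = None,
) -> np.ndarray:
    """Integrate the long-term compartment for one series.

    Inputs are per-year rate arrays.  The initial condition defaults to the
    steady state of the first year's rates, i / (i + m + f), since the
    pre-study epidemic history is not modelled.  Returns end-of-year
    prevalence.
    """
    i = np.asarray(incidence, float)
    m = np.asarray(background_mortality, float)
    f = np.asarray(excess_mortality, float)
    if not (np.isfinite(i).all() and np.isfinite(m).all() and np.isfinite(f).all()):
        raise ValidationError("non-finite hazard in long-term ODE inputs")
    if (i < 0).any() or (m < 0).any() or (f < 0).any():
        raise ValidationError("hazards must be non-negative")
    if initial is None:
        denom = i[0] + m[0] + f[0]
        P0 = float(i[0] / denom) if denom > 0 else 0.0
    else:
        P0 = float(initial)
    return _integrate_years(i[:, None], m[:, None], f[:, None],
                            np.array([P0]), step)[:, 0]


def long_term_prevalence(
    i_lt_draws: pd.DataFrame,
    background_mortality: pd.DataFrame,
    nature_excess_mortality: dict[str, float] | None = None,
    step: float = 0.1,
) -> pd.DataFrame:
    """Long-term prevalence draws from the compartmental ODE.

    *i_lt_draws* is a long draw matrix with cause_id and nature_id covering
    a complete, common year range per series; the ODE is integrated over
    years independently for every (cause, nature, location, age, sex)
    series and draw, vectorised across series.  *background_mortality* has
    ID_COLS + ``rate``; *nature_excess_mortality* maps nature_id -> hazard
    (e.g. brain and spinal-cord injuries).
    """
    excess = nature_excess_mortality or {}
    dcols = draw_cols(i_lt_draws)
    series_cols = ["cause_id", "nature_id", "location_id", "age_group_id", "sex"]
    df = i_lt_draws.merge(background_mortality, on=ID_COLS, how="left", validate="m:1")
    if df["rate"].isna().any():
        raise ValidationError("background mortality missing for some cells")
    df = df.sort_values(series_cols + ["year"]).reset_index(drop=True)
    years = np.sort(df["year"].unique())
    n_series, rem = divmod(len(df), len(years))
    if rem or not (df["year"].to_numpy().reshape(n_series, len(years)) == years).all():
        raise ValidationError("every series must cover the same year range")

    ivals = df[dcols].to_numpy(float)
    if (ivals < 0).any():
        raise ValidationError("negative long-term incidence draws")
    i3 = ivals.reshape(n_series, len(years), len(dcols)).transpose(1, 0, 2)
    m3 = df["rate"].to_numpy(float).reshape(n_series, len(years)).T[:, :, None]
    f_series = df.groupby(series_cols, sort=True)["nature_id"].first().map(
        lambda n: excess.get(n, 0.0)
    ).to_numpy(float)
    f3 = np.broadcast_to(f_series[None, :, None], (len(years), n_series, 1))
    denom = i3[0] + m3[0] + f3[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        P0 = np.where(denom > 0, i3[0] / np.where(denom > 0, denom, 1.0), 0.0)
    prev = _integrate_years(i3, m3, f3, P0, step)       # (years, series, draws)
    out = df[["cause_id", "nature_id"] + ID_COLS].copy()
    out[dcols] = prev.transpose(1, 0, 2).reshape(len(df), len(dcols))
    return out


def reconcile_streams(p_st: pd.DataFrame, p_lt: pd.DataFrame) -> pd.DataFrame:
    """P_lt_adj = max(P_lt - P_st, 0): remove person-time already counted in
    the short-term stream.  Floored cells are counted in
    ``result.attrs["floored_cells"]``."""
    keys = ["cause_id", "nature_id"] + ID_COLS
    dcols = draw_cols(p_lt)
    st = p_st.sort_values(keys).reset_index(drop=True)
    lt = p_lt.sort_values(keys).reset_index(drop=True)
    if not st[keys].equals(lt[keys]):
        raise ValidationError("short- and long-term streams misaligned")
    diff = lt[dcols].to_numpy(float) - st[dcols].to_numpy(float)
    floored = int((diff < 0).any(axis=1).sum())
    out = lt.copy()
    out[dcols] = np.maximum(diff, 0.0)
    out.attrs["floored_cells"] = floored
    return out


# ---------------------------------------------------------------------------
# YLDs
# ---------------------------------------------------------------------------

def compute_yld_table(
    p_st: pd.DataFrame,
    p_lt_adj: pd.DataFrame,
    registry: NatureRegistry,
    population: pd.DataFrame,
    long_term_dw: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Full cause-nature YLD draw table:
    YLD = (P_st x dw_short + P_lt x dw_long) x population."""
    keys = ["cause_id", "nature_id"] + ID_COLS
    dcols = draw_cols(p_st)
    st = p_st.sort_values(keys).reset_index(drop=True)
    lt = p_lt_adj.sort_values(keys).reset_index(drop=True)
    if not st[keys].equals(lt[keys]):
        raise ValidationError("prevalence streams misaligned")

    dw_long_map = {}
    dw_short_map = {}
    for nid in st["nature_id"].unique():
        cat = registry.get(nid)
        dw_short_map[nid] = 0.0 if cat.dw_short is None else cat.dw_short
        dw = (long_term_dw or {}).get(nid, cat.dw_long)
        if dw is None:
            if not cat.no_long_term:
                raise ValidationError(f"no long-term weight for {nid!r}")
            dw = 0.0
        dw_long_map[nid] = dw

    ws = st["nature_id"].map(dw_short_map).to_numpy(float)[:, None]
    wl = lt["nature_id"].map(dw_long_map).to_numpy(float)[:, None]
    pop = st.merge(population, on=ID_COLS, how="left", validate="m:1")["population"]
    if pop.isna().any():
        raise ValidationError("population missing for some cells")
    yld_vals = (st[dcols].to_numpy(float) * ws
                + lt[dcols].to_numpy(float) * wl) * pop.to_numpy(float)[:, None]
    full = st[keys].copy()
    full[dcols] = yld_vals
    return full


def compute_ylds(
    p_st: pd.DataFrame,
    p_lt_adj: pd.DataFrame,
    registry: NatureRegistry,
    population: pd.DataFrame,
    long_term_dw: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """YLD draws by cause and by nature.

    The two results are the marginals of the same cause-nature YLD array
    (see :func:`compute_yld_table`), so they always agree when summed the
    other way.  *long_term_dw* overrides the registry's default long-term
    weights, e.g. with a location/year-specific table collapsed to natures.
    """
    full = compute_yld_table(p_st, p_lt_adj, registry, population, long_term_dw)
    dcols = draw_cols(full)
    by_cause = full.groupby(["cause_id"] + ID_COLS, as_index=False)[dcols].sum()
    by_nature = full.groupby(["nature_id"] + ID_COLS, as_index=False)[dcols].sum()
    return by_cause, by_nature


# ---------------------------------------------------------------------------
# Comorbidity adjustment
# ---------------------------------------------------------------------------

def combine_disability_weights(dws: np.ndarray) -> float:
    """Combined weight of co-occurring conditions: 1 - prod(1 - dw_k)."""
    return float(1.0 - np.prod(1.0 - np.asarray(dws, float)))


def attribute_combined_weight(dws: np.ndarray) -> np.ndarray:
    """Split the combined multiplicative weight across conditions in
    proportion to their individual weights: dw_k / sum(dw) * combined."""
    dws = np.asarray(dws, float)
    total = dws.sum()
    if total == 0:
        return np.zeros_like(dws)
    return dws / total * combine_disability_weights(dws)


def comorbidity_adjust(
    condition_prevalences: np.ndarray,
    condition_dws: np.ndarray,
    n_sim: int = 20_000,
    seed: int = 0,
) -> np.ndarray:
    """Comorbidity-adjusted YLD rate per condition by microsimulation.

    Simulates *n_sim* individuals with independent condition indicators;
    an individual with several conditions gets the multiplicative combined
    weight, attributed to each condition in proportion to its own weight.
    Returns the per-condition mean attributed weight (among individuals
    carrying the condition) times prevalence, i.e. an adjusted YLD rate
    that is always <= dw_k * prev_k.  Conditions never sampled in the
    simulation fall back to their unadjusted weight.
    """
    p = np.asarray(condition_prevalences, float)
    dw = np.asarray(condition_dws, float)
    if n_sim < 1000:
        raise ValidationError("n_sim must be >= 1000")
    if ((p < 0) | (p >= 1)).any():
        raise ValidationError("prevalences must lie in [0, 1)")
    if (dw >= 1.0).any():
        raise ValidationError(
            "a disability weight of 1 makes proportional attribution undefined"
        )
    if (dw < 0).any():
        raise ValidationError("disability weights must be non-negative")
    rng = np.random.default_rng(seed)
    has = rng.random((n_sim, len(p))) < p            # independent indicators
    log1m = np.log1p(-dw)
    combined = 1.0 - np.exp(has @ log1m)             # 1 - prod(1-dw) per person
    dw_sum = has @ dw
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(dw_sum > 0, combined / dw_sum, 0.0)
    adjusted = np.empty(len(p))
    for k in range(len(p)):
        carriers = has[:, k]
        if not carriers.any():
            adjusted[k] = dw[k] * p[k]               # unadjusted fallback
            continue
        mean_attr = float((dw[k] * scale[carriers]).mean())
        adjusted[k] = mean_attr * p[k]
    return adjusted


def comorbidity_factors(
    prevalences: np.ndarray,
    dws: np.ndarray,
    n_sim: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell, per-condition comorbidity attenuation factors.

    *prevalences* is (cells x conditions); *dws* per condition.  For each
    cell a cohort of n_sim individuals with independent condition
    indicators is simulated; the factor for condition k is the mean
    attributed weight among carriers divided by dw_k, i.e. the multiplier
    that turns an unadjusted YLD into its comorbidity-adjusted value.
    Cells where a condition was never sampled keep factor 1.
    """
    p = np.asarray(prevalences, float)
    dw = np.asarray(dws, float)
    if ((p < 0) | (p >= 1)).any():
        raise ValidationError("prevalences must lie in [0, 1)")
    if ((dw < 0) | (dw >= 1)).any():
        raise ValidationError("disability weights must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_cells, K = p.shape
    has = rng.random((n_cells, n_sim, K)) < p[:, None, :]
    log1m = np.log1p(-dw)
    combined = 1.0 - np.exp(has @ log1m)              # (cells, n_sim)
    dw_sum = has @ dw
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(dw_sum > 0, combined / dw_sum, 0.0)
    carriers = has.sum(axis=1)                         # (cells, K)
    attr_sum = np.einsum("csk,cs->ck", has, scale)
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = np.where(carriers > 0, attr_sum / np.maximum(carriers, 1), 1.0)
    return factors
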