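"""Synthetic world with known ground truth, and input-table simulators.

The generator builds a fully specified miniature estimation problem: a
nested location hierarchy (2 super-regions x 2 regions x 2 countries), an
8-group age grid, both sexes, years 1990-2017, six injury causes spanning
the shapes of the cause tree (one parent with sub-causes, one
non-fatal-only cause) and eight natures of injury drawn from the bundled
registry.  True cause-specific mortality and incidence surfaces are
log-linear in two bundled covariates with nested location random effects,
so the estimation machinery's model family can represent the truth; every
simulator (vital registration, hospital, dual-coded, sexual-violence
surveys) draws Poisson / multinomial / binomial observations around that
truth, or emits exact expected values in the infinite-population limit
(``expected=True``).

The world also computes its own true YLL / YLD / DALY surfaces with the
same structural formulas the pipeline applies, which is what makes
end-to-end identity testing possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codcorrect import LifeTable, build_reference_life_table
from .crosswalk import DEFAULT_ACUTE_WINDOW, EPS_PREVALENCE, F_MAX
from .draws import ID_COLS, make_draws
from .errors import ValidationError
from .prevalence import _integrate_years, fraction_treated
from .registries import (
    AgeGroup,
    CauseHierarchy,
    CauseNode,
    DemographicGrid,
    Location,
    NatureRegistry,
    build_nature_registry,
)

DESK_NATURES = [
    "sci_neck", "fx_hip", "fx_pelvis", "tbi_minor",
    "open_wound", "contusion", "amp_lower_unilateral", "superficial",
]

# long-term excess-mortality hazards (/year) for severe natures
DESK_EXCESS_MORTALITY = {"sci_neck": 0.05, "amp_lower_unilateral": 0.01}


@dataclass
class WorldConfig:
    """Desk-scale study conditions.

    Defaults are the conditions every recovery and identity test runs
    under; ``full_registries`` swaps in the complete 38-cause / 47-nature
    bundled registries.
    """
    n_super_regions: int = 2
    n_regions_per: int = 2
    n_countries_per: int = 2
    year_start: int = 1990
    year_end: int = 2017
    natures: tuple[str, ...] = tuple(DESK_NATURES)
    re_sd: float = 0.1                 # country random-effect sd (log scale)
    completeness: float = 1.0
    acute_window: float = DEFAULT_ACUTE_WINDOW
    sv_intercept: float = -3.5         # logit past-year prevalence ~ 0.03
    sv_alcohol_slope: float = 0.05     # per litre of alcohol per capita
    sv_bias_penetrative: float = 0.4   # logit shift of penetrative-only surveys
    sv_dw: float = 0.10                # placeholder short-term weight
    full_registries: bool = False

    def __post_init__(self):
        if self.year_end < self.year_start:
            raise ValidationError("year_end before year_start")
        if not (0 < self.completeness <= 1):
            raise ValidationError("completeness must be in (0, 1]")
        if self.re_sd < 0:
            raise ValidationError("re_sd must be >= 0")


def _desk_hierarchy() -> CauseHierarchy:
    """Six estimated causes: road (with two sub-causes), falls, drowning and
    a non-fatal-only cause (foreign body in eyes)."""
    nodes = [
        CauseNode("all_injuries", "All injuries", 0, None, True, True),
        CauseNode("transport", "Transport injuries", 1, "all_injuries", True, True),
        CauseNode("unintentional", "Unintentional injuries", 1, "all_injuries", True, True),
        CauseNode("road", "Road injuries", 2, "transport", True, True),
        CauseNode("pedestrian_road", "Pedestrian road injuries", 3, "road", True, True),
        CauseNode("other_road", "Other road injuries", 3, "road", True, True),
        CauseNode("falls", "Falls", 2, "unintentional", True, True),
        CauseNode("drowning", "Drowning", 2, "unintentional", True, True),
        CauseNode("fb_eyes", "Foreign body in eyes", 2, "unintentional", False, True),
    ]
    return CauseHierarchy(nodes)


def _desk_age_groups() -> list[AgeGroup]:
    bounds = [0, 5, 15, 25, 35, 45, 55, 65, 95]
    return [
        AgeGroup(f"a{i}", f"{lo} to {hi}", float(lo), float(hi))
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
    ]


@dataclass
class SyntheticWorld:
    """Ground truth for every pipeline input; bit-reproducible from
    (config, seed)."""
    config: WorldConfig
    seed: int
    hierarchy: CauseHierarchy
    natures: NatureRegistry
    grid: DemographicGrid
    covariates: pd.DataFrame            # location_id, year, x1, x2
    alcohol: pd.DataFrame               # location_id, year, alcohol
    haq: pd.DataFrame                   # location_id, year, haq
    background_mortality: pd.DataFrame  # ID_COLS + rate (all-cause)
    csmr_params: dict = field(repr=False)
    incidence_params: dict = field(repr=False)
    crosswalk_ratios: dict = field(repr=False)    # (cause, category) -> ratio
    cause_nature_probs: pd.DataFrame = field(repr=False)
    durations: pd.DataFrame = field(repr=False)   # nature_id, d_treated, d_untreated
    excess_mortality: dict = field(repr=False)    # nature_id -> hazard
    leaf_fatal: list = field(default_factory=list)
    leaf_nonfatal: list = field(default_factory=list)

    # -- truth surfaces ----------------------------------------------------

    def _surface(self, params: dict, cause_id: str) -> pd.DataFrame:
        p = params[cause_id]
        cells = self.grid.country_cells()
        cov = cells.merge(self.covariates, on=["location_id", "year"], how="left")
        log_rate = (
            p["b0"]
            + cov["age_group_id"].map(p["age_effects"]).to_numpy(float)
            + np.where(cov["sex"] == "male", p["sex_male"], 0.0)
            + p["b1"] * cov["x1"].to_numpy(float)
            + p["b2"] * cov["x2"].to_numpy(float)
            + cov["location_id"].map(p["re"]).to_numpy(float)
        )
        out = cells.copy()
        out["rate"] = np.exp(log_rate)
        return out

    def true_csmr(self, cause_id: str) -> pd.DataFrame:
        """True cause-specific mortality rate per cell (leaf fatal causes)."""
        return self._surface(self.csmr_params, cause_id)

    def true_incidence(self, cause_id: str) -> pd.DataFrame:
        """True inpatient incidence per cell (non-fatal causes)."""
        return self._surface(self.incidence_params, cause_id)

    def population(self) -> pd.DataFrame:
        pops = self.grid.population_frame()
        return pops[pops["location_id"].isin(self.grid.countries)]

    def envelope_deaths(self) -> pd.DataFrame:
        """True all-injury deaths per cell: the sum over leaf fatal causes."""
        pop = self.population().set_index(ID_COLS)["population"]
        total = None
        for cause in self.leaf_fatal:
            s = self.true_csmr(cause).set_index(ID_COLS)["rate"] * pop
            total = s if total is None else total + s
        return total.rename("deaths").reset_index()

    def life_table(self) -> LifeTable:
        """Reference life table from per-location minimum all-cause rates."""
        rates = (
            self.background_mortality
            .groupby(["location_id", "age_group_id"], as_index=False)["rate"].mean()
        )
        pops = (
            self.population().groupby("location_id", as_index=False)["population"].sum()
        )
        return build_reference_life_table(
            rates, pops, threshold_pop=5_000_000, age_groups=self.grid.age_groups
        )

    # -- analytic truth for the end-to-end identity ------------------------

    def true_yll(self) -> pd.DataFrame:
        """True YLL counts per leaf fatal cause and cell."""
        lt = self.life_table()
        mid = {a.age_group_id: a.midpoint for a in self.grid.age_groups}
        pop = self.population().set_index(ID_COLS)["population"]
        frames = []
        for cause in self.leaf_fatal:
            df = self.true_csmr(cause)
            deaths = df["rate"].to_numpy(float) * pop.reindex(pd.MultiIndex.from_frame(df[ID_COLS])).to_numpy(float)
            ex = lt.ex_at(df["age_group_id"].map(mid).to_numpy(float))
            out = df[ID_COLS].copy()
            out.insert(0, "cause_id", cause)
            out["value"] = deaths * ex
            frames.append(out)
        return pd.concat(frames, ignore_index=True)

    def true_yld(self) -> pd.DataFrame:
        """True YLD counts per non-fatal cause and cell (pre-comorbidity),
        built with the same structural formulas the pipeline applies."""
        pop = self.population().set_index(ID_COLS)["population"]
        years = np.array(self.grid.years)
        bg = self.background_mortality.set_index(ID_COLS)["rate"]
        probs = self.cause_nature_probs.set_index(
            ["cause_id", "age_group_id", "sex"]
        )
        dur = self.durations.set_index("nature_id")
        haq = self.haq.set_index(["location_id", "year"])["haq"]
        frames = []
        for cause in self.leaf_nonfatal:
            inc = self.true_incidence(cause).set_index(ID_COLS)["rate"]
            csmr = (self.true_csmr(cause).set_index(ID_COLS)["rate"]
                    if cause in self.csmr_params else inc * 0.0)
            r_out = self.crosswalk_ratios[(cause, "outpatient")]
            total_i = inc * (1.0 + r_out)
            f_acute = np.clip(
                csmr / np.maximum(inc * self.config.acute_window, EPS_PREVALENCE),
                0.0, F_MAX,
            )
            i_surv = total_i * np.exp(-f_acute * self.config.acute_window)

            # per (location, age, sex) series over years
            yld = pd.Series(0.0, index=i_surv.index)
            for nid in self.natures.ids():
                cat = self.natures.get(nid)
                p_n = probs.loc[cause][nid]      # indexed by (age, sex)
                keys = i_surv.index.to_frame(index=False)
                p_vec = p_n.reindex(
                    pd.MultiIndex.from_frame(keys[["age_group_id", "sex"]])
                ).to_numpy(float)
                i_n = i_surv.to_numpy(float) * p_vec
                p_long = cat.p_long_default
                i_st = i_n * (1.0 - p_long)
                i_lt = i_n * p_long

                pi = fraction_treated(
                    haq.reindex(
                        pd.MultiIndex.from_frame(keys[["location_id", "year"]])
                    ).to_numpy(float)
                )
                dbar = (pi * dur.loc[nid, "d_treated"]
                        + (1.0 - pi) * dur.loc[nid, "d_untreated"])
                p_st = np.minimum(i_st * dbar, 0.999)

                # long-term ODE, vectorised across (location, age, sex) series
                p_lt = np.zeros(len(keys))
                if p_long > 0:
                    dfk = keys.copy()
                    dfk["i_lt"] = i_lt
                    dfk["m"] = bg.reindex(pd.MultiIndex.from_frame(keys[ID_COLS])).to_numpy(float)
                    f_n = self.excess_mortality.get(nid, 0.0)
                    order = dfk.sort_values(["location_id", "age_group_id", "sex", "year"])
                    n_y = len(years)
                    n_series = len(order) // n_y
                    i3 = order["i_lt"].to_numpy(float).reshape(n_series, n_y).T
                    m3 = order["m"].to_numpy(float).reshape(n_series, n_y).T
                    f3 = np.full_like(m3, f_n)
                    denom = i3[0] + m3[0] + f3[0]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        P0 = np.where(denom > 0, i3[0] / np.where(denom > 0, denom, 1.0), 0.0)
                    sol = _integrate_years(i3, m3, f3, P0, 0.1)   # (years, series)
                    p_lt[order.index.to_numpy()] = sol.T.reshape(-1)
                p_lt_adj = np.maximum(p_lt - p_st, 0.0)
                dw_s = cat.dw_short or 0.0
                dw_l = cat.dw_long or 0.0
                yld = yld + (p_st * dw_s + p_lt_adj * dw_l) * pop.reindex(i_surv.index).to_numpy(float)
            out = i_surv.index.to_frame(index=False)
            out.insert(0, "cause_id", cause)
            out["value"] = yld.to_numpy()
            frames.append(out)
        return pd.concat(frames, ignore_index=True)

    def true_sv_prevalence(self) -> pd.DataFrame:
        cells = self.grid.country_cells()
        alc = cells.merge(self.alcohol, on=["location_id", "year"], how="left")["alcohol"]
        logit = (self.config.sv_intercept
                 + self.config.sv_alcohol_slope * alc.to_numpy(float))
        out = cells.copy()
        out["prevalence"] = 1.0 / (1.0 + np.exp(-logit))
        return out

    def true_sv_yld(self) -> pd.DataFrame:
        pop = self.population().set_index(ID_COLS)["population"]
        prev = self.true_sv_prevalence()
        out = prev[ID_COLS].copy()
        out.insert(0, "cause_id", "sexual_violence")
        out["value"] = (prev["prevalence"].to_numpy(float)
                        * self.config.sv_dw
                        * pop.reindex(pd.MultiIndex.from_frame(prev[ID_COLS])).to_numpy(float))
        return out

    def true_daly(self) -> pd.DataFrame:
        """True DALY counts = YLL + YLD (including sexual violence YLDs)."""
        yll = self.true_yll().set_index(["cause_id"] + ID_COLS)["value"]
        yld = pd.concat([self.true_yld(), self.true_sv_yld()]).set_index(
            ["cause_id"] + ID_COLS
        )["value"]
        return yll.add(yld, fill_value=0.0).rename("value").reset_index()


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Deterministically build a :class:`SyntheticWorld` from (config, seed)."""
    cfg = config or WorldConfig()
    rng = np.random.default_rng(seed)

    # locations: nested codes SR / SR.R / SR.R.C
    locations, countries = [], []
    for s in range(cfg.n_super_regions):
        sr = f"SR{s}"
        locations.append(Location(sr, 0, None))
        for r in range(cfg.n_regions_per):
            reg = f"{sr}_R{r}"
            locations.append(Location(reg, 1, sr))
            for c in range(cfg.n_countries_per):
                cid = f"{reg}_C{c}"
                locations.append(Location(cid, 2, reg))
                countries.append(cid)

    age_groups = _desk_age_groups()
    years = range(cfg.year_start, cfg.year_end + 1)

    # populations: varied country sizes, fixed pyramid, constant over time
    age_shares = np.array([0.12, 0.18, 0.16, 0.15, 0.13, 0.11, 0.09, 0.06])
    age_shares = age_shares / age_shares.sum()
    totals = {c: float(rng.uniform(2e6, 6e7)) for c in countries}
    pop_rows = []
    for c in countries:
        for y in years:
            for ag, share in zip(age_groups, age_shares):
                for sex in ("male", "female"):
                    pop_rows.append((c, y, ag.age_group_id, sex,
                                     totals[c] * share * 0.5))
    populations = pd.DataFrame(
        pop_rows, columns=["location_id", "year", "age_group_id", "sex", "population"]
    )
    grid = DemographicGrid(locations, age_groups, years, populations)

    # covariates per (country, year): smooth trends plus country offsets
    cov_rows = []
    for c in countries:
        o1, o2 = rng.normal(0, 1, 2)
        for t, y in enumerate(years):
            cov_rows.append((c, y, o1 + 0.04 * t, o2 + rng.normal(0, 0.15)))
    covariates = pd.DataFrame(cov_rows, columns=["location_id", "year", "x1", "x2"])

    alcohol = covariates[["location_id", "year"]].copy()
    alc_base = {c: float(rng.uniform(2.0, 12.0)) for c in countries}
    alcohol["alcohol"] = [
        alc_base[c] for c in alcohol["location_id"]
    ]

    haq = covariates[["location_id", "year"]].copy()
    haq_base = {c: float(rng.uniform(35.0, 85.0)) for c in countries}
    haq["haq"] = [
        min(haq_base[c] + 0.3 * (y - cfg.year_start), 95.0)
        for c, y in zip(haq["location_id"], haq["year"])
    ]

    hierarchy = _desk_hierarchy()
    nature_source = build_nature_registry()
    if cfg.full_registries:
        natures = nature_source
    else:
        natures = NatureRegistry([nature_source.get(n) for n in cfg.natures])

    leaf_fatal = ["pedestrian_road", "other_road", "falls", "drowning"]
    leaf_nonfatal = ["pedestrian_road", "other_road", "falls", "drowning", "fb_eyes"]

    # true age patterns: mortality rises with age; incidence peaks young-adult
    ages = [a.age_group_id for a in age_groups]

    def _params(base_lo: float, base_hi: float, age_slope: float) -> dict:
        b0 = float(rng.uniform(base_lo, base_hi))
        age_eff = {a: age_slope * k + float(rng.normal(0, 0.1))
                   for k, a in enumerate(ages)}
        return {
            "b0": b0,
            "age_effects": age_eff,
            "sex_male": float(rng.uniform(0.1, 0.5)),
            "b1": float(rng.uniform(-0.4, 0.4)),
            "b2": float(rng.uniform(-0.4, 0.4)),
            "re": {c: float(rng.normal(0, cfg.re_sd)) for c in countries},
        }

    csmr_params = {c: _params(-10.5, -9.0, 0.25) for c in leaf_fatal}

    # category-to-inpatient ratios: bundled values where they exist
    from .crosswalk import load_crosswalk_table
    bundled = load_crosswalk_table()
    crosswalk_ratios = {}
    for cause in leaf_nonfatal:
        try:
            crosswalk_ratios[(cause, "outpatient")] = bundled.get(cause, "outpatient").ratio
        except Exception:
            crosswalk_ratios[(cause, "outpatient")] = 3.0

    # inpatient intercepts chosen so the *total* incidence (inpatient plus
    # expanded outpatient) lands near a realistic 0.005-0.03 events per
    # person-year whatever the cause's outpatient multiplier is
    incidence_params = {}
    for cause in leaf_nonfatal:
        target_total = float(rng.uniform(0.005, 0.03))
        b0 = float(np.log(target_total / (1.0 + crosswalk_ratios[(cause, "outpatient")])))
        p = _params(b0 - 0.1, b0 + 0.1, 0.05)
        incidence_params[cause] = p

    # true most-disabling-nature probabilities per (cause, age, sex): severe
    # natures (high disability weight) are rare outcomes, as in dual-coded
    # clinical data, so the prior concentration decays with the weight
    nids = natures.ids()
    severity = np.array([
        max(natures.get(n).dw_short or 0.0, natures.get(n).dw_long or 0.0)
        for n in nids
    ])
    base_alpha = 8.0 * np.exp(-8.0 * severity) + 0.05
    prob_rows = []
    for cause in leaf_nonfatal:
        base = rng.dirichlet(base_alpha)
        for ag in ages:
            for sex in ("male", "female"):
                p = rng.dirichlet(base * 60.0 + 0.05)
                prob_rows.append({"cause_id": cause, "age_group_id": ag,
                                  "sex": sex, **dict(zip(nids, p))})
    cause_nature_probs = pd.DataFrame(prob_rows)

    durations = pd.DataFrame({
        "nature_id": nids,
        "d_treated": rng.uniform(0.02, 0.3, len(nids)),
    })
    durations["d_untreated"] = durations["d_treated"] * rng.uniform(1.2, 2.5, len(nids))

    # background all-cause mortality: U-shaped in age, country level shifts
    base_curve = np.array([-4.5, -6.5, -6.2, -5.8, -5.2, -4.5, -3.8, -2.5])
    bg_rows = []
    for c in countries:
        shift = float(rng.normal(0, 0.05))
        for y in years:
            for k, ag in enumerate(age_groups):
                for sex in ("male", "female"):
                    lr = base_curve[k] + shift + (0.1 if sex == "male" else 0.0)
                    bg_rows.append((c, y, ag.age_group_id, sex, float(np.exp(lr))))
    background = pd.DataFrame(
        bg_rows, columns=["location_id", "year", "age_group_id", "sex", "rate"]
    )

    return SyntheticWorld(
        config=cfg, seed=seed, hierarchy=hierarchy, natures=natures, grid=grid,
        covariates=covariates, alcohol=alcohol, haq=haq,
        background_mortality=background,
        csmr_params=csmr_params, incidence_params=incidence_params,
        crosswalk_ratios=crosswalk_ratios, cause_nature_probs=cause_nature_probs,
        durations=durations, excess_mortality=dict(DESK_EXCESS_MORTALITY),
        leaf_fatal=leaf_fatal, leaf_nonfatal=leaf_nonfatal,
    )


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def simulate_vr(
    world: SyntheticWorld,
    completeness: float | None = None,
    seed: int = 1,
    expected: bool = False,
) -> pd.DataFrame:
    """Vital-registration death counts: Poisson(rate x pop x completeness).

    ``expected=True`` emits exact expected counts (infinite-population
    limit).  The envelope-deaths column carries the cell's true all-injury
    deaths, scaled by completeness, for cause-fraction modelling.
    """
    comp = world.config.completeness if completeness is None else completeness
    if not (0 < comp <= 1):
        raise ValidationError("completeness must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pop = world.population().set_index(ID_COLS)["population"]
    env = world.envelope_deaths().set_index(ID_COLS)["deaths"]
    frames = []
    for cause in world.leaf_fatal:
        df = world.true_csmr(cause)
        mu = df["rate"].to_numpy(float) * pop.reindex(pd.MultiIndex.from_frame(df[ID_COLS])).to_numpy(float) * comp
        deaths = mu if expected else rng.poisson(mu).astype(float)
        out = df[ID_COLS].copy()
        out["cause_id"] = cause
        out["deaths"] = deaths
        mi = pd.MultiIndex.from_frame(df[ID_COLS])
        out["sample_size"] = pop.reindex(mi).to_numpy(float) * comp
        out["envelope_deaths"] = env.reindex(mi).to_numpy(float) * comp
        out["source_type"] = "VR"
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def simulate_hospital(
    world: SyntheticWorld,
    seed: int = 2,
    expected: bool = False,
) -> pd.DataFrame:
    """Inpatient and outpatient incidence observations.

    Inpatient counts ~ Poisson(i x pop); outpatient counts
    ~ Poisson(ratio x i x pop); values are reported as rates per
    person-year with the cell population as sample size.
    """
    rng = np.random.default_rng(seed)
    pop_s = world.population().set_index(ID_COLS)["population"]
    frames = []
    for cause in world.leaf_nonfatal:
        df = world.true_incidence(cause)
        pop = pop_s.reindex(pd.MultiIndex.from_frame(df[ID_COLS])).to_numpy(float)
        ratio = world.crosswalk_ratios[(cause, "outpatient")]
        for category, mult in (("inpatient", 1.0), ("outpatient", ratio)):
            mu = df["rate"].to_numpy(float) * mult * pop
            counts = mu if expected else rng.poisson(mu).astype(float)
            out = df[ID_COLS].copy()
            out["cause_id"] = cause
            out["measure"] = "incidence"
            out["value"] = counts / pop
            out["category"] = category
            out["sample_size"] = pop
            frames.append(out)
    return pd.concat(frames, ignore_index=True)


def simulate_dual_coded(
    world: SyntheticWorld,
    n_per_cell: int = 2000,
    seed: int = 3,
    expected: bool = False,
) -> pd.DataFrame:
    """Dual-coded counts ~ Multinomial(n_per_cell, p) per (cause, age, sex)."""
    if n_per_cell < 1:
        raise ValidationError("n_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    nids = world.natures.ids()
    rows = []
    for _, r in world.cause_nature_probs.iterrows():
        p = np.array([r[n] for n in nids], dtype=float)
        counts = n_per_cell * p if expected else rng.multinomial(n_per_cell, p).astype(float)
        for nid, cnt in zip(nids, counts):
            rows.append((r["cause_id"], nid, r["age_group_id"], r["sex"], cnt))
    return pd.DataFrame(
        rows, columns=["cause_id", "nature_id", "age_group_id", "sex", "count"]
    )


def simulate_sv_surveys(
    world: SyntheticWorld,
    n_rows: int = 200,
    sample_size: int = 2000,
    seed: int = 4,
    expected: bool = False,
) -> pd.DataFrame:
    """Survey rows at true logit prevalence; penetrative-only rows are
    shifted down by the definition bias before sampling."""
    if n_rows < 1:
        raise ValidationError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    cells = world.grid.country_cells()
    adult = cells[cells["age_group_id"].isin(["a2", "a3", "a4"])].reset_index(drop=True)
    pick = rng.choice(len(adult), size=n_rows, replace=True)
    rows = adult.iloc[pick].reset_index(drop=True)
    alc = rows.merge(world.alcohol, on=["location_id", "year"], how="left")["alcohol"].to_numpy(float)
    flags = rng.random(n_rows) < 0.5
    logit = (world.config.sv_intercept + world.config.sv_alcohol_slope * alc
             - np.where(flags, world.config.sv_bias_penetrative, 0.0))
    p = 1.0 / (1.0 + np.exp(-logit))
    if expected:
        prev = p
    else:
        prev = rng.binomial(sample_size, p) / sample_size
    out = rows[ID_COLS].copy()
    out["prevalence"] = prev
    out["sample_size"] = float(sample_size)
    out["penetrative_only"] = flags.astype(int)
    return out


def envelope_draws(
    world: SyntheticWorld,
    n_draws: int,
    seed: int = 5,
    expected: bool = False,
) -> pd.DataFrame:
    """All-injury envelope as a draw matrix (exact or Poisson-perturbed)."""
    env = world.envelope_deaths()
    mu = env["deaths"].to_numpy(float)
    if expected:
        vals = np.tile(mu[:, None], (1, n_draws))
    else:
        rng = np.random.default_rng(seed)
        vals = rng.poisson(mu[:, None], size=(len(mu), n_draws)).astype(float)
    return make_draws(env[ID_COLS], vals)
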