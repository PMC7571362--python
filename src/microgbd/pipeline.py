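"""Pipeline driver: configuration, stage chaining and provenance.

Chains the full desk-scale burden-estimation flow on a synthetic world:

    simulate -> fit-cod -> codcorrect -> yll -> fit-incidence ->
    nature-split -> prevalence -> yld (+ comorbidity) ->
    sexual-violence -> daly -> report

All randomness flows from one master seed through named substreams
(crc32 of the stage name), so reruns with an identical config are
bit-identical.  Outputs are long CSVs plus a manifest recording the config
checksum, master seed and per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codem, daly, nature_split, prevalence, sexual_violence
from .codcorrect import compute_yll, scale_to_envelope
from .crosswalk import (
    CrosswalkCoefficient,
    CrosswalkTable,
    crosswalk_frame,
    expand_to_category,
    fit_incidence,
    remove_early_deaths,
)
from .draws import ID_COLS, draw_cols, make_draws
from .errors import PipelineError, ValidationError
from .synthetic import SyntheticWorld, WorldConfig, envelope_draws, generate_world
from .synthetic import simulate_dual_coded, simulate_hospital, simulate_sv_surveys, simulate_vr


@dataclass
class PipelineConfig:
    """Stage parameters for one pipeline run."""
    seed: int = 0
    n_draws: int = 50
    psi: float = 2.5
    alpha: float = 0.5
    acute_window: float = 28.0 / 365.0
    haq_lo: float = 30.0
    haq_hi: float = 95.0
    ode_step: float = 0.1
    families: tuple[str, ...] = ("ln_rate",)
    holdout_fraction: float = 0.2
    holdout_repeats: int = 5
    ensemble_trim: float | None = 2.0
    comorbidity: bool = True
    comorbidity_n_sim: int = 2000
    expected_counts: bool = False      # infinite-population limit
    dual_coded_n: int = 2000
    sv_rows: int = 200
    world: WorldConfig = field(default_factory=WorldConfig)
    out_dir: str | None = None

    def substream(self, name: str) -> int:
        return (int(self.seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def checksum(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty means valid."""
    problems = []
    if config.n_draws < 2:
        problems.append("n_draws must be >= 2")
    if config.psi <= 1:
        problems.append("psi must be > 1")
    if config.alpha < 0:
        problems.append("alpha must be >= 0")
    if not (0 < config.holdout_fraction <= 0.5):
        problems.append("holdout_fraction must be in (0, 0.5]")
    if config.acute_window <= 0:
        problems.append("acute_window must be positive")
    if config.haq_lo >= config.haq_hi:
        problems.append("haq_lo must be below haq_hi")
    if config.ode_step <= 0 or config.ode_step > 1:
        problems.append("ode_step must be in (0, 1]")
    for fam in config.families:
        if fam not in codem.FAMILIES:
            problems.append(f"unknown model family {fam!r}")
    if config.out_dir is not None:
        parent = Path(config.out_dir).parent
        if not parent.exists():
            problems.append(f"output directory parent missing: {parent}")
    return problems


def _location_meta(world: SyntheticWorld) -> pd.DataFrame:
    rows = []
    for c in world.grid.countries:
        loc = world.grid.locations[c]
        region = loc.parent_id
        super_region = world.grid.locations[region].parent_id
        rows.append({"location_id": c, "region_id": region,
                     "super_region_id": super_region})
    return pd.DataFrame(rows)


def _world_crosswalk_table(world: SyntheticWorld) -> CrosswalkTable:
    coefs = [
        CrosswalkCoefficient(cause, category, r, r, r)
        for (cause, category), r in world.crosswalk_ratios.items()
    ]
    return CrosswalkTable(coefs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a dict of result frames and writes them
    (plus a manifest) when ``config.out_dir`` is set."""
    problems = validate_config(config)
    if problems:
        raise ValidationError("invalid config: " + "; ".join(problems))
    results: dict = {"config": config}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:                      # noqa: BLE001
                if isinstance(exc, PipelineError):
                    raise
                raise PipelineError(name, str(exc)) from exc
        return deco

    # ------------------------------------------------------------- simulate
    @stage("simulate")
    def _sim():
        world = generate_world(config.world, config.substream("world"))
        results["world"] = world
        results["vr"] = simulate_vr(world, seed=config.substream("vr"),
                                    expected=config.expected_counts)
        results["hospital"] = simulate_hospital(world, seed=config.substream("hospital"),
                                                expected=config.expected_counts)
        results["dual_coded"] = simulate_dual_coded(
            world, n_per_cell=config.dual_coded_n,
            seed=config.substream("dual"), expected=config.expected_counts)
        results["sv_surveys"] = simulate_sv_surveys(
            world, n_rows=config.sv_rows, seed=config.substream("sv"),
            expected=config.expected_counts)
        results["envelope"] = envelope_draws(
            world, config.n_draws, seed=config.substream("envelope"),
            expected=config.expected_counts)
        return world

    world: SyntheticWorld = results["world"]
    pop = world.population()
    meta = _location_meta(world)
    cells = world.grid.country_cells()

    # -------------------------------------------------------------- fit-cod
    @stage("fit-cod")
    def _cod():
        death_frames = []
        summaries = {}
        for cause in world.leaf_fatal:
            obs = results["vr"][results["vr"]["cause_id"] == cause].reset_index(drop=True)
            specs = codem.enumerate_submodels(["x1", "x2"], config.families)
            plan = codem.make_holdouts(obs, config.holdout_fraction,
                                       config.holdout_repeats,
                                       config.substream(f"holdout_{cause}"))
            fits, metrics = [], []
            for spec in specs:
                fit = codem.fit_submodel(obs, world.covariates, spec, meta)
                fits.append(fit)
                metrics.append(codem.evaluate_predictive_validity(fit, plan))
            ens = codem.build_ensemble(fits, metrics, psi=config.psi,
                                       trim_ratio=config.ensemble_trim)
            summaries[cause] = ens.summary()
            grid = cells.copy()
            if "logit_cause_fraction" in config.families:
                env = results["envelope"].copy()
                env_mean = env[draw_cols(env)].mean(axis=1)
                env_rate = env[ID_COLS].copy()
                env_rate["envelope_rate"] = env_mean / pop.set_index(ID_COLS)[
                    "population"].reindex(pd.MultiIndex.from_frame(env[ID_COLS])).to_numpy()
                grid = grid.merge(env_rate, on=ID_COLS, how="left")
            rate_draws = codem.predict_draws(ens, grid, config.n_draws,
                                             config.substream(f"draws_{cause}"))
            p = pop.set_index(ID_COLS)["population"].reindex(
                pd.MultiIndex.from_frame(rate_draws[ID_COLS])).to_numpy(float)
            deaths = rate_draws.copy()
            dcols = draw_cols(deaths)
            deaths[dcols] = deaths[dcols].to_numpy(float) * p[:, None]
            deaths.insert(0, "cause_id", cause)
            death_frames.append(deaths)
        results["ensemble_summaries"] = summaries
        results["death_draws_raw"] = pd.concat(death_frames, ignore_index=True)

    # ----------------------------------------------------------- codcorrect
    @stage("codcorrect")
    def _correct():
        scaled = scale_to_envelope(results["death_draws_raw"], world.hierarchy,
                                   results["envelope"])
        results["death_draws"] = scaled
        csmr = scaled.copy()
        dcols = draw_cols(csmr)
        p = pop.set_index(ID_COLS)["population"].reindex(
            pd.MultiIndex.from_frame(csmr[ID_COLS])).to_numpy(float)
        csmr[dcols] = csmr[dcols].to_numpy(float) / p[:, None]
        results["csmr_draws"] = csmr

    # ------------------------------------------------------------------ yll
    @stage("yll")
    def _yll():
        lt = world.life_table()
        results["life_table"] = lt
        results["yll_draws"] = compute_yll(results["death_draws"], lt,
                                           age_groups=world.grid.age_groups)

    # -------------------------------------------------------- fit-incidence
    @stage("fit-incidence")
    def _incidence():
        xwalk = _world_crosswalk_table(world)
        surv_frames = []
        for cause in world.leaf_nonfatal:
            obs = results["hospital"]
            obs = obs[obs["cause_id"] == cause].reset_index(drop=True)
            adj = crosswalk_frame(obs, xwalk)
            csmr_c = results["csmr_draws"]
            csmr_c = csmr_c[csmr_c["cause_id"] == cause].drop(columns="cause_id")
            if csmr_c.empty:   # non-fatal-only cause: zero mortality
                csmr_c = make_draws(cells[ID_COLS],
                                    np.zeros((len(cells), config.n_draws)))
            fit = fit_incidence(
                adj, csmr_c, world.covariates, meta, cells,
                n_draws=config.n_draws,
                seed=config.substream(f"incidence_{cause}"),
                acute_duration=config.acute_window,
                covariate_ids=("x1", "x2"),
            )
            # total incidence: inpatient stream plus expanded outpatient stream
            dcols = draw_cols(fit.incidence_draws)
            total = fit.incidence_draws.copy()
            outpatient_vals = expand_to_category(
                total[dcols].to_numpy(float), cause, "outpatient", xwalk)
            total[dcols] = total[dcols].to_numpy(float) + outpatient_vals
            surv = remove_early_deaths(total, fit.f_draws, config.acute_window)
            surv.insert(0, "cause_id", cause)
            surv_frames.append(surv)
        results["incidence_surviving"] = pd.concat(surv_frames, ignore_index=True)

    # --------------------------------------------------------- nature-split
    @stage("nature-split")
    def _split():
        matrix = nature_split.estimate_cause_nature_matrix(
            results["dual_coded"], alpha=config.alpha,
            nature_ids=world.natures.ids())
        results["cause_nature_matrix"] = matrix
        results["cn_incidence"] = nature_split.apply_nature_split(
            results["incidence_surviving"], matrix)

    # ----------------------------------------------------------- prevalence
    @stage("prevalence")
    def _prev():
        st_inc, lt_inc = prevalence.split_short_long(
            results["cn_incidence"], world.natures)
        dur = world.durations.set_index("nature_id")
        haq = world.haq.set_index(["location_id", "year"])["haq"]
        pi = prevalence.fraction_treated(
            haq.reindex(pd.MultiIndex.from_frame(
                st_inc[["location_id", "year"]])).to_numpy(float),
            config.haq_lo, config.haq_hi)
        d_t = dur["d_treated"].reindex(st_inc["nature_id"]).to_numpy(float)
        d_u = dur["d_untreated"].reindex(st_inc["nature_id"]).to_numpy(float)
        dbar = pi * d_t + (1.0 - pi) * d_u
        results["prev_st"] = prevalence.short_term_prevalence(st_inc, dbar)
        p_lt = prevalence.long_term_prevalence(
            lt_inc, world.background_mortality,
            world.excess_mortality, step=config.ode_step)
        results["prev_lt"] = prevalence.reconcile_streams(results["prev_st"], p_lt)

    # ------------------------------------------------------------------ yld
    @stage("yld")
    def _yld():
        full = prevalence.compute_yld_table(
            results["prev_st"], results["prev_lt"], world.natures, pop)
        dcols = draw_cols(full)
        if config.comorbidity:
            # conditions at the nature level: prevalence summed over causes,
            # weight = the nature's larger disability weight (conservative)
            keys = ["cause_id", "nature_id"] + ID_COLS
            st = results["prev_st"].sort_values(keys).reset_index(drop=True)
            lt = results["prev_lt"].sort_values(keys).reset_index(drop=True)
            prev_total = st[keys].copy()
            prev_total[dcols] = st[dcols].to_numpy(float) + lt[dcols].to_numpy(float)
            mean_prev = prev_total[["nature_id"] + ID_COLS].copy()
            mean_prev["prev"] = prev_total[dcols].mean(axis=1)
            wide = mean_prev.groupby(ID_COLS + ["nature_id"])["prev"].sum().unstack(
                "nature_id", fill_value=0.0)
            nids = list(wide.columns)
            dws = np.array([
                max(world.natures.get(n).dw_short or 0.0,
                    world.natures.get(n).dw_long or 0.0)
                for n in nids
            ])
            factors = prevalence.comorbidity_factors(
                np.clip(wide.to_numpy(float), 0.0, 0.999), dws,
                n_sim=config.comorbidity_n_sim,
                seed=config.substream("comorbidity"))
            fac = pd.DataFrame(factors, index=wide.index, columns=nids).stack()
            fac.index.names = ID_COLS + ["nature_id"]
            f_vec = fac.reindex(pd.MultiIndex.from_frame(
                full[ID_COLS + ["nature_id"]])).to_numpy(float)
            full[dcols] = full[dcols].to_numpy(float) * f_vec[:, None]
        results["yld_table"] = full
        results["yld_by_cause"] = full.groupby(
            ["cause_id"] + ID_COLS, as_index=False)[dcols].sum()
        results["yld_by_nature"] = full.groupby(
            ["nature_id"] + ID_COLS, as_index=False)[dcols].sum()

    # -------------------------------------------------------- sexual-violence
    @stage("sexual-violence")
    def _sv():
        fit = sexual_violence.fit_sv_prevalence(
            results["sv_surveys"], world.alcohol, cells,
            n_draws=config.n_draws, seed=config.substream("sv_fit"))
        results["sv_fit"] = fit
        results["sv_yld"] = sexual_violence.compute_sv_ylds(
            fit.prevalence_draws, world.config.sv_dw, pop)

    # ----------------------------------------------------------------- daly
    @stage("daly")
    def _daly():
        yld_all = pd.concat([results["yld_by_cause"], results["sv_yld"]],
                            ignore_index=True)
        yld_agg = _aggregate_hierarchy(yld_all, world)
        results["yld_by_cause_agg"] = yld_agg
        yll_agg = _aggregate_hierarchy(results["yll_draws"], world)
        results["yll_draws"] = yll_agg
        results["daly_draws"] = daly.assemble_dalys(yll_agg, yld_agg)

    # --------------------------------------------------------------- report
    @stage("report")
    def _report():
        out = []
        for measure, key in (("csmr", "csmr_draws"), ("yll", "yll_draws"),
                             ("yld", "yld_by_cause_agg"), ("daly", "daly_draws")):
            s = daly.summarise_draws(results[key])
            s.insert(0, "measure", measure)
            out.append(s)
        nat = daly.summarise_draws(results["yld_by_nature"])
        nat.insert(0, "measure", "yld")
        out.append(nat)
        results["report"] = pd.concat(out, ignore_index=True)
        if config.out_dir is not None:
            _write_outputs(config, results)

    return results


def _aggregate_hierarchy(yld_by_cause: pd.DataFrame, world: SyntheticWorld) -> pd.DataFrame:
    """Sum cause-level draws up the cause tree (children into parents)."""
    dcols = draw_cols(yld_by_cause)
    have = dict(tuple(yld_by_cause.groupby("cause_id")))
    hierarchy = world.hierarchy
    max_level = max(n.level for n in hierarchy.nodes.values())
    for level in range(max_level, 0, -1):
        for cause_id in list(have):
            if cause_id not in hierarchy:
                continue
            node = hierarchy[cause_id]
            if node.level != level or node.parent_id is None:
                continue
            parent = node.parent_id
            if parent in have:
                continue
            kids = [k.cause_id for k in hierarchy.children(parent) if k.cause_id in have]
            total = None
            for k in kids:
                block = have[k].set_index(ID_COLS)[dcols]
                total = block if total is None else total + block
            agg = total.reset_index()
            agg.insert(0, "cause_id", parent)
            have[parent] = agg
    frames = []
    for cause_id in sorted(have):
        f = have[cause_id][["cause_id"] + ID_COLS + dcols]
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _write_outputs(config: PipelineConfig, results: dict) -> None:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "results.csv": results["report"],
        "yld_by_nature.csv": daly.summarise_draws(results["yld_by_nature"]),
        "ensemble_metrics.csv": pd.concat(
            [s.assign(cause_id=c) for c, s in results["ensemble_summaries"].items()],
            ignore_index=True),
    }
    checksums = {}
    for name, frame in files.items():
        path = out_dir / name
        frame.to_csv(path, index=False)
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    manifest = {
        "config_checksum": config.checksum(),
        "master_seed": config.seed,
        "config": config.to_dict(),
        "files": checksums,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
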