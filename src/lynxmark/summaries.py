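"""Derived demographic quantities and the end-to-end pipeline.

Annual survival per lynx year (back-transformed from the intercept plus the
year random effect), the mean survival time of independent lynx (subadults
and adults pooled, a truncated discrete life expectancy with the 18-year
cap), and annualized emigration probabilities.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.special import expit

from .age_at_death import T_MAX
from .data_model import AGE_NAMES
from .inference import FitConfig, FitResult, fit
from .multistate import ModelSpec, SEX_LABELS


def annual_survival_by_year(result: FitResult, area: int, sex: int, age: int
                            ) -> pd.DataFrame:
    """Posterior of annual survival for each fitted lynx year.

    Per draw, the product of the within-year interval survivals equals the
    inverse-logit of the intercept plus the scaled year deviate, so the
    annual probability is computed directly on that scale.
    """
    spec = result.spec
    tr = result.transform
    space = spec.space
    if area >= space.n_inside:
        raise ValueError("annual survival by year is defined inside the "
                         "study population")
    b0_lab = (f"b0[{space.area_labels[area]},{SEX_LABELS[sex]},"
              f"{AGE_NAMES[age]}]")
    k_b0 = tr.labels.index(b0_lab)
    group = age if spec.layout == "one_area" else area
    rows = []
    for y in range(spec.n_years):
        if result.constrained_draws is not None:
            flat = result.constrained_draws.reshape(-1, tr.n_dim)
            b0 = flat[:, k_b0]
            if spec.year_effects:
                ks = tr.labels.index(f"sigma_S[{group}]")
                kg = tr.labels.index(f"gamma[{group},{y}]")
                S = expit(b0 + flat[:, ks] * flat[:, kg])
            else:
                S = expit(b0)
            rows.append((y, S.mean(), np.quantile(S, 0.025),
                         np.quantile(S, 0.975)))
        else:
            p = result.params
            lg = p.b0[0 if spec.layout == "one_area" else area, sex, age]
            if spec.year_effects:
                lg = lg + (p.sigma_S[group] * p.gamma[group, y])
            S = float(expit(lg))
            rows.append((y, S, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["year_index", "S_mean", "S_q2.5",
                                       "S_q97.5"])


def mean_survival_time(s_subadult: float, s_adult: float,
                       t_max: int = T_MAX) -> float:
    """Expected whole years lived from independence (start of year 2).

    Truncated discrete life expectancy: sum over years 2..t_max of the
    probability of completing that year, i.e.
    ``sum_{j=2}^{t_max} prod_{k=2}^{j} s_k`` with s_2 the subadult and
    s_3..s_tmax the adult annual survival.  With survival 1 throughout this
    equals t_max - 1 (the cap); with survival 0 it is 0.
    """
    if not (0 <= s_subadult <= 1 and 0 <= s_adult <= 1):
        raise ValueError("survival probabilities must lie in [0, 1]")
    total = 0.0
    alive = 1.0
    for year in range(2, t_max + 1):
        alive *= s_subadult if year == 2 else s_adult
        total += alive
    return total


def annualize_movement(m_interval: float, intervals_per_year: int) -> float:
    """Annual probability of at least one move: 1 - (1 - m)^K."""
    if not 0 <= m_interval <= 1:
        raise ValueError("movement probability must lie in [0, 1]")
    return 1.0 - (1.0 - m_interval) ** intervals_per_year


def deannualize_movement(m_annual: float, intervals_per_year: int) -> float:
    if not 0 <= m_annual <= 1:
        raise ValueError("movement probability must lie in [0, 1]")
    return 1.0 - (1.0 - m_annual) ** (1.0 / intervals_per_year)


def derived_report(result: FitResult) -> pd.DataFrame:
    """Annual survival, mean survival time, and annual emigration per class."""
    spec = result.spec
    space = spec.space
    surv = result.survival_table()
    rows = []
    for a in range(space.n_inside):
        for s in range(2):
            sub = surv[(surv.subarea == space.area_labels[a])
                       & (surv.sex == SEX_LABELS[s])]
            s_by_age = {r.age_class: r.S_mean for r in sub.itertuples()}
            mst = mean_survival_time(s_by_age["subadult"], s_by_age["adult"])
            for g in range(3):
                m_cell = result.params.m[s, g]
                emig_interval = m_cell[-1] if space.layout == "one_area" \
                    else m_cell[1]
                rows.append((space.area_labels[a], SEX_LABELS[s],
                             AGE_NAMES[g], s_by_age[AGE_NAMES[g]], mst,
                             annualize_movement(float(emig_interval),
                                                spec.intervals_per_year)))
    return pd.DataFrame(rows, columns=[
        "subarea", "sex", "age_class", "annual_survival",
        "mean_survival_time_independent", "annual_emigration"])


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """simulate|load -> preprocess -> fit -> report, writing all outputs.

    config keys: either ``simulate`` (SimulationConfig fields) or ``data``
    (path to a dataset directory), optional ``model`` (ModelSpec fields)
    and ``fit`` (FitConfig fields).
    """
    from . import simulate as sim_mod
    from .data_model import preprocess

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed}

    try:
        if "simulate" in config:
            sc = sim_mod.SimulationConfig(**config["simulate"])
            sim = sim_mod.simulate_population(sc, seed=seed)
            sim_mod.write_dataset(sim, out / "data")
            detections, recoveries = sim.detections, sim.recoveries
            individuals, effort = sim.individuals_meta, sim.effort
            ages, grid, space = sim.age_records, sim.grid, sim.spec.space
            spec = sim.spec
        elif "data" in config:
            (detections, recoveries, individuals, effort, ages, grid,
             space) = sim_mod.read_dataset(config["data"])
            spec = ModelSpec(layout=space.layout,
                             intervals_per_year=grid.per_year,
                             n_years=grid.n_years,
                             **config.get("model", {}))
        else:
            raise ValueError("config needs a 'simulate' or 'data' section")
    except Exception as e:
        raise RuntimeError(f"[stage: load/simulate] {e}") from e

    try:
        if "model" in config and "simulate" in config:
            spec = ModelSpec(layout=space.layout,
                             intervals_per_year=grid.per_year,
                             n_years=grid.n_years, **config["model"])
        ds, prep_report = preprocess(detections, recoveries, individuals,
                                     grid, space, effort)
        report["preprocess"] = {
            k: v for k, v in prep_report.items() if k != "cleanup"}
    except Exception as e:
        raise RuntimeError(f"[stage: preprocess] {e}") from e

    try:
        fc = FitConfig(seed=seed, **config.get("fit", {"mode": "mle"}))
        result = fit(ds, spec, fc, age_records=ages)
        result.summary.to_csv(out / "summary.csv")
        if result.constrained_draws is not None:
            flat = result.constrained_draws.reshape(
                -1, result.transform.n_dim)
            pd.DataFrame(flat, columns=result.transform.labels).to_csv(
                out / "draws.csv", index=False)
        report["fit"] = {"mode": fc.mode, "loglik": result.loglik,
                         "converged": bool(result.converged),
                         "flags": list(result.flags)}
    except Exception as e:
        raise RuntimeError(f"[stage: fit] {e}") from e

    try:
        rep = derived_report(result)
        rep.to_csv(out / "derived_report.csv", index=False)
        report["derived"] = rep.to_dict(orient="records")
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    default=str))
    except Exception as e:
        raise RuntimeError(f"[stage: report] {e}") from e
    return report
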