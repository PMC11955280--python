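"""Synthetic monitoring-data generator.

Emulates the data-generating context of a long-term lynx monitoring
programme: cohorts of juveniles, subadults and (unknown-birth-year) adults
enter at lynx-year boundaries, latent states evolve by the multi-state
transition model (mortality before movement, one-way emigration),
detections are drawn from the observation model with systematic/
opportunistic effort covariates and telemetry status, carcasses are
recovered with age- and sex-specific probabilities, and an independent
sample of known-age carcasses is drawn via the recovery-corrected
age-at-death mechanics.

Default parameter magnitudes mirror a reintroduced Alpine-type population:
adult annual survival near 0.78, juvenile near 0.3, per-occasion detection
0.1-0.4, recovery 0.1-0.3, and roughly half of all pictured individuals of
unknown sex.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit

from . import data_model as dm
from .age_at_death import corrected_theta
from .data_model import (AgeAtDeathRecord, DeadRecoveryRecord,
                         DetectionRecord, EffortCovariates, OccasionGrid)
from .likelihood import (age_model_schedules, detection_prob_rows,
                         recovery_prob_rows, transition_table)
from .multistate import (ModelSpec, ParameterSet, PriorSpec, StateSpace,
                         TWO_SUBAREA)


@dataclass
class SimulationConfig:
    """Truth values and design of one synthetic monitoring dataset.

    Class-structured truths are (sex, age) arrays: rows F/M, columns
    juvenile/subadult/adult.  Movement entries are per-interval
    probabilities, (m12, m13, m21, m23) for the two-subarea layout or a
    single emigration probability for the one-area layout.
    """

    layout: str = TWO_SUBAREA
    n_years: int = 25
    interval_months: int = 2
    start_lynx_year: int = 1997
    # cohort sizes per lynx year and inside subarea
    cohort_juveniles: int = 6
    cohort_subadults: int = 2
    cohort_adults: int = 3
    # natural-scale truth
    survival: Sequence = ((0.33, 0.82, 0.78), (0.29, 0.84, 0.78))
    survival_outside: float = 0.70
    detection: Sequence = ((0.40, 0.11, 0.12), (0.20, 0.16, 0.19))
    detection_outside: float = 0.03
    detection_telemetry: float = 0.95
    a1: float = 0.45
    a2: float = 0.0
    recovery: Sequence = ((0.11, 0.13, 0.13), (0.07, 0.33, 0.15))
    recovery_outside: float = 0.02
    movement: Sequence = None   # filled per layout in __post_init__
    sigma_S: float = 0.3
    sigma_p: float = 1.0
    psi: Sequence = (0.5, 0.5)
    # design fractions
    unknown_sex_fraction: float = 0.49
    telemetry_fraction: float = 0.15
    telemetry_years: float = 1.5
    translocation_fraction: float = 0.01
    flank_mismatch_fraction: float = 0.0
    n_extra_carcasses: int = 200
    unknown_sex_carcass_fraction: float = 0.1
    # effort schedule
    use_effort: bool = True
    systmon_period_years: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.movement is None:
            juv2 = (0.015, 0.004, 0.07, 0.01)
            older2 = (0.004, 0.001, 0.01, 0.002)
            juv1, older1 = (0.012,), (0.002,)
            if self.layout == TWO_SUBAREA:
                self.movement = ((juv2, juv2, older2), (juv2, juv2, older2))
            else:
                self.movement = ((juv1, juv1, older1), (juv1, juv1, older1))
        self.survival = np.asarray(self.survival, dtype=float)
        self.detection = np.asarray(self.detection, dtype=float)
        self.recovery = np.asarray(self.recovery, dtype=float)
        self.movement = np.asarray(self.movement, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)

    @property
    def intervals_per_year(self) -> int:
        return 12 // self.interval_months

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            layout=self.layout,
            intervals_per_year=self.intervals_per_year,
            n_years=self.n_years,
            year_effects=self.sigma_S > 0,
            individual_effects=self.sigma_p > 0,
            effort_effects=self.use_effort,
            telemetry=self.telemetry_fraction > 0,
            priors=PriorSpec(),
        )

    def to_parameter_set(self, spec: ModelSpec, n_individuals: int,
                         rng: np.random.Generator) -> ParameterSet:
        """Truth ParameterSet on the link scale; random effects drawn."""
        p = ParameterSet.zeros(spec, n_individuals)
        for a in range(spec.space.n_inside):
            p.b0[a] = logit(self.survival)
        p.b_out = float(logit(self.survival_outside))
        p.sigma_S = np.full_like(p.sigma_S, self.sigma_S)
        if self.sigma_S > 0:
            p.gamma = rng.standard_normal(p.gamma.shape)
        for a in range(spec.space.n_inside):
            p.a0[a, :, :, 0] = logit(self.detection)
            p.a0[a, :, :, 1] = logit(self.detection_telemetry)
        out = spec.space.n_areas - 1
        p.a0[out, :, :, 0] = logit(self.detection_outside)
        p.a0[out, :, :, 1] = logit(self.detection_telemetry)
        p.a1, p.a2 = self.a1, self.a2
        p.sigma_p = self.sigma_p
        if self.sigma_p > 0:
            p.epsilon = rng.standard_normal(n_individuals)
        p.d0 = logit(self.recovery)
        if spec.layout == TWO_SUBAREA:
            p.d_area = np.array([
                0.0, 0.0,
                float(logit(self.recovery_outside) - p.d0.mean())])
        p.m = self.movement.astype(float)
        p.psi = self.psi.astype(float)
        return p


@dataclass
class TruthRecords:
    """Ground truth per simulated individual (arrays aligned with ids)."""

    ids: list
    states: np.ndarray        # (n, T) latent state index, -1 before entry
    sex: np.ndarray           # (n,) true sex 0/1
    birth_lynx_year: np.ndarray  # (n,) lynx year, -1 for unknown-age adults
    entry: np.ndarray         # (n,) entry occasion
    death_occasion: np.ndarray   # (n,) occasion of the died-this-interval
                                 # state, -1 if survived the window
    death_area: np.ndarray    # (n,) area of death, -1 if none
    recovered: np.ndarray     # (n,) bool


@dataclass
class SimulatedData:
    config: SimulationConfig
    spec: ModelSpec
    grid: OccasionGrid
    effort: EffortCovariates
    params: ParameterSet
    detections: list
    recoveries: list
    individuals_meta: dict
    age_records: list
    truth: TruthRecords

    def to_dataset(self, apply_flank_filter: bool = True):
        return dm.preprocess(self.detections, self.recoveries,
                             self.individuals_meta, self.grid,
                             self.spec.space, self.effort,
                             apply_flank_filter=apply_flank_filter)


def make_effort(config: SimulationConfig, grid: OccasionGrid,
                space: StateSpace, rng: np.random.Generator
                ) -> EffortCovariates:
    """Systematic winter sessions every few years; oppmon random walk."""
    n_in = space.n_inside
    systmon = np.zeros((n_in, grid.n_occasions))
    oppmon = np.ones((n_in, grid.n_occasions))
    if not config.use_effort:
        return EffortCovariates(systmon, oppmon)
    per_year = grid.per_year
    winter_months = (7, 8)   # Dec and Jan as offsets from 1 May
    for a in range(n_in):
        level = float(rng.integers(1, 4))
        for y in range(grid.n_years):
            session = (y + a) % config.systmon_period_years == 0
            for t in range(y * per_year, (y + 1) * per_year):
                within = t % per_year
                months = range(within * grid.interval_months,
                               (within + 1) * grid.interval_months)
                frac = np.mean([1.0 if mo in winter_months else 0.0
                                for mo in months])
                if session:
                    systmon[a, t] = frac
                oppmon[a, t] = level
            level = float(np.clip(level + rng.choice([-1, 0, 0, 1]), 1, 3))
    return EffortCovariates(systmon, oppmon)


def _sample_rows(P: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Categorical draw per row of a row-stochastic matrix."""
    c = np.cumsum(P, axis=1)
    return (u[:, None] > c).sum(axis=1)


def simulate_population(config: SimulationConfig,
                        seed: Optional[int] = None) -> SimulatedData:
    """Generate a complete synthetic dataset plus ground truth.

    Deterministic under a fixed seed (defaults to ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spec = config.model_spec()
    space = spec.space
    grid = OccasionGrid(config.start_lynx_year, config.n_years,
                        config.interval_months)
    T = grid.n_occasions
    effort = make_effort(config, grid, space, rng)

    # --- cohorts -----------------------------------------------------------
    ids, sex_true, birth_ly, entry, area0 = [], [], [], [], []
    counter = 0
    for y in range(config.n_years):
        for a in range(space.n_inside):
            for n_k, age0 in ((config.cohort_juveniles, 0),
                              (config.cohort_subadults, 1),
                              (config.cohort_adults, 2)):
                for _ in range(n_k):
                    ids.append(f"LX{counter:05d}")
                    counter += 1
                    sex_true.append(int(rng.random() < config.psi[1]))
                    if age0 == 2:
                        birth_ly.append(-1)   # unknown birth year
                    else:
                        birth_ly.append(config.start_lynx_year + y - age0)
                    entry.append(y * grid.per_year)
                    area0.append(a)
    n = len(ids)
    sex_true = np.asarray(sex_true)
    birth_ly = np.asarray(birth_ly)
    entry = np.asarray(entry)
    area0 = np.asarray(area0)

    params = config.to_parameter_set(spec, n, rng)

    # per-occasion age class (true birth year where known, else adult)
    year_of_occ = np.array([grid.lynx_year_of_occasion(t) for t in range(T)])
    age_nt = np.full((n, T), dm.ADULT, dtype=np.int8)
    known = birth_ly >= 0
    age_nt[known] = np.clip(year_of_occ[None, :] - birth_ly[known, None],
                            0, 2).astype(np.int8)

    # telemetry windows
    tel_nt = np.zeros((n, T), dtype=bool)
    n_tel_occ = max(1, int(round(config.telemetry_years
                                 * grid.per_year)))
    collared = rng.random(n) < config.telemetry_fraction
    for i in np.flatnonzero(collared):
        t0 = int(entry[i] + rng.integers(0, max(1, T - entry[i])))
        tel_nt[i, t0:t0 + n_tel_occ] = True

    # translocation censoring
    censor = np.full(n, T, dtype=int)
    translocated = rng.random(n) < config.translocation_fraction
    for i in np.flatnonzero(translocated):
        if entry[i] + 1 < T:
            censor[i] = int(rng.integers(entry[i] + 1, T))

    # --- latent states -----------------------------------------------------
    year_idx = np.array([grid.year_index_of_occasion(t) for t in range(T)])
    Ttab = transition_table(params, spec)
    z = np.full((n, T), -1, dtype=np.int8)
    z[np.arange(n), entry] = [space.alive_state(a) for a in area0]
    for t in range(T - 1):
        act = (entry <= t) & (z[:, t] >= 0)
        if not act.any():
            continue
        rows_T = Ttab[sex_true[act], age_nt[act, t], year_idx[t]]
        P = rows_T[np.arange(act.sum()), z[act, t]]
        z[act, t + 1] = _sample_rows(P, rng.random(act.sum()))

    # --- observations ------------------------------------------------------
    p_nat = detection_prob_rows(params, spec, _EffortView(effort), sex_true,
                                np.arange(n), age_nt, tel_nt)
    r_nat = recovery_prob_rows(params, spec, sex_true, age_nt)
    codes = np.zeros((n, T), dtype=np.int16)
    u_det = rng.random((n, T))
    u_rec = rng.random((n, T))
    for a in range(space.n_areas):
        alive = z == space.alive_state(a)
        died = z == space.died_state(a)
        codes[alive & (u_det < p_nat[:, a, :])] = space.code_detected(a)
        codes[died & (u_rec < r_nat[:, a, :])] = space.code_recovered(a)
    occ_range = np.arange(T)[None, :]
    codes[occ_range >= censor[:, None]] = 0   # removed at translocation

    # --- truth bookkeeping -------------------------------------------------
    death_occ = np.full(n, -1, dtype=int)
    death_area = np.full(n, -1, dtype=int)
    recovered = np.zeros(n, dtype=bool)
    for a in range(space.n_areas):
        hit = z == space.died_state(a)
        has = hit.any(axis=1)
        death_occ[has] = hit[has].argmax(axis=1)
        death_area[has] = a
        recovered |= (codes == space.code_recovered(a)).any(axis=1)
    truth = TruthRecords(ids, z, sex_true, birth_ly, entry, death_occ,
                         death_area, recovered)

    # --- records -----------------------------------------------------------
    max_day = 28 * config.interval_months
    detections: list[DetectionRecord] = []
    recoveries: list[DeadRecoveryRecord] = []
    individuals_meta: dict[str, dict] = {}
    sex_known_obs = rng.random(n) >= config.unknown_sex_fraction
    for i in range(n):
        obs_t = np.flatnonzero(codes[i])
        if len(obs_t) == 0:
            continue
        iid = ids[i]
        for t in obs_t:
            c = int(codes[i, t])
            area = (c - 1) // 2
            date = grid.start_date_of_occasion(t) + dt.timedelta(
                days=int(rng.integers(0, max_day)))
            label = space.area_labels[area]
            if c % 2 == 0:   # dead recovery
                recoveries.append(DeadRecoveryRecord(
                    iid, date, label,
                    dm.SEX_NAME[int(sex_true[i])],
                    int(birth_ly[i]) if birth_ly[i] >= 0 else None))
            else:
                if tel_nt[i, t]:
                    source = "telemetry"
                elif area < space.n_inside and effort.systmon[area, t] > 0:
                    source = "systematic_camera"
                else:
                    source = "opportunistic_camera"
                detections.append(DetectionRecord(iid, date, label, source))
        sex_obs = int(sex_true[i]) if (sex_known_obs[i] or recovered[i]) else -1
        meta = {"sex": sex_obs}
        if birth_ly[i] >= 0:
            meta["birth_lynx_year"] = int(birth_ly[i])
        if censor[i] < T:
            meta["censor_occasion"] = int(censor[i])
        tel_occ = np.flatnonzero(tel_nt[i])
        if len(tel_occ):
            meta["telemetry_occasions"] = [int(t) for t in tel_occ]
        individuals_meta[iid] = meta

    # --- independent age-at-death sample -----------------------------------
    s_by_sex, r_by_sex = age_model_schedules(params, spec)
    age_records: list[AgeAtDeathRecord] = []
    for _ in range(config.n_extra_carcasses):
        sex = int(rng.random() < params.psi[1])
        theta = corrected_theta(s_by_sex[sex], r_by_sex[sex])
        age = int(rng.choice(len(theta), p=theta)) + 1
        obs_sex = -1 if rng.random() < config.unknown_sex_carcass_fraction \
            else sex
        age_records.append(AgeAtDeathRecord(obs_sex, age))

    if config.flank_mismatch_fraction > 0:
        detections, _ = degrade_to_flanks(
            detections, recoveries, individuals_meta,
            config.flank_mismatch_fraction,
            rng.integers(0, 2**31 - 1))

    return SimulatedData(config, spec, grid, effort, params, detections,
                         recoveries, individuals_meta, age_records, truth)


class _EffortView:
    """Minimal dataset-shaped adapter so the detection-probability code can
    be reused by the simulator."""

    def __init__(self, effort: EffortCovariates):
        self.effort = effort


def degrade_to_flanks(detections: Sequence[DetectionRecord],
                      recoveries: Sequence[DeadRecoveryRecord],
                      individuals_meta: dict, fraction: float,
                      seed: int, p_left: float = 0.45
                      ) -> tuple[list, dict]:
    """Split camera-only individuals into left/right-flank pseudo-individuals.

    Only individuals identified exclusively from camera pictures (no
    telemetry or live capture, never recovered dead) are eligible: a
    recovered carcass or a handled animal is photographed from both sides
    and can always be matched.  A selected individual's records are divided
    between an "<id>__L" and an "<id>__R" pseudo-individual (an individual
    with a single record yields one single-flank pseudo-individual).
    Returns the new detection list and a mapping original id -> pseudo ids.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    recovered_ids = {r.individual_id for r in recoveries}
    by_id: dict[str, list[DetectionRecord]] = {}
    for r in detections:
        by_id.setdefault(r.individual_id, []).append(r)
    out: list[DetectionRecord] = []
    mapping: dict[str, list[str]] = {}
    for iid, recs in by_id.items():
        handled = any(r.source in ("telemetry", "live_capture") for r in recs)
        eligible = (iid not in recovered_ids) and not handled
        if not eligible or rng.random() >= fraction:
            out.extend(recs)
            mapping[iid] = [iid]
            continue
        sides = np.where(rng.random(len(recs)) < p_left, "left", "right")
        if len(recs) >= 2 and len(set(sides)) == 1:
            sides[rng.integers(0, len(recs))] = \
                "left" if sides[0] == "right" else "right"
        pseudo = []
        for side in ("left", "right"):
            sel = [r for r, s in zip(recs, sides) if s == side]
            if not sel:
                continue
            pid = f"{iid}__{side[0].upper()}"
            pseudo.append(pid)
            meta = dict(individuals_meta.get(iid, {"sex": -1}))
            meta["flank"] = side
            individuals_meta[pid] = meta
            for r in sel:
                out.append(DetectionRecord(pid, r.date, r.location,
                                           r.source, side))
        mapping[iid] = pseudo
    return out, mapping


# ---------------------------------------------------------------------------
# file round-trip
# ---------------------------------------------------------------------------

def write_dataset(sim: SimulatedData, directory) -> dict:
    """Write the CSV dialects the preprocessing layer reads, plus truth JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    det = pd.DataFrame(
        [(r.individual_id, r.date.isoformat(), r.location, r.source, r.flank)
         for r in sim.detections],
        columns=["id", "date", "subarea", "source", "flank"])
    det.to_csv(d / "detections.csv", index=False)
    rec = pd.DataFrame(
        [(r.individual_id, r.date.isoformat(), r.location, r.sex,
          r.birth_year) for r in sim.recoveries],
        columns=["id", "date", "subarea", "sex", "birth_lynx_year"])
    rec.to_csv(d / "dead_recoveries.csv", index=False)
    rows = []
    for iid, meta in sim.individuals_meta.items():
        rows.append((
            iid, dm.SEX_NAME[meta.get("sex", -1)],
            meta.get("birth_lynx_year"),
            meta.get("censor_occasion"),
            ";".join(str(t) for t in meta.get("telemetry_occasions", []))))
    pd.DataFrame(rows, columns=["id", "sex", "birth_lynx_year",
                                "censor_occasion", "telemetry_occasions"]
                 ).to_csv(d / "individuals.csv", index=False)
    eff = []
    for a in range(sim.spec.space.n_inside):
        for t in range(sim.grid.n_occasions):
            eff.append((sim.spec.space.area_labels[a], t,
                        sim.effort.systmon[a, t], sim.effort.oppmon[a, t]))
    pd.DataFrame(eff, columns=["subarea", "occasion", "systmon", "oppmon"]
                 ).to_csv(d / "effort.csv", index=False)
    pd.DataFrame([(dm.SEX_NAME[r.sex], r.age) for r in sim.age_records],
                 columns=["sex", "age_years"]
                 ).to_csv(d / "ages_at_death.csv", index=False)
    meta = {"layout": sim.spec.layout, "grid": sim.grid.to_dict(),
            "intervals_per_year": sim.spec.intervals_per_year}
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    truth = {
        "ids": sim.truth.ids,
        "sex": sim.truth.sex.tolist(),
        "birth_lynx_year": sim.truth.birth_lynx_year.tolist(),
        "entry": sim.truth.entry.tolist(),
        "death_occasion": sim.truth.death_occasion.tolist(),
        "death_area": sim.truth.death_area.tolist(),
        "recovered": sim.truth.recovered.astype(int).tolist(),
        "states": sim.truth.states.tolist(),
    }
    (d / "truth.json").write_text(json.dumps(truth))
    return {"n_detections": len(det), "n_recoveries": len(rec),
            "n_individuals": len(sim.individuals_meta),
            "n_age_records": len(sim.age_records)}


def read_dataset(directory):
    """Load a written dataset directory back into preprocessing inputs."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    space = StateSpace(meta["layout"])
    grid = OccasionGrid.from_dict(meta["grid"])
    detections = dm.read_detections(d / "detections.csv")
    recoveries = dm.read_dead_recoveries(d / "dead_recoveries.csv")
    individuals = dm.read_individuals(d / "individuals.csv")
    effort = dm.read_effort(d / "effort.csv", grid, space)
    ages = dm.read_ages_at_death(d / "ages_at_death.csv")
    return detections, recoveries, individuals, effort, ages, grid, space
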