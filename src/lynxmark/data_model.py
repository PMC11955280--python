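"""Domain types, file I/O, and preprocessing of raw monitoring records.

Raw inputs are delimited text tables of individual detections (camera traps,
chance pictures, telemetry, live captures), dead recoveries, and per-occasion
monitoring-effort covariates.  Preprocessing bins records onto an occasion
grid aligned to "lynx years" (1 May - 30 April, matching the species'
reproductive cycle), assigns age classes that advance at lynx-year
boundaries, resolves unmatched single-flank pseudo-individuals, and applies
censoring at translocation.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .multistate import StateSpace

JUVENILE, SUBADULT, ADULT = 0, 1, 2
AGE_NAMES = ("juvenile", "subadult", "adult")
SEX_CODE = {"F": 0, "M": 1, "unknown": -1}
SEX_NAME = {0: "F", 1: "M", -1: "unknown"}

SOURCES = ("systematic_camera", "opportunistic_camera", "chance_picture",
           "telemetry", "live_capture")
FLANKS = ("both", "left", "right")

LYNX_YEAR_START_MONTH = 5  # 1 May


def lynx_year_of(date: dt.date) -> int:
    """Lynx year containing a calendar date (year Y runs 1 May Y - 30 Apr Y+1)."""
    return date.year if date.month >= LYNX_YEAR_START_MONTH else date.year - 1


@dataclass(frozen=True)
class DetectionRecord:
    individual_id: str
    date: dt.date
    location: str          # subarea label or "outside"
    source: str
    flank: str = "both"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.flank not in FLANKS:
            raise ValueError(f"unknown flank {self.flank!r}")


@dataclass(frozen=True)
class DeadRecoveryRecord:
    individual_id: Optional[str]
    date: dt.date
    location: str
    sex: str = "unknown"
    birth_year: Optional[int] = None   # lynx year of birth

    def age_at_death(self) -> Optional[int]:
        """Whole-year age category (1..18) when the birth year is known."""
        if self.birth_year is None:
            return None
        age = lynx_year_of(self.date) - self.birth_year + 1
        if not 1 <= age <= 18:
            raise ValueError(
                f"age at death {age} outside 1..18 for {self.individual_id!r}")
        return age


@dataclass
class Individual:
    id: str
    sex: int = -1                       # 0 = F, 1 = M, -1 = unknown
    birth_lynx_year: Optional[int] = None
    first_occasion: int = 0
    censor_occasion: Optional[int] = None  # translocation; occasions >= this dropped
    telemetry_occasions: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.censor_occasion is not None and \
                self.first_occasion > self.censor_occasion:
            raise ValueError(
                f"{self.id}: first occasion after censor occasion")


@dataclass(frozen=True)
class AgeAtDeathRecord:
    sex: int      # 0 = F, 1 = M, -1 = unknown
    age: int      # whole years, 1..18

    def __post_init__(self):
        if not 1 <= self.age <= 18:
            raise ValueError(f"age at death must lie in 1..18, got {self.age}")


class OccasionGrid:
    """Capture-occasion grid: 12/interval_months occasions per lynx year."""

    def __init__(self, start_lynx_year: int, n_years: int, interval_months: int):
        if interval_months not in (1, 2):
            raise ValueError("interval_months must be 1 or 2")
        self.start_lynx_year = start_lynx_year
        self.n_years = n_years
        self.interval_months = interval_months
        self.per_year = 12 // interval_months
        self.n_occasions = n_years * self.per_year

    @property
    def occasions(self) -> list[tuple[int, int]]:
        return [(self.start_lynx_year + t // self.per_year, t % self.per_year)
                for t in range(self.n_occasions)]

    def lynx_year_of_occasion(self, t: int) -> int:
        return self.start_lynx_year + t // self.per_year

    def year_index_of_occasion(self, t: int) -> int:
        return t // self.per_year

    def occasion_of(self, date: dt.date) -> int:
        """Occasion index containing a date; raises if outside the window."""
        ly = lynx_year_of(date)
        if not self.start_lynx_year <= ly < self.start_lynx_year + self.n_years:
            raise ValueError(
                f"date {date.isoformat()} outside grid window "
                f"(lynx years {self.start_lynx_year}.."
                f"{self.start_lynx_year + self.n_years - 1})")
        month_offset = (date.month - LYNX_YEAR_START_MONTH) % 12
        within = month_offset // self.interval_months
        return (ly - self.start_lynx_year) * self.per_year + within

    def start_date_of_occasion(self, t: int) -> dt.date:
        ly, within = self.occasions[t]
        month0 = LYNX_YEAR_START_MONTH - 1 + within * self.interval_months
        return dt.date(ly + month0 // 12, month0 % 12 + 1, 1)

    def to_dict(self) -> dict:
        return {"start_lynx_year": self.start_lynx_year,
                "n_years": self.n_years,
                "interval_months": self.interval_months}

    @classmethod
    def from_dict(cls, d: dict) -> "OccasionGrid":
        return cls(**d)


@dataclass
class EncounterHistory:
    """One individual's per-occasion observation codes plus covariates."""

    individual: Individual
    codes: np.ndarray          # (n_occasions,) int observation codes
    age_class: np.ndarray      # (n_occasions,) int in {0, 1, 2}

    def validate(self, space: StateSpace) -> None:
        rec = [t for t, c in enumerate(self.codes)
               if c != 0 and c % 2 == 0]
        if len(rec) > 1:
            raise ValueError(f"{self.individual.id}: multiple dead recoveries")
        if rec:
            after = self.codes[rec[0] + 1:]
            if np.any(after != 0):
                raise ValueError(
                    f"{self.individual.id}: detection after dead recovery")


@dataclass
class EffortCovariates:
    """Per-(inside subarea, occasion) monitoring-effort covariates.

    systmon in [0, 1]: monthly systematic-session indicator averaged over the
    subarea and occasion.  oppmon in [1, 3]: cantonal opportunistic-effort
    scores averaged within each (sub)area, constant within a lynx year.
    """

    systmon: np.ndarray   # (n_inside, n_occasions)
    oppmon: np.ndarray    # (n_inside, n_occasions)

    def __post_init__(self):
        self.systmon = np.asarray(self.systmon, dtype=float)
        self.oppmon = np.asarray(self.oppmon, dtype=float)
        if np.any(self.systmon < 0) or np.any(self.systmon > 1):
            raise ValueError("systmon must lie in [0, 1]")
        if np.any(self.oppmon < 1) or np.any(self.oppmon > 3):
            raise ValueError("oppmon must lie in [1, 3]")

    @classmethod
    def zeros(cls, n_inside: int, n_occasions: int) -> "EffortCovariates":
        return cls(np.zeros((n_inside, n_occasions)),
                   np.ones((n_inside, n_occasions)))


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def area_index(location: str, space: StateSpace) -> int:
    try:
        return space.area_labels.index(location)
    except ValueError:
        raise ValueError(f"unknown subarea label {location!r}; "
                         f"expected one of {space.area_labels}") from None


def bin_to_occasions(records: Iterable[DetectionRecord], grid: OccasionGrid,
                     space: StateSpace) -> tuple[np.ndarray, list[str]]:
    """Collapse one individual's detections onto the occasion grid.

    Multiple detections in the same subarea and occasion collapse to a
    single detected-alive code.  When one occasion contains detections in
    different subareas the chronologically last detection wins and the
    conflict is logged.
    """
    codes = np.zeros(grid.n_occasions, dtype=np.int16)
    last_date: dict[int, dt.date] = {}
    conflicts: list[str] = []
    for rec in records:
        try:
            t = grid.occasion_of(rec.date)
        except ValueError as e:
            raise ValueError(f"{rec.individual_id}: {e}") from None
        area = area_index(rec.location, space)
        code = space.code_detected(area)
        if codes[t] not in (0, code):
            conflicts.append(
                f"{rec.individual_id}: occasion {t} detected in "
                f"{space.code_name(codes[t])} and {space.code_name(code)}; "
                "keeping the later detection")
            if rec.date >= last_date[t]:
                codes[t] = code
                last_date[t] = rec.date
        else:
            codes[t] = code
            last_date[t] = max(rec.date, last_date.get(t, rec.date))
    return codes, conflicts


def overlay_dead_recovery(codes: np.ndarray, recovery: DeadRecoveryRecord,
                          grid: OccasionGrid, space: StateSpace) -> np.ndarray:
    """Insert a recovered-dead code; recovery takes precedence over detection."""
    t = grid.occasion_of(recovery.date)
    area = area_index(recovery.location, space)
    codes = codes.copy()
    codes[t] = space.code_recovered(area)
    codes[t + 1:] = 0
    return codes


def assign_age_class(birth_lynx_year: Optional[int], current_lynx_year: int,
                     first_detection_year: int) -> int:
    """Juvenile in the first year of life, subadult in the second, adult after.

    Individuals with unknown birth year count as adults from first detection.
    """
    if birth_lynx_year is None:
        if current_lynx_year < first_detection_year:
            raise ValueError("current lynx year precedes first detection")
        return ADULT
    if current_lynx_year < birth_lynx_year:
        raise ValueError("current lynx year precedes birth year")
    return min(current_lynx_year - birth_lynx_year, ADULT)


def filter_single_flanks(flank_by_id: Mapping[str, str]
                         ) -> tuple[list[str], dict]:
    """Delete the less abundant single-flank pseudo-individual group.

    Both-flank individuals are always retained.  Among single-flank
    individuals the smaller side is deleted entirely (ties delete the
    left-only group; deterministic).  Returns (retained ids, report).
    """
    both = [i for i, f in flank_by_id.items() if f == "both"]
    left = [i for i, f in flank_by_id.items() if f == "left"]
    right = [i for i, f in flank_by_id.items() if f == "right"]
    if len(left) <= len(right):
        deleted_side, deleted, kept_single = "left", left, right
    else:
        deleted_side, deleted, kept_single = "right", right, left
    if not deleted:
        deleted_side = None
    retained = both + kept_single
    report = {
        "n_both": len(both), "n_left": len(left), "n_right": len(right),
        "deleted_side": deleted_side, "n_deleted": len(deleted),
        "deleted_ids": sorted(deleted),
    }
    return retained, report


def apply_record_cleanup(history: EncounterHistory, space: StateSpace
                         ) -> tuple[Optional[EncounterHistory], dict]:
    """Single-outside-record deletion and censoring at translocation.

    A lone outside detection flanked by inside detections is removed (the
    animal is treated as having stayed inside).  Occasions at and after the
    censor occasion are blanked; an individual whose first record is the
    translocation capture is dropped (returns None).
    """
    ind = history.individual
    codes = history.codes.copy()
    report = {"id": ind.id, "outside_record_deleted": False,
              "censored": False, "excluded": False}

    outside_code = space.code_detected(space.n_areas - 1)
    inside_codes = {space.code_detected(a) for a in range(space.n_inside)}
    out_t = np.flatnonzero(codes == outside_code)
    if len(out_t) == 1:
        t = out_t[0]
        before = np.isin(codes[:t], list(inside_codes)).any()
        after = np.isin(codes[t + 1:], list(inside_codes)).any()
        if before and after:
            codes[t] = 0
            report["outside_record_deleted"] = True

    if ind.censor_occasion is not None:
        detected = np.flatnonzero(codes != 0)
        if len(detected) == 0 or detected[0] >= ind.censor_occasion:
            report["excluded"] = True
            return None, report
        codes[ind.censor_occasion:] = 0
        report["censored"] = True

    out = EncounterHistory(ind, codes, history.age_class.copy())
    return out, report


def build_age_classes(individual: Individual, grid: OccasionGrid,
                      first_detection_year: int) -> np.ndarray:
    """Per-occasion age class, advancing at lynx-year boundaries."""
    ages = np.empty(grid.n_occasions, dtype=np.int8)
    for t in range(grid.n_occasions):
        ly = grid.lynx_year_of_occasion(t)
        if individual.birth_lynx_year is None:
            ages[t] = ADULT
        else:
            ages[t] = min(max(ly - individual.birth_lynx_year, 0), ADULT)
    return ages


# ---------------------------------------------------------------------------
# the assembled dataset used by the likelihood
# ---------------------------------------------------------------------------

@dataclass
class MultiStateDataset:
    """Encounter histories on the occasion grid in dense array form.

    first is the first-capture occasion, last the exclusive end of each
    individual's likelihood window (censor occasion, or the grid length).
    """

    space: StateSpace
    grid: OccasionGrid
    ids: list[str]
    codes: np.ndarray       # (n, T) int16
    first: np.ndarray       # (n,) int
    last: np.ndarray        # (n,) int, exclusive
    age: np.ndarray         # (n, T) int8
    telemetry: np.ndarray   # (n, T) bool
    sex: np.ndarray         # (n,) int8; -1 unknown
    effort: EffortCovariates
    year_index: np.ndarray  # (T,) int

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        if np.any(self.first >= self.last):
            bad = [self.ids[i] for i in np.flatnonzero(self.first >= self.last)]
            raise ValueError(f"empty likelihood window for {bad}")
        for i in range(self.n_individuals):
            c = self.codes[i, self.first[i]]
            if c == 0:
                raise ValueError(f"{self.ids[i]}: not detected at first occasion")
            if c % 2 == 0:
                raise ValueError(
                    f"{self.ids[i]}: first observation is a dead recovery")


def build_dataset(histories: Sequence[EncounterHistory], grid: OccasionGrid,
                  space: StateSpace, effort: EffortCovariates | None = None
                  ) -> MultiStateDataset:
    """Assemble validated encounter histories into dense arrays."""
    if effort is None:
        effort = EffortCovariates.zeros(space.n_inside, grid.n_occasions)
    n, T = len(histories), grid.n_occasions
    codes = np.zeros((n, T), dtype=np.int16)
    first = np.zeros(n, dtype=int)
    last = np.full(n, T, dtype=int)
    age = np.zeros((n, T), dtype=np.int8)
    tel = np.zeros((n, T), dtype=bool)
    sex = np.zeros(n, dtype=np.int8)
    ids = []
    for i, h in enumerate(histories):
        h.validate(space)
        detected = np.flatnonzero(h.codes != 0)
        if len(detected) == 0:
            raise ValueError(f"{h.individual.id}: history has no observations")
        codes[i] = h.codes
        first[i] = detected[0]
        if h.individual.censor_occasion is not None:
            last[i] = min(T, h.individual.censor_occasion)
        age[i] = h.age_class
        for t in h.individual.telemetry_occasions:
            if 0 <= t < T:
                tel[i, t] = True
        sex[i] = h.individual.sex
        ids.append(h.individual.id)
    year_index = np.array([grid.year_index_of_occasion(t) for t in range(T)])
    ds = MultiStateDataset(space, grid, ids, codes, first, last, age, tel,
                           sex, effort, year_index)
    ds.validate()
    return ds


def preprocess(detections: Sequence[DetectionRecord],
               recoveries: Sequence[DeadRecoveryRecord],
               individuals_meta: Mapping[str, dict],
               grid: OccasionGrid, space: StateSpace,
               effort: EffortCovariates | None = None,
               apply_flank_filter: bool = True
               ) -> tuple[MultiStateDataset, dict]:
    """Full preprocessing: flank filter, binning, cleanup, dataset assembly.

    individuals_meta maps id -> dict with optional keys sex, birth_lynx_year,
    censor_occasion, telemetry_occasions, flank.  Returns the dataset and a
    bookkeeping report of every deletion.
    """
    det_by_id: dict[str, list[DetectionRecord]] = {}
    for r in detections:
        det_by_id.setdefault(r.individual_id, []).append(r)
    rec_by_id = {r.individual_id: r for r in recoveries
                 if r.individual_id is not None}

    flank_by_id = {}
    for iid, recs in det_by_id.items():
        meta_flank = individuals_meta.get(iid, {}).get("flank")
        if meta_flank is None:
            sides = {r.flank for r in recs}
            meta_flank = "both" if ("both" in sides or len(sides) > 1) \
                else next(iter(sides))
        flank_by_id[iid] = meta_flank
    if apply_flank_filter:
        retained, flank_report = filter_single_flanks(flank_by_id)
    else:
        retained = list(flank_by_id)
        flank_report = {"n_deleted": 0, "deleted_side": None,
                        "deleted_ids": []}

    histories = []
    cleanup_reports = []
    n_carcass_only = 0
    for iid in sorted(retained):
        meta = individuals_meta.get(iid, {})
        codes, conflicts = bin_to_occasions(det_by_id[iid], grid, space)
        if iid in rec_by_id:
            codes = overlay_dead_recovery(codes, rec_by_id[iid], grid, space)
        detected = np.flatnonzero(codes != 0)
        if len(detected) == 0:
            continue
        sex = meta.get("sex", -1)
        if isinstance(sex, str):
            sex = SEX_CODE[sex]
        ind = Individual(
            id=iid, sex=sex,
            birth_lynx_year=meta.get("birth_lynx_year"),
            first_occasion=int(detected[0]),
            censor_occasion=meta.get("censor_occasion"),
            telemetry_occasions=frozenset(meta.get("telemetry_occasions", ())),
        )
        first_year = grid.lynx_year_of_occasion(ind.first_occasion)
        ages = build_age_classes(ind, grid, first_year)
        hist = EncounterHistory(ind, codes, ages)
        hist, rep = apply_record_cleanup(hist, space)
        rep["conflicts"] = conflicts
        cleanup_reports.append(rep)
        if hist is None:
            continue
        detected = np.flatnonzero(hist.codes != 0)
        if len(detected) == 0:
            continue
        if hist.codes[detected[0]] % 2 == 0:
            # carcass found before any live detection: no encounter history
            n_carcass_only += 1
            continue
        hist.individual.first_occasion = int(detected[0])
        histories.append(hist)

    ds = build_dataset(histories, grid, space, effort)
    report = {
        "flank_filter": flank_report,
        "n_individuals": ds.n_individuals,
        "n_excluded_translocation": sum(r["excluded"] for r in cleanup_reports),
        "n_censored": sum(r["censored"] for r in cleanup_reports),
        "n_outside_records_deleted":
            sum(r["outside_record_deleted"] for r in cleanup_reports),
        "n_carcass_only": n_carcass_only,
        "cleanup": cleanup_reports,
    }
    return ds, report


# ---------------------------------------------------------------------------
# file I/O (plain CSV / JSON)
# ---------------------------------------------------------------------------

def read_detections(path) -> list[DetectionRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    return [DetectionRecord(row.id, dt.date.fromisoformat(row.date),
                            row.subarea, row.source, row.flank)
            for row in df.itertuples()]


def read_dead_recoveries(path) -> list[DeadRecoveryRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    out = []
    for row in df.itertuples():
        by = None if pd.isna(row.birth_lynx_year) else int(row.birth_lynx_year)
        out.append(DeadRecoveryRecord(row.id, dt.date.fromisoformat(row.date),
                                      row.subarea, row.sex, by))
    return out


def read_individuals(path) -> dict[str, dict]:
    df = pd.read_csv(path, dtype={"id": str})
    meta = {}
    for row in df.itertuples():
        d: dict = {"sex": row.sex}
        if not pd.isna(row.birth_lynx_year):
            d["birth_lynx_year"] = int(row.birth_lynx_year)
        if "censor_occasion" in df.columns and not pd.isna(row.censor_occasion):
            d["censor_occasion"] = int(row.censor_occasion)
        if "telemetry_occasions" in df.columns and \
                isinstance(row.telemetry_occasions, str) and row.telemetry_occasions:
            d["telemetry_occasions"] = [
                int(x) for x in row.telemetry_occasions.split(";")]
        meta[row.id] = d
    return meta


def read_effort(path, grid: OccasionGrid, space: StateSpace) -> EffortCovariates:
    df = pd.read_csv(path)
    systmon = np.zeros((space.n_inside, grid.n_occasions))
    oppmon = np.ones((space.n_inside, grid.n_occasions))
    for row in df.itertuples():
        a = area_index(row.subarea, space)
        systmon[a, int(row.occasion)] = row.systmon
        oppmon[a, int(row.occasion)] = row.oppmon
    return EffortCovariates(systmon, oppmon)


def read_ages_at_death(path) -> list[AgeAtDeathRecord]:
    df = pd.read_csv(path)
    return [AgeAtDeathRecord(SEX_CODE[row.sex], int(row.age_years))
            for row in df.itertuples()]


def write_histories(path, histories: Sequence[EncounterHistory],
                    grid: OccasionGrid, space: StateSpace) -> None:
    payload = {
        "layout": space.layout,
        "grid": grid.to_dict(),
        "individuals": [
            {
                "id": h.individual.id,
                "sex": SEX_NAME[h.individual.sex],
                "birth_lynx_year": h.individual.birth_lynx_year,
                "first_occasion": h.individual.first_occasion,
                "censor_occasion": h.individual.censor_occasion,
                "telemetry_occasions":
                    sorted(h.individual.telemetry_occasions),
                "codes": [space.code_name(int(c)) for c in h.codes],
                "age_class": [AGE_NAMES[a] for a in h.age_class],
            }
            for h in histories
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_histories(path) -> tuple[list[EncounterHistory], OccasionGrid, StateSpace]:
    with open(path) as fh:
        payload = json.load(fh)
    space = StateSpace(payload["layout"])
    grid = OccasionGrid.from_dict(payload["grid"])
    histories = []
    for d in payload["individuals"]:
        ind = Individual(
            id=d["id"], sex=SEX_CODE[d["sex"]],
            birth_lynx_year=d["birth_lynx_year"],
            first_occasion=d["first_occasion"],
            censor_occasion=d["censor_occasion"],
            telemetry_occasions=frozenset(d["telemetry_occasions"]),
        )
        codes = np.array([space.code_from_name(c) for c in d["codes"]],
                         dtype=np.int16)
        ages = np.array([AGE_NAMES.index(a) for a in d["age_class"]],
                        dtype=np.int8)
        histories.append(EncounterHistory(ind, codes, ages))
    return histories, grid, space
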