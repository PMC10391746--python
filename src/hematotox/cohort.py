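"""Cohort data model and CSV input/output.

A cohort is stored as four CSV files in one directory:

``patients.csv``
    One row per patient: baseline labs with their sample days (relative to
    the start of lymphodepletion; negative = before), the day
    lymphodepletion started (relative to CAR-T infusion = day 0), baseline
    covariates and survival outcomes.
``labs.csv``
    Longitudinal labs: ``patient_id, day, analyte, value, unit`` with
    ``day`` relative to infusion.  Analytes: ``anc``, ``platelets``,
    ``hemoglobin`` (and optionally ``crp``/``ferritin`` for pre-infusion
    baseline candidates).
``infections.csv``
    ``patient_id, onset_day, category, source, grade``.
``events.csv``
    ``patient_id, day, event_type`` for supportive-care events
    (transfusions, G-CSF, TPO agonists, stem cell boosts).

Canonical units are ANC and platelets in G/l (10^9/l), hemoglobin in g/dl,
CRP in mg/dl, ferritin in ng/ml.  ``labs.csv`` rows may carry per-µl counts
with an explicit ``per_ul`` unit and are divided by 1000 on read; units are
never guessed from magnitude.  Missing values are empty cells, never 0
(0 is a legal ANC).

All day arithmetic uses integer study days; CAR-T infusion is day 0.
Windows such as "days 0–60" are closed integer intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError

ANALYTES = ("anc", "hemoglobin", "platelets", "crp", "ferritin")
SERIES_ANALYTES = ("anc", "platelets", "hemoglobin")
INFECTION_CATEGORIES = ("bacterial", "viral", "fungal", "clinical_syndrome")
DEATH_CAUSES = ("none", "progression", "infection", "CRS", "cardiotoxicity", "other")
RESPONSES = ("sCR", "CR", "VGPR", "PR", "SD", "PD", "not_evaluable")
EVENT_TYPES = (
    "platelet_transfusion",
    "prbc_transfusion",
    "gcsf",
    "tpo_agonist",
    "stem_cell_boost",
)

#: units accepted per analyte; the canonical unit is listed first
_UNITS = {
    "anc": ("g_per_l", "per_ul"),
    "platelets": ("g_per_l", "per_ul"),
    "hemoglobin": ("g_per_dl",),
    "crp": ("mg_per_dl",),
    "ferritin": ("ng_per_ml",),
}


def normalize_value(analyte: str, value: float, unit: str) -> float:
    """Convert a lab value to its canonical unit.

    Idempotent: a value already in the canonical unit is returned unchanged.
    Per-µl neutrophil/platelet counts are divided by 1000 to give G/l.
    """
    if analyte not in _UNITS:
        raise CohortValidationError(f"unknown analyte {analyte!r}")
    if unit not in _UNITS[analyte]:
        raise CohortValidationError(f"unit {unit!r} not valid for analyte {analyte!r}")
    if unit == "per_ul":
        return value / 1000.0
    return value


@dataclass(frozen=True)
class BaselineLabs:
    """Selected pre-lymphodepletion labs, one (value, sample_day) per analyte.

    ``sample_day`` is relative to the start of lymphodepletion (0 = the day
    lymphodepletion started, negative = before).  A missing analyte is
    ``None`` for both value and day.
    """

    anc: float | None = None
    anc_day: int | None = None
    hemoglobin: float | None = None
    hemoglobin_day: int | None = None
    platelets: float | None = None
    platelets_day: int | None = None
    crp: float | None = None
    crp_day: int | None = None
    ferritin: float | None = None
    ferritin_day: int | None = None

    def value(self, analyte: str) -> float | None:
        return getattr(self, "anc" if analyte == "anc" else analyte)

    def day(self, analyte: str) -> int | None:
        return getattr(self, f"{analyte}_day" if analyte != "anc" else "anc_day")

    def missing(self) -> list[str]:
        return [a for a in ANALYTES if self.value(a) is None]


@dataclass(frozen=True)
class LabSeries:
    """Ordered (day, value) pairs for one analyte, day 0 = CAR-T infusion."""

    days: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.days) != len(self.values):
            raise CohortValidationError("days and values differ in length")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise CohortValidationError("series days must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise CohortValidationError("lab values must be >= 0")

    def __len__(self) -> int:
        return len(self.days)

    def in_window(self, start: int, end: int) -> "LabSeries":
        pairs = [(d, v) for d, v in zip(self.days, self.values) if start <= d <= end]
        return LabSeries(tuple(d for d, _ in pairs), tuple(v for _, v in pairs))


@dataclass(frozen=True)
class InfectionEvent:
    """One infection event: onset is the day of the diagnostic test.

    Severity uses the 5-grade scale (1 mild ... 5 fatal); grade >= 3 is
    "severe" (requiring IV anti-infectives and/or hospitalization).
    Neutropenic fever alone is not an infection event and is dropped on read.
    """

    onset_day: int
    category: str
    source: str
    grade: int

    def __post_init__(self):
        if self.category not in INFECTION_CATEGORIES:
            raise CohortValidationError(f"unknown infection category {self.category!r}")
        if self.grade not in (1, 2, 3, 4, 5):
            raise CohortValidationError(f"infection grade must be 1-5, got {self.grade}")


@dataclass(frozen=True)
class OutcomeRecord:
    """Survival outcomes in months from CAR-T infusion."""

    pfs_time: float
    pfs_event: int
    os_time: float
    os_event: int
    death_cause: str = "none"
    response: str = "not_evaluable"

    def __post_init__(self):
        if self.pfs_time > self.os_time + 1e-9:
            raise CohortValidationError("pfs_time must be <= os_time")
        if self.death_cause not in DEATH_CAUSES:
            raise CohortValidationError(f"unknown death cause {self.death_cause!r}")
        if (self.death_cause == "none") != (self.os_event == 0):
            raise CohortValidationError("death_cause must be 'none' iff os_event == 0")
        if self.response not in RESPONSES:
            raise CohortValidationError(f"unknown response {self.response!r}")

    @property
    def nrm_event(self) -> bool:
        """Death without prior progression/relapse (non-relapse mortality)."""
        return self.os_event == 1 and self.death_cause != "progression"


@dataclass(frozen=True)
class Covariates:
    egfr: float | None = None
    ldh_above_uln: bool | None = None
    ecog: int | None = None
    bm_plasma_cell_pct: float | None = None
    prior_bcma_therapy: bool | None = None
    crs_max_grade: int | None = None
    icans_max_grade: int | None = None
    hospital_days: int | None = None

    def __post_init__(self):
        if self.ecog is not None and self.ecog not in range(5):
            raise CohortValidationError("ecog must be in 0..4")
        if self.bm_plasma_cell_pct is not None and not (
            0 <= self.bm_plasma_cell_pct <= 100
        ):
            raise CohortValidationError("bm_plasma_cell_pct must be in [0, 100]")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    ld_start_day: int = -5
    baseline: BaselineLabs = field(default_factory=BaselineLabs)
    #: extra pre-lymphodepletion candidates per analyte, days relative to
    #: lymphodepletion start: {analyte: ((day, value), ...)}
    baseline_candidates: dict = field(default_factory=dict)
    anc_series: LabSeries | None = None
    platelet_series: LabSeries | None = None
    hemoglobin_series: LabSeries | None = None
    platelet_transfusion_days: tuple[int, ...] = ()
    prbc_transfusion_days: tuple[int, ...] = ()
    other_events: tuple[tuple[int, str], ...] = ()
    infections: tuple[InfectionEvent, ...] = ()
    outcome: OutcomeRecord | None = None
    covariates: Covariates = field(default_factory=Covariates)


@dataclass
class ValidationReport:
    """Rows dropped or flagged during reading; never silent."""

    flags: list[str] = field(default_factory=list)

    def add(self, patient_id: str, message: str) -> None:
        self.flags.append(f"{patient_id}: {message}")

    def __len__(self) -> int:
        return len(self.flags)


@dataclass
class Cohort:
    records: list[PatientRecord]
    report: ValidationReport = field(default_factory=ValidationReport)
    #: generator-side metadata (e.g. latent stratum per patient); not persisted
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# CSV schemas

_PATIENT_COLUMNS = [
    "patient_id",
    "ld_start_day",
    "anc_baseline", "anc_sample_day",
    "hemoglobin_baseline", "hemoglobin_sample_day",
    "platelets_baseline", "platelets_sample_day",
    "crp_baseline", "crp_sample_day",
    "ferritin_baseline", "ferritin_sample_day",
    "egfr", "ldh_above_uln", "ecog", "bm_plasma_cell_pct", "prior_bcma_therapy",
    "crs_max_grade", "icans_max_grade", "hospital_days",
    "pfs_time", "pfs_event", "os_time", "os_event", "death_cause", "response",
]
_LAB_COLUMNS = ["patient_id", "day", "analyte", "value", "unit"]
_INFECTION_COLUMNS = ["patient_id", "onset_day", "category", "source", "grade"]
_EVENT_COLUMNS = ["patient_id", "day", "event_type"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], fname: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing mandatory column(s) {missing}")


def _opt_float(row, col) -> float | None:
    v = row[col]
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise CohortValidationError(
            f"{row['patient_id']}: non-numeric value {v!r} in column {col}"
        )


def _opt_int(row, col) -> int | None:
    v = _opt_float(row, col)
    return None if v is None else int(v)


def _opt_bool(row, col) -> bool | None:
    v = row[col]
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "1.0", "yes"):
        return True
    if s in ("false", "0", "0.0", "no"):
        return False
    raise CohortValidationError(f"{row['patient_id']}: non-boolean value {v!r} in {col}")


def read_cohort(path: str | Path, schema_version: str = "1") -> Cohort:
    """Read and validate a cohort directory.

    Returns a :class:`Cohort` whose ``report`` lists every dropped or
    flagged row with the patient id and field concerned.  Duplicate lab
    draws on the same day keep the minimum value (conservative) and are
    flagged.  Rows labelled ``neutropenic_fever`` in infections.csv are
    dropped (neutropenic fever alone is not an infection event) and flagged.
    """
    path = Path(path)
    report = ValidationReport()

    patients = pd.read_csv(path / "patients.csv", dtype={"patient_id": str})
    _require_columns(patients, _PATIENT_COLUMNS, "patients.csv")
    dupes = patients["patient_id"][patients["patient_id"].duplicated()]
    if len(dupes):
        raise CohortValidationError(
            f"patients.csv: duplicate patient_id {sorted(set(dupes))}"
        )

    labs = pd.read_csv(path / "labs.csv", dtype={"patient_id": str})
    _require_columns(labs, _LAB_COLUMNS, "labs.csv")
    infections = pd.read_csv(path / "infections.csv", dtype={"patient_id": str})
    _require_columns(infections, _INFECTION_COLUMNS, "infections.csv")
    events = pd.read_csv(path / "events.csv", dtype={"patient_id": str})
    _require_columns(events, _EVENT_COLUMNS, "events.csv")

    known_ids = set(patients["patient_id"])
    for fname, df in (("labs.csv", labs), ("infections.csv", infections),
                      ("events.csv", events)):
        for pid in set(df["patient_id"]) - known_ids:
            report.add(pid, f"{fname}: unknown patient_id, rows dropped")

    records: list[PatientRecord] = []
    labs_by_pid = dict(tuple(labs.groupby("patient_id", sort=False)))
    inf_by_pid = dict(tuple(infections.groupby("patient_id", sort=False)))
    ev_by_pid = dict(tuple(events.groupby("patient_id", sort=False)))

    for _, prow in patients.iterrows():
        pid = prow["patient_id"]
        ld_start = _opt_int(prow, "ld_start_day")
        if ld_start is None:
            raise CohortValidationError(f"{pid}: ld_start_day is mandatory")

        base_kwargs = {}
        for a in ANALYTES:
            v = _opt_float(prow, f"{a}_baseline")
            d = _opt_int(prow, f"{a}_sample_day")
            if (v is None) != (d is None):
                raise CohortValidationError(
                    f"{pid}: baseline {a} must have both value and sample_day or neither"
                )
            if v is not None and v < 0:
                raise CohortValidationError(f"{pid}: negative baseline {a}")
            key = "anc" if a == "anc" else a
            base_kwargs[key] = v
            base_kwargs[f"{key}_day" if a != "anc" else "anc_day"] = d
        baseline = BaselineLabs(**base_kwargs)

        series: dict[str, LabSeries | None] = {a: None for a in SERIES_ANALYTES}
        candidates: dict[str, list[tuple[int, float]]] = {}
        if pid in labs_by_pid:
            sub = labs_by_pid[pid]
            for analyte, grp in sub.groupby("analyte", sort=False):
                if analyte not in ANALYTES:
                    report.add(pid, f"labs.csv: unknown analyte {analyte!r}, rows dropped")
                    continue
                rows = []
                for _, lrow in grp.iterrows():
                    val = _opt_float(lrow, "value")
                    if val is None:
                        report.add(pid, f"labs.csv: empty {analyte} value dropped")
                        continue
                    day = _opt_int(lrow, "day")
                    rows.append((day, normalize_value(analyte, val, str(lrow["unit"]))))
                # same-day duplicate draws: keep the minimum (conservative), flag
                by_day: dict[int, float] = {}
                for day, val in rows:
                    if day in by_day:
                        report.add(pid, f"duplicate {analyte} draw on day {day}; kept minimum")
                        by_day[day] = min(by_day[day], val)
                    else:
                        by_day[day] = val
                ordered = sorted(by_day.items())
                if analyte in SERIES_ANALYTES:
                    post = [(d, v) for d, v in ordered if d >= ld_start]
                    if post:
                        series[analyte] = LabSeries(
                            tuple(d for d, _ in post), tuple(v for _, v in post)
                        )
                    # draws strictly before lymphodepletion are baseline
                    # candidates only; later draws live in the series (and
                    # are scanned by select_baseline_labs directly)
                    cand = [(d - ld_start, v) for d, v in ordered if d < ld_start]
                else:
                    cand = [(d - ld_start, v) for d, v in ordered]
                if cand:
                    candidates[analyte] = cand

        infs: list[InfectionEvent] = []
        if pid in inf_by_pid:
            for _, irow in inf_by_pid[pid].iterrows():
                cat = str(irow["category"])
                if cat == "neutropenic_fever":
                    report.add(pid, "neutropenic fever alone is not an infection event; dropped")
                    continue
                grade = _opt_int(irow, "grade")
                if grade not in (1, 2, 3, 4, 5):
                    raise CohortValidationError(
                        f"{pid}: infection grade must be 1-5, got {grade}"
                    )
                infs.append(InfectionEvent(
                    onset_day=_opt_int(irow, "onset_day"),
                    category=cat,
                    source=str(irow["source"]),
                    grade=grade,
                ))
        infs.sort(key=lambda e: (e.onset_day, e.category, e.grade))

        plt_tx: list[int] = []
        prbc_tx: list[int] = []
        other: list[tuple[int, str]] = []
        if pid in ev_by_pid:
            for _, erow in ev_by_pid[pid].iterrows():
                etype = str(erow["event_type"])
                day = _opt_int(erow, "day")
                if etype not in EVENT_TYPES:
                    report.add(pid, f"events.csv: unknown event_type {etype!r}, dropped")
                    continue
                if etype == "platelet_transfusion":
                    plt_tx.append(day)
                elif etype == "prbc_transfusion":
                    prbc_tx.append(day)
                else:
                    other.append((day, etype))

        outcome = None
        if _opt_float(prow, "pfs_time") is not None:
            outcome = OutcomeRecord(
                pfs_time=_opt_float(prow, "pfs_time"),
                pfs_event=_opt_int(prow, "pfs_event"),
                os_time=_opt_float(prow, "os_time"),
                os_event=_opt_int(prow, "os_event"),
                death_cause=str(prow["death_cause"]),
                response=str(prow["response"]),
            )

        cov = Covariates(
            egfr=_opt_float(prow, "egfr"),
            ldh_above_uln=_opt_bool(prow, "ldh_above_uln"),
            ecog=_opt_int(prow, "ecog"),
            bm_plasma_cell_pct=_opt_float(prow, "bm_plasma_cell_pct"),
            prior_bcma_therapy=_opt_bool(prow, "prior_bcma_therapy"),
            crs_max_grade=_opt_int(prow, "crs_max_grade"),
            icans_max_grade=_opt_int(prow, "icans_max_grade"),
            hospital_days=_opt_int(prow, "hospital_days"),
        )

        records.append(PatientRecord(
            patient_id=pid,
            ld_start_day=ld_start,
            baseline=baseline,
            baseline_candidates={k: tuple(v) for k, v in candidates.items()},
            anc_series=series["anc"],
            platelet_series=series["platelets"],
            hemoglobin_series=series["hemoglobin"],
            platelet_transfusion_days=tuple(sorted(plt_tx)),
            prbc_transfusion_days=tuple(sorted(prbc_tx)),
            other_events=tuple(sorted(other)),
            infections=tuple(infs),
            outcome=outcome,
            covariates=cov,
        ))

    return Cohort(records=records, report=report)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_cohort(cohort: Cohort | Iterable[PatientRecord], path: str | Path) -> None:
    """Write a cohort to the four-file CSV layout.

    Output is deterministic (sorted by patient id and day), so writing the
    same cohort twice produces byte-identical files, and
    ``read_cohort(write_cohort(x))`` round-trips.
    """
    records = list(cohort.records if isinstance(cohort, Cohort) else cohort)
    records = sorted(records, key=lambda r: r.patient_id)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    prow_list = []
    lab_rows = []
    inf_rows = []
    ev_rows = []
    for r in records:
        b, o, c = r.baseline, r.outcome, r.covariates
        prow_list.append({
            "patient_id": r.patient_id,
            "ld_start_day": r.ld_start_day,
            "anc_baseline": _fmt(b.anc), "anc_sample_day": _fmt(b.anc_day),
            "hemoglobin_baseline": _fmt(b.hemoglobin),
            "hemoglobin_sample_day": _fmt(b.hemoglobin_day),
            "platelets_baseline": _fmt(b.platelets),
            "platelets_sample_day": _fmt(b.platelets_day),
            "crp_baseline": _fmt(b.crp), "crp_sample_day": _fmt(b.crp_day),
            "ferritin_baseline": _fmt(b.ferritin),
            "ferritin_sample_day": _fmt(b.ferritin_day),
            "egfr": _fmt(c.egfr), "ldh_above_uln": _fmt(c.ldh_above_uln),
            "ecog": _fmt(c.ecog), "bm_plasma_cell_pct": _fmt(c.bm_plasma_cell_pct),
            "prior_bcma_therapy": _fmt(c.prior_bcma_therapy),
            "crs_max_grade": _fmt(c.crs_max_grade),
            "icans_max_grade": _fmt(c.icans_max_grade),
            "hospital_days": _fmt(c.hospital_days),
            "pfs_time": _fmt(o.pfs_time) if o else "",
            "pfs_event": _fmt(o.pfs_event) if o else "",
            "os_time": _fmt(o.os_time) if o else "",
            "os_event": _fmt(o.os_event) if o else "",
            "death_cause": o.death_cause if o else "",
            "response": o.response if o else "",
        })
        for analyte, series in (
            ("anc", r.anc_series),
            ("platelets", r.platelet_series),
            ("hemoglobin", r.hemoglobin_series),
        ):
            if series is None:
                continue
            unit = _UNITS[analyte][0]
            for d, v in zip(series.days, series.values):
                lab_rows.append({"patient_id": r.patient_id, "day": d,
                                 "analyte": analyte, "value": _fmt(float(v)),
                                 "unit": unit})
        for analyte, pairs in sorted(r.baseline_candidates.items()):
            for d, v in pairs:
                abs_day = d + r.ld_start_day
                # series analytes sampled at/after LD start already live in the
                # series rows above; only strictly earlier candidates are extra
                if analyte in SERIES_ANALYTES and abs_day >= r.ld_start_day:
                    continue
                lab_rows.append({"patient_id": r.patient_id, "day": abs_day,
                                 "analyte": analyte, "value": _fmt(float(v)),
                                 "unit": _UNITS[analyte][0]})
        for e in r.infections:
            inf_rows.append({"patient_id": r.patient_id, "onset_day": e.onset_day,
                             "category": e.category, "source": e.source,
                             "grade": e.grade})
        for d in r.platelet_transfusion_days:
            ev_rows.append({"patient_id": r.patient_id, "day": d,
                            "event_type": "platelet_transfusion"})
        for d in r.prbc_transfusion_days:
            ev_rows.append({"patient_id": r.patient_id, "day": d,
                            "event_type": "prbc_transfusion"})
        for d, etype in r.other_events:
            ev_rows.append({"patient_id": r.patient_id, "day": d,
                            "event_type": etype})

    pd.DataFrame(prow_list, columns=_PATIENT_COLUMNS).to_csv(
        path / "patients.csv", index=False)
    lab_df = pd.DataFrame(lab_rows, columns=_LAB_COLUMNS)
    if len(lab_df):
        lab_df = lab_df.sort_values(["patient_id", "analyte", "day"],
                                    kind="mergesort")
    lab_df.to_csv(path / "labs.csv", index=False)
    inf_df = pd.DataFrame(inf_rows, columns=_INFECTION_COLUMNS)
    if len(inf_df):
        inf_df = inf_df.sort_values(["patient_id", "onset_day"], kind="mergesort")
    inf_df.to_csv(path / "infections.csv", index=False)
    ev_df = pd.DataFrame(ev_rows, columns=_EVENT_COLUMNS)
    if len(ev_df):
        ev_df = ev_df.sort_values(["patient_id", "day", "event_type"],
                                  kind="mergesort")
    ev_df.to_csv(path / "events.csv", index=False)
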