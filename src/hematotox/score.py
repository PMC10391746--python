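"""CAR-HEMATOTOX score: a 0–7 point rubric over five pre-lymphodepletion labs.

One point each for ANC <= 1.2 G/l (1200/µl), hemoglobin <= 9.0 g/dl,
platelets in the 76–175 G/l band, CRP >= 3.0 mg/dl, and ferritin in the
650–2000 ng/ml band; two points for platelets <= 75 G/l or ferritin
>= 2000 ng/ml.  A total of 2 or more is high risk (HT-high), 0–1 low risk.

Labs are taken before the start of lymphodepleting chemotherapy, with a
leniency window of up to three days before the start; for each analyte the
draw closest to the start wins (ties broken toward the later draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import ANALYTES, BaselineLabs, Cohort, PatientRecord
from .errors import ScoringError

HIGH_RISK_THRESHOLD = 2
MAX_SCORE = 7


@dataclass(frozen=True)
class HTScoreResult:
    points_anc: int
    points_hb: int
    points_plt: int
    points_crp: int
    points_ferritin: int
    total: int
    risk_class: str  # "low" | "high"
    components_used: BaselineLabs
    imputed_zero: tuple[str, ...] = ()  # analytes scored 0 under zero_points policy


def _points_anc(v: float) -> int:
    return 1 if v <= 1.2 else 0


def _points_hb(v: float) -> int:
    return 1 if v <= 9.0 else 0


def _points_plt(v: float) -> int:
    # printed bands "<= 75" / "76–175" / "> 175"; implemented on the
    # continuum as <= 75 / (75, 175] / > 175 so non-integer counts are defined
    if v <= 75:
        return 2
    if v <= 175:
        return 1
    return 0


def _points_crp(v: float) -> int:
    return 1 if v >= 3.0 else 0


def _points_ferritin(v: float) -> int:
    if v >= 2000:
        return 2
    if v >= 650:
        return 1
    return 0


_POINT_FUNCS = {
    "anc": _points_anc,
    "hemoglobin": _points_hb,
    "platelets": _points_plt,
    "crp": _points_crp,
    "ferritin": _points_ferritin,
}


def score_components(labs: BaselineLabs,
                     missing_policy: str = "strict") -> HTScoreResult:
    """Score one patient's baseline labs.

    With ``missing_policy="strict"`` (default) a missing analyte raises
    :class:`ScoringError`; with ``"zero_points"`` it scores 0 and is listed
    in ``imputed_zero`` so exploratory use is always flagged.
    """
    if missing_policy not in ("strict", "zero_points"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    missing = labs.missing()
    if missing and missing_policy == "strict":
        raise ScoringError(f"missing analyte(s) for scoring: {missing}")

    pts = {}
    for a in ANALYTES:
        v = labs.value(a)
        pts[a] = 0 if v is None else _POINT_FUNCS[a](v)
    total = sum(pts.values())
    return HTScoreResult(
        points_anc=pts["anc"],
        points_hb=pts["hemoglobin"],
        points_plt=pts["platelets"],
        points_crp=pts["crp"],
        points_ferritin=pts["ferritin"],
        total=total,
        risk_class="high" if total >= HIGH_RISK_THRESHOLD else "low",
        components_used=labs,
        imputed_zero=tuple(missing),
    )


def select_baseline_labs(record: PatientRecord,
                         leniency_days: int = 3,
                         missing_policy: str = "strict",
                         window: str = "before") -> BaselineLabs:
    """Pick the lab draw to score for each analyte.

    Candidates are the per-analyte ``(sample_day, value)`` pairs from the
    patient row plus any pre-infusion draws in the longitudinal labs, with
    sample days relative to the start of lymphodepletion.  Eligible draws
    lie in ``[-leniency_days, 0]`` (``window="before"``, default: values
    after the start of chemotherapy are never scored) or
    ``[-leniency_days, +leniency_days]`` (``window="symmetric"``).  The draw
    with the smallest ``|sample_day|`` wins; ties go to the later draw.
    """
    if window not in ("before", "symmetric"):
        raise ValueError(f"unknown window {window!r}")
    hi = 0 if window == "before" else leniency_days

    series_by_analyte = {
        "anc": record.anc_series,
        "platelets": record.platelet_series,
        "hemoglobin": record.hemoglobin_series,
    }
    chosen: dict[str, tuple[int, float] | None] = {}
    missing: list[str] = []
    for a in ANALYTES:
        cands: list[tuple[int, float]] = []
        v, d = record.baseline.value(a), record.baseline.day(a)
        if v is not None:
            cands.append((d, v))
        cands.extend(record.baseline_candidates.get(a, ()))
        series = series_by_analyte.get(a)
        if series is not None:
            # series days are infusion-anchored; re-anchor to LD start
            cands.extend((sd - record.ld_start_day, sv)
                         for sd, sv in zip(series.days, series.values)
                         if -leniency_days <= sd - record.ld_start_day <= hi)
        eligible = [(d, v) for d, v in cands if -leniency_days <= d <= hi]
        if not eligible:
            chosen[a] = None
            missing.append(a)
            continue
        # closest to lymphodepletion start; ties toward the later (larger) day
        chosen[a] = min(eligible, key=lambda dv: (abs(dv[0]), -dv[0]))

    if missing and missing_policy == "strict":
        raise ScoringError(
            f"{record.patient_id}: no eligible draw within the leniency window "
            f"for: {missing}"
        )

    def _get(a, idx):
        return None if chosen[a] is None else chosen[a][idx]

    return BaselineLabs(
        anc=_get("anc", 1), anc_day=_get("anc", 0),
        hemoglobin=_get("hemoglobin", 1), hemoglobin_day=_get("hemoglobin", 0),
        platelets=_get("platelets", 1), platelets_day=_get("platelets", 0),
        crp=_get("crp", 1), crp_day=_get("crp", 0),
        ferritin=_get("ferritin", 1), ferritin_day=_get("ferritin", 0),
    )


@dataclass
class CohortScores:
    table: pd.DataFrame
    results: dict = field(default_factory=dict)  # patient_id -> HTScoreResult
    unscoreable: dict = field(default_factory=dict)  # patient_id -> reason

    @property
    def counts(self) -> dict:
        vc = self.table["risk_class"].value_counts()
        return {"low": int(vc.get("low", 0)), "high": int(vc.get("high", 0))}


def score_cohort(cohort: Cohort | list[PatientRecord],
                 leniency_days: int = 3,
                 missing_policy: str = "strict") -> CohortScores:
    """Score every patient; failures are collected, never thrown."""
    records = cohort.records if isinstance(cohort, Cohort) else cohort
    rows, results, unscoreable = [], {}, {}
    for r in records:
        try:
            labs = select_baseline_labs(r, leniency_days, missing_policy)
            res = score_components(labs, missing_policy)
        except ScoringError as e:
            unscoreable[r.patient_id] = str(e)
            continue
        results[r.patient_id] = res
        rows.append({
            "patient_id": r.patient_id,
            "points_anc": res.points_anc,
            "points_hb": res.points_hb,
            "points_plt": res.points_plt,
            "points_crp": res.points_crp,
            "points_ferritin": res.points_ferritin,
            "total": res.total,
            "risk_class": res.risk_class,
            "anc_sample_day": labs.anc_day,
            "hemoglobin_sample_day": labs.hemoglobin_day,
            "platelets_sample_day": labs.platelets_day,
            "crp_sample_day": labs.crp_day,
            "ferritin_sample_day": labs.ferritin_day,
        })
    cols = ["patient_id", "points_anc", "points_hb", "points_plt", "points_crp",
            "points_ferritin", "total", "risk_class", "anc_sample_day",
            "hemoglobin_sample_day", "platelets_sample_day", "crp_sample_day",
            "ferritin_sample_day"]
    return CohortScores(table=pd.DataFrame(rows, columns=cols),
                        results=results, unscoreable=unscoreable)
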