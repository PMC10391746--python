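"""Neutropenia/cytopenia endpoints from longitudinal lab series.

Between lab draws, values are expanded onto an integer daily grid by
last-observation-carried-forward (LOCF); days before the first draw are
unknown and never count toward any threshold.  All day windows are closed
integer intervals anchored at CAR-T infusion = day 0.

Thresholds (ANC in G/l = 10^9/l):
  severe neutropenia   ANC < 0.5;   profound ANC < 0.1
  prolonged neutropenia ANC < 1.0 measured >= 21 days after infusion
  severe thrombocytopenia platelets < 50 G/l
  severe anemia        Hb < 8 g/dl or pRBC transfusion in the window

Neutrophil-recovery phenotypes (decision order):
  aplastic     continuous severe neutropenia (ANC < 0.5) for >= 14 days
  intermittent recovery (ANC > 1.5) followed by a second dip below 1.0
               after day 21
  quick        neither (sustained recovery without a qualifying dip)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import LabSeries, PatientRecord
from .errors import CohortValidationError

MEASURED, CARRIED, UNKNOWN = "measured", "carried_forward", "unknown"


@dataclass(frozen=True)
class DailyGrid:
    """Per-day LOCF expansion of a series; NaN where no prior measurement."""

    start_day: int
    values: np.ndarray      # float, NaN on unknown days
    provenance: np.ndarray  # str flags per day

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.start_day, self.start_day + len(self.values))

    def known(self) -> np.ndarray:
        return ~np.isnan(self.values)


def daily_grid(series: LabSeries, window: tuple[int, int]) -> DailyGrid:
    """Expand a series onto integer days ``window[0]..window[1]`` (closed).

    Measured days reproduce the raw series exactly; other days carry the
    most recent prior measurement forward (including measurements before the
    window); days before the first measurement are unknown.
    """
    if series is None or len(series) == 0:
        raise CohortValidationError("cannot build a daily grid from an empty series")
    start, end = window
    if end < start:
        raise ValueError("window end before start")
    n = end - start + 1
    values = np.full(n, np.nan)
    prov = np.full(n, UNKNOWN, dtype=object)
    s_days = np.asarray(series.days)
    s_vals = np.asarray(series.values, dtype=float)
    for i, day in enumerate(range(start, end + 1)):
        idx = np.searchsorted(s_days, day, side="right") - 1
        if idx < 0:
            continue
        values[i] = s_vals[idx]
        prov[i] = MEASURED if s_days[idx] == day else CARRIED
    return DailyGrid(start_day=start, values=values, provenance=prov)


def _threshold_days(grid: DailyGrid, threshold: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return (grid.values < threshold) & grid.known()


def _max_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def severe_neutropenia_days(record: PatientRecord,
                            window: tuple[int, int] = (0, 60),
                            mode: str = "locf") -> int:
    """Cumulative days with ANC < 0.5 G/l in the window (default days 0–60).

    ``mode="locf"`` counts grid days (default); ``mode="measured"`` counts
    only days with an actual draw (sensitivity analysis).  Unknown days
    contribute 0.  Raises if the ANC series has no draw inside the window.
    """
    if mode not in ("locf", "measured"):
        raise ValueError(f"unknown mode {mode!r}")
    series = record.anc_series
    if series is None or len(series.in_window(*window)) == 0:
        raise CohortValidationError(
            f"{record.patient_id}: no ANC measurement in window {window}"
        )
    grid = daily_grid(series, window)
    severe = _threshold_days(grid, 0.5)
    if mode == "measured":
        severe = severe & (grid.provenance == MEASURED)
    return int(severe.sum())


@dataclass(frozen=True)
class PhenotypeResult:
    label: str  # quick | intermittent | aplastic
    low_confidence: bool = False


def classify_phenotype(record: PatientRecord, horizon: int = 100) -> PhenotypeResult:
    """Classify the neutrophil-recovery trajectory over days [0, horizon].

    Aplastic takes precedence over intermittent; quick is the residual
    class, so every classifiable trajectory lands in exactly one class.
    Follow-up shorter than 21 grid days yields a low-confidence flag.
    """
    series = record.anc_series
    if series is None or len(series) == 0:
        raise CohortValidationError(f"{record.patient_id}: no ANC series")
    grid = daily_grid(series, (0, horizon))
    # follow-up is judged by actual draws, not carried-forward days
    measured = [d for d in series.days if 0 <= d <= horizon]
    low_conf = (max(measured, default=-1) < 21)

    severe = _threshold_days(grid, 0.5)
    if _max_run(severe) >= 14:
        return PhenotypeResult("aplastic", low_conf)

    days = grid.days
    recovered = _threshold_days(grid, np.inf) & (grid.values > 1.5)
    dip = _threshold_days(grid, 1.0) & (days >= 22)  # "after day 21"
    if recovered.any():
        first_rec = days[recovered].min()
        if (dip & (days > first_rec)).any():
            return PhenotypeResult("intermittent", low_conf)
    return PhenotypeResult("quick", low_conf)


@dataclass(frozen=True)
class NeutropeniaMetrics:
    severe_days_d0_60: int
    phenotype: str
    phenotype_low_confidence: bool
    severe_d0_30: bool
    severe_d31_100: bool
    protracted_severe: bool      # ANC < 0.5 for >= 7 consecutive days
    profound_d0_100: bool        # any ANC < 0.1
    protracted_profound: bool    # ANC < 0.1 for >= 7 consecutive days
    prolonged: bool              # any ANC < 1.0 on a day >= 21


def neutropenia_metrics(record: PatientRecord, horizon: int = 100,
                        mode: str = "locf") -> NeutropeniaMetrics:
    grid = daily_grid(record.anc_series, (0, horizon))
    severe = _threshold_days(grid, 0.5)
    profound = _threshold_days(grid, 0.1)
    sub10 = _threshold_days(grid, 1.0)
    days = grid.days
    pheno = classify_phenotype(record, horizon)
    return NeutropeniaMetrics(
        severe_days_d0_60=severe_neutropenia_days(record, (0, 60), mode),
        phenotype=pheno.label,
        phenotype_low_confidence=pheno.low_confidence,
        severe_d0_30=bool(severe[(days >= 0) & (days <= 30)].any()),
        severe_d31_100=bool(severe[(days >= 31) & (days <= 100)].any()),
        protracted_severe=_max_run(severe) >= 7,
        profound_d0_100=bool(profound.any()),
        protracted_profound=_max_run(profound) >= 7,
        prolonged=bool(sub10[days >= 21].any()),
    )


@dataclass(frozen=True)
class CytopeniaFlags:
    """None means not evaluable (no data in the window), distinct from False."""

    severe_thrombocytopenia_d0_30: bool | None
    severe_thrombocytopenia_d31_100: bool | None
    severe_anemia_d0_30: bool | None
    severe_anemia_d31_100: bool | None


def _window_flag(series: LabSeries | None, window: tuple[int, int],
                 threshold: float) -> bool | None:
    if series is None or len(series.in_window(*window)) == 0:
        return None
    grid = daily_grid(series, window)
    return bool(_threshold_days(grid, threshold).any())


def cytopenia_flags(record: PatientRecord) -> CytopeniaFlags:
    """Severe thrombocytopenia (< 50 G/l) and severe anemia (Hb < 8 g/dl or
    pRBC transfusion) flags for days 0–30 and 31–100."""
    out = {}
    for name, window in (("d0_30", (0, 30)), ("d31_100", (31, 100))):
        out[f"severe_thrombocytopenia_{name}"] = _window_flag(
            record.platelet_series, window, 50.0)
        hb = _window_flag(record.hemoglobin_series, window, 8.0)
        prbc = any(window[0] <= d <= window[1] for d in record.prbc_transfusion_days)
        # a transfusion makes the window evaluable even without Hb draws
        out[f"severe_anemia_{name}"] = True if prbc else hb
    return CytopeniaFlags(**out)
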