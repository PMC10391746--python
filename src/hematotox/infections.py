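"""Infection endpoints: per-patient day 0–90 flags and cumulative incidence.

An infection event carries an onset day (day of the diagnostic test), a
category (bacterial / viral / fungal / clinical syndrome), a clinical
source, and a 5-grade severity; grade >= 3 is "severe".  A patient may
contribute several events, but each per-patient flag counts once; all
events remain in the descriptive tallies.

Cumulative incidence is one minus the Kaplan–Meier estimator of the time to
the first qualifying event, censoring at death or the horizon (death is
treated as censoring, not a competing event, to match a log-rank curve
comparison; a competing-risks variant is available via
:func:`hematotox.stats.aalen_johansen`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import INFECTION_CATEGORIES, PatientRecord
from .errors import StatisticalError
from .stats import SurvivalCurve, km_fit, logrank

DAYS_PER_MONTH = 30.4375  # months -> study days for censoring at death


@dataclass(frozen=True)
class InfectionSummary:
    per_patient: pd.DataFrame  # flags + first onset day per category
    event_tally: pd.DataFrame  # counts by category, source, grade (all events)
    n_events: int
    n_patients_with_event: int


def _first_onset(events, predicate, horizon: int):
    days = [e.onset_day for e in events if predicate(e) and 0 <= e.onset_day <= horizon]
    return min(days) if days else None


def summarize_infections(records, horizon: int = 90) -> InfectionSummary:
    """Per-patient infection flags over days [0, horizon] plus event tallies.

    Flags derive only from events with onset inside the window; events past
    the horizon stay in the raw tallies.
    """
    rows = []
    tally_rows = []
    n_events = 0
    n_pat = 0
    for r in records:
        events = list(r.infections)
        n_events += len(events)
        for e in events:
            tally_rows.append({"category": e.category, "source": e.source,
                               "grade": e.grade})
        row = {"patient_id": r.patient_id}
        row["any_d0_90"] = _first_onset(events, lambda e: True, horizon) is not None
        row["severe_d0_90"] = _first_onset(events, lambda e: e.grade >= 3,
                                           horizon) is not None
        row["first_any_day"] = _first_onset(events, lambda e: True, horizon)
        row["first_severe_day"] = _first_onset(events, lambda e: e.grade >= 3,
                                               horizon)
        for cat in INFECTION_CATEGORIES:
            first = _first_onset(events, lambda e, c=cat: e.category == c, horizon)
            row[cat] = first is not None
            row[f"first_{cat}_day"] = first
        rows.append(row)
        if row["any_d0_90"]:
            n_pat += 1
    per_patient = pd.DataFrame(rows)
    if len(tally_rows):
        tally = (pd.DataFrame(tally_rows)
                 .groupby(["category", "source", "grade"]).size()
                 .reset_index(name="n_events"))
    else:
        tally = pd.DataFrame(columns=["category", "source", "grade", "n_events"])
    return InfectionSummary(per_patient=per_patient, event_tally=tally,
                            n_events=n_events, n_patients_with_event=n_pat)


def _qualifies(event, category: str) -> bool:
    if category == "any":
        return True
    if category == "severe":
        return event.grade >= 3
    return event.category == category


def _death_day(record: PatientRecord) -> float:
    o = record.outcome
    if o is None or o.os_event == 0:
        return np.inf
    return o.os_time * DAYS_PER_MONTH


def infection_incidence(records, category: str = "any",
                        horizon: int = 90) -> SurvivalCurve:
    """Time-to-first-qualifying-infection incidence for one set of patients.

    Returns the KM curve of the *event-free* probability; the cumulative
    incidence at day d is ``1 - curve.at(d)``.
    """
    if category not in ("any", "severe") + INFECTION_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    times, events = [], []
    for r in records:
        onset = _first_onset(r.infections, lambda e: _qualifies(e, category),
                             horizon)
        censor = min(_death_day(r), horizon)
        if onset is not None and onset <= censor:
            times.append(onset)
            events.append(1)
        else:
            times.append(censor)
            events.append(0)
    return km_fit(times, events)


@dataclass(frozen=True)
class IncidenceComparison:
    curves: dict            # group label -> SurvivalCurve (event-free)
    chi2: float
    p_value: float
    category: str
    horizon: int

    def cumulative_incidence(self, group: str, day: float) -> float:
        return 1.0 - self.curves[group].at(day)


def cumulative_incidence_infection(records, groups: dict, category: str = "any",
                                   horizon: int = 90) -> IncidenceComparison:
    """Group-wise day 0–horizon infection incidence with a log-rank test.

    ``groups`` maps patient_id to a group label (e.g. HT risk class); every
    group must be non-empty.
    """
    by_group: dict[str, list[PatientRecord]] = {}
    for r in records:
        by_group.setdefault(groups[r.patient_id], []).append(r)
    if any(len(v) == 0 for v in by_group.values()) or len(by_group) < 2:
        raise StatisticalError("need >= 2 non-empty groups")
    curves = {g: infection_incidence(rs, category, horizon)
              for g, rs in sorted(by_group.items())}

    labels = sorted(by_group)
    if len(labels) == 2:
        def _td(rs):
            t, e = [], []
            for r in rs:
                onset = _first_onset(r.infections,
                                     lambda ev: _qualifies(ev, category), horizon)
                censor = min(_death_day(r), horizon)
                if onset is not None and onset <= censor:
                    t.append(onset); e.append(1)
                else:
                    t.append(censor); e.append(0)
            return t, e
        ta, ea = _td(by_group[labels[0]])
        tb, eb = _td(by_group[labels[1]])
        chi2, p = logrank(ta, ea, tb, eb)
    else:
        chi2, p = np.nan, np.nan
    return IncidenceComparison(curves=curves, chi2=chi2, p_value=p,
                               category=category, horizon=horizon)
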