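"""Survival and infection statistics comparing HT-high vs HT-low strata.

Runs the score on a simulated cohort, then compares the strata with the
study's statistical toolkit: Kaplan-Meier + log-rank for PFS, univariate
Cox for the hazard ratio, Aalen-Johansen for 1-year non-relapse mortality,
and the day 0-90 severe-infection cumulative incidence.
"""

import pandas as pd

from hematotox import (GeneratorConfig, cumulative_incidence_infection,
                       cox_fit, generate_cohort, km_fit, logrank, nrm_cuminc,
                       score_cohort)

cohort = generate_cohort(GeneratorConfig(n_patients=600), seed=11)
scores = score_cohort(cohort)
cls = dict(zip(scores.table.patient_id, scores.table.risk_class))

rows = []
for r in cohort:
    rows.append({"patient_id": r.patient_id, "ht_high": int(cls[r.patient_id] == "high"),
                 "pfs_time": r.outcome.pfs_time, "pfs_event": r.outcome.pfs_event})
df = pd.DataFrame(rows)

for label, flag in (("HT-low", 0), ("HT-high", 1)):
    sub = df[df.ht_high == flag]
    curve = km_fit(sub.pfs_time, sub.pfs_event)
    med = f"{curve.median:.1f} months" if curve.median_reached else "not reached"
    print(f"{label}: n={curve.n}, PFS events={curve.n_events}, median PFS {med}")

low, high = df[df.ht_high == 0], df[df.ht_high == 1]
chi2, p = logrank(low.pfs_time, low.pfs_event, high.pfs_time, high.pfs_event)
print(f"log-rank PFS: chi2={chi2:.1f}, p={p:.2g}")

hr = cox_fit(df, ["ht_high"], "pfs_time", "pfs_event")
lo, hi = hr.table.loc["ht_high", ["ci_lower", "ci_upper"]]
print(f"univariate Cox HR (high vs low): {hr.ratio('ht_high'):.2f} "
      f"[95% CI {lo:.2f}-{hi:.2f}]")

curves, (chi2_nrm, p_nrm) = nrm_cuminc(cohort.records,
                                       groups={r.patient_id: cls[r.patient_id]
                                               for r in cohort})
for g in ("low", "high"):
    print(f"1-year NRM, HT-{g}: {100 * curves[g].at('NRM', 12):.1f}%")
print(f"NRM cause-specific log-rank p={p_nrm:.2g}")

comp = cumulative_incidence_infection(
    cohort.records, {r.patient_id: cls[r.patient_id] for r in cohort},
    category="severe")
for g in ("low", "high"):
    print(f"90-day severe-infection incidence, HT-{g}: "
          f"{100 * comp.cumulative_incidence(g, 90):.1f}%")
print(f"severe-infection log-rank p={comp.p_value:.2g}")
print()
print("The high stratum shows shorter PFS, a hazard ratio well above 1, "
      "higher non-relapse mortality and a steeper infection curve - the "
      "orderings the score is designed to capture.")
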