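"""Classify a neutrophil-recovery trajectory and count severe-neutropenia days.

Sparse ANC draws are expanded onto a daily grid by carrying the last
observation forward; days with ANC < 0.5 G/l in days 0-60 are summed, and
the trajectory is labelled quick / intermittent / aplastic.
"""

from hematotox import LabSeries, PatientRecord, neutropenia_metrics

# biphasic course: early severe dip, recovery, then a second dip after day 21
draws = [(0, 2.1), (3, 0.4), (6, 0.3), (9, 0.6), (12, 1.7), (18, 1.9),
         (24, 0.8), (27, 0.9), (30, 1.6), (45, 1.8), (60, 2.0), (90, 2.2)]
record = PatientRecord(
    patient_id="example",
    anc_series=LabSeries(tuple(d for d, _ in draws),
                         tuple(v for _, v in draws)),
)

m = neutropenia_metrics(record)
print(f"severe-neutropenia days (d0-60): {m.severe_days_d0_60}")
print(f"recovery phenotype:             {m.phenotype}")
print(f"prolonged (ANC < 1.0 at d>=21): {m.prolonged}")
print("The second dip below 1.0 G/l after day 21, following recovery above "
      "1.5 G/l, is what makes this trajectory 'intermittent' rather than "
      "'quick'.")
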