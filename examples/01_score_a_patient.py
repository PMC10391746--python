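"""Score a single patient's pre-lymphodepletion labs.

The CAR-HEMATOTOX score awards 0-7 points across five labs drawn before
the start of lymphodepleting chemotherapy; a total of 2 or more marks the
patient as high risk for hematological toxicity.
"""

from hematotox import BaselineLabs, score_components

labs = BaselineLabs(
    anc=1.1, anc_day=-1,            # G/l; <= 1.2 scores 1 point
    hemoglobin=8.7, hemoglobin_day=-1,  # g/dl; <= 9.0 scores 1 point
    platelets=68, platelets_day=-1,     # G/l; <= 75 scores 2 points
    crp=1.2, crp_day=0,                 # mg/dl; below the 3.0 cut: 0 points
    ferritin=900, ferritin_day=0,       # ng/ml; 650-2000 band: 1 point
)

result = score_components(labs)
print(f"component points: ANC={result.points_anc} Hb={result.points_hb} "
      f"platelets={result.points_plt} CRP={result.points_crp} "
      f"ferritin={result.points_ferritin}")
print(f"total = {result.total}  ->  risk class: {result.risk_class}")
print("A total >= 2 places this patient in the high-risk stratum, which "
      "carries longer severe neutropenia and more severe infections.")
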