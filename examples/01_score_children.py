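"""Score three hypothetical children with all three risk scores.

Each score is a weighted sum of bedside findings; the breakdown shows which
parameters contributed points.  Note the RISC conditional rule: chest
indrawing only scores when SpO2 > 90%.
"""

from pneumorisk import ALL_SCORES, PatientRecord, score_record

children = [
    PatientRecord("hypoxemic-infant", age_months=6, died=False, sex="female",
                  spo2=87, chest_indrawing=True, wheeze=False,
                  refusal_to_feed=True, grunting=True, cough_history=True,
                  unconscious=False, illness_duration_days=4, waz=-3.4),
    PatientRecord("wheezy-toddler", age_months=18, died=False, sex="male",
                  spo2=96, chest_indrawing=False, wheeze=True,
                  refusal_to_feed=False, grunting=False, cough_history=True,
                  unconscious=False, illness_duration_days=2, waz=-0.5),
    PatientRecord("borderline", age_months=10, died=False, sex="male",
                  spo2=91, chest_indrawing=True, wheeze=False,
                  refusal_to_feed=False, grunting=False, cough_history=True,
                  unconscious=False, illness_duration_days=6, waz=-2.4),
]

for child in children:
    print(f"\n{child.patient_id} (age {child.age_months} mo, "
          f"SpO2 {child.spo2}%, WAZ {child.waz})")
    for name in ALL_SCORES:
        result = score_record(child, name)
        parts = ", ".join(f"{lbl} {pts:+d}" for lbl, pts in result.components
                          if pts != 0) or "no scoring findings"
        print(f"  {name:18s} total {result.total:+d}   [{parts}]")

print("\nHigher totals indicate higher in-hospital mortality risk; each "
      "score has its own range\n(RISC -2..6, RISC-Malawi -1..17, adapted "
      "PERCH -1..12) so totals are not comparable across scores.")
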