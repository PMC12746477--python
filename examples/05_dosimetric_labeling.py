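"""Label a fraction from its DVH metric tables using the clinical criteria.

The labeler scores the re-calculated ATP plan and the ATS plan against the
12 per-structure dose-volume criteria (each with a clinical tolerance that
relaxes the limit). A fraction is ground-truth ATP only when the ATP plan
is acceptable; otherwise replanning (ATS) is required.
"""

from mrgart import default_criteria, determine_strategy, evaluate_plan
from mrgart.labeler import DVHMetricTable

print("Clinical criteria (structure, metric, rule, tolerance):")
for c in default_criteria():
    print(f"  {c.structure:<8} {c.metric:<10} {c.comparator} {c.limit:g} {c.unit:<3} "
          f"tol {c.tolerance:+g} {c.unit}")

atp = DVHMetricTable()
ats = DVHMetricTable()
for table, dmax in ((atp, 41.2), (ats, 37.9)):  # ATP overdoses the rectum
    table.set("CTV4000", "V_40Gy", 96.5, "%")
    table.set("PTV", "V_36.25Gy", 96.0, "%")
    table.set("PTV", "V_34.4Gy", 98.8, "%")
    table.set("Rectum", "D_max", dmax, "Gy")
    table.set("Rectum", "V_38Gy", 0.05, "cc")
    table.set("Rectum", "V_36Gy", 0.6, "cc")
    table.set("Rectum", "V_29Gy", 16.0, "%")
    table.set("Bladder", "V_37Gy", 7.5, "cc")
    table.set("Bladder", "V_18.1Gy", 44.0, "%")
    table.set("Femur_R", "V_14.5Gy", 3.2, "%")
    table.set("Femur_L", "V_14.5Gy", 3.4, "%")
    table.set("Urethra", "D_50%", 40.1, "Gy")

for name, t in (("ATP", atp), ("ATS", ats)):
    ev = evaluate_plan(t)
    print(f"\n{name} plan acceptable: {ev.acceptable}")
    for key in ev.violations:
        print(f"  violates {key[0]} {key[1]}")

decision = determine_strategy(atp, ats)
print(f"\nground-truth strategy: {decision.label.name}")
print("The rectum D_max criterion has zero tolerance, so 41.2 Gy > 40 Gy forces ATS.")
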