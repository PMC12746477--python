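"""Small builders shared across test modules."""

from mrgart.labeler import DVHMetricTable


def passing_dvh_table() -> DVHMetricTable:
    """A DVH table strictly inside every clinical limit."""
    t = DVHMetricTable()
    t.set("CTV4000", "V_40Gy", 97.0, "%")
    t.set("PTV", "V_36.25Gy", 97.0, "%")
    t.set("PTV", "V_34.4Gy", 99.0, "%")
    t.set("Rectum", "D_max", 38.0, "Gy")
    t.set("Rectum", "V_38Gy", 0.05, "cc")
    t.set("Rectum", "V_36Gy", 0.5, "cc")
    t.set("Rectum", "V_29Gy", 15.0, "%")
    t.set("Bladder", "V_37Gy", 8.0, "cc")
    t.set("Bladder", "V_18.1Gy", 45.0, "%")
    t.set("Femur_R", "V_14.5Gy", 3.0, "%")
    t.set("Femur_L", "V_14.5Gy", 3.0, "%")
    t.set("Urethra", "D_50%", 39.0, "Gy")
    return t
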