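"""Published county-level counts from the CDS-AF trial, used as fixed inputs.

These are the printed per-arm counts from the trial's baseline and final
censuses (intervention arm first). They serve as calibration anchors for the
synthetic county and as arithmetic cross-checks: summing the arm counts must
reproduce the printed county totals.
"""

from __future__ import annotations

#: Per-arm counts at baseline and of new diagnoses during the study:
#: (intervention, control).
ARM_COUNTS = {
    "clinics": (22, 21),
    "population": (232_561, 211_786),
    "af_patients": (7_764, 6_370),
    "af_with_indication": (7_370, 6_009),
    "new_af_diagnoses": (955, 902),
    "new_af_with_indication": (873, 832),
    "final_analysis_af_patients": (8_292, 6_508),
}

#: Printed county totals the arm counts must sum to.
COUNTY_TOTALS = {
    "clinics": 43,
    "population": 444_347,
    "af_patients": 14_134,
    "af_with_indication": 13_379,
    "new_af_diagnoses": 1_857,
    "new_af_with_indication": 1_705,
    "final_analysis_af_patients": 14_800,
}

#: Cluster-size summaries per arm (mean, SD of clinic list size).
CLINIC_LIST_SIZE = {"cds": (10_570, 5_032), "control": (10_085, 3_658)}

#: Primary-endpoint numerators/denominators per arm at the two censuses.
ADHERENCE_COUNTS = {
    "baseline": {"cds": (5_186, 7_370), "control": (4_187, 6_009)},
    "followup": {"cds": (5_734, 7_861), "control": (4_346, 6_156)},
}


def arm_sum(key: str) -> int:
    """Sum of the two arm counts for a county quantity."""
    a, b = ARM_COUNTS[key]
    return a + b
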