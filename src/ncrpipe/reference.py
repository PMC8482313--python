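"""Published summary statistics of the original four-group Stroop cohort.

The pipeline was developed against a clinical fNIRS study of 13 healthy
controls, 20 migraineurs, 26 OCD patients, and 21 schizophrenia patients
performing a color-word Stroop task (neutral/congruent/incongruent).  The
raw recordings are not distributable; what is public are the group-level
summary tables.  They serve two roles here: (a) behavioral defaults for
the synthetic cohort generator, and (b) inputs to the worked examples that
recompute the derived biomarker summaries (mean CQ, mean NCR, GE
reductions) from the per-stimulus tables.

All values are (mean, SD) per stimulus type unless noted.  RT is in
milliseconds, ACC in percent, CQ in %/s, GE dimensionless, NCR in %/s.
"""

from __future__ import annotations

GROUPS = ("control", "migraine", "ocd", "schizo")

GROUP_SIZES = {"control": 13, "migraine": 20, "ocd": 26, "schizo": 21}

# Reaction times, ms
REFERENCE_RT = {
    "control": {"N": (975.7, 134.7), "C": (1041.8, 190.8), "I": (1170.6, 227.6)},
    "migraine": {"N": (1233.0, 394.6), "C": (1352.2, 345.9), "I": (1560.7, 576.8)},
    "ocd": {"N": (1593.1, 453.3), "C": (1631.5, 400.7), "I": (2019.7, 512.7)},
    "schizo": {"N": (1750.9, 458.1), "C": (1815.5, 323.4), "I": (2202.2, 346.4)},
}

# Accuracy rates, %
REFERENCE_ACC = {
    "control": {"N": (98.2, 2.2), "C": (97.2, 4.7), "I": (92.8, 7.4)},
    "migraine": {"N": (92.0, 18.2), "C": (95.2, 8.4), "I": (82.3, 24.9)},
    "ocd": {"N": (98.4, 2.5), "C": (96.8, 4.4), "I": (86.3, 17.5)},
    "schizo": {"N": (91.4, 13.9), "C": (90.4, 13.7), "I": (69.6, 21.4)},
}

# Cognitive quotient CQ = ACC/RT, %/s (per-subject ratios averaged per group)
REFERENCE_CQ = {
    "control": {"N": (102.42, 14.15), "C": (96.00, 16.87), "I": (82.44, 19.19)},
    "migraine": {"N": (82.80, 27.50), "C": (75.04, 19.68), "I": (61.41, 28.62)},
    "ocd": {"N": (66.85, 19.49), "C": (63.12, 16.49), "I": (47.18, 19.44)},
    "schizo": {"N": (56.99, 19.77), "C": (52.05, 14.62), "I": (33.53, 15.19)},
}

# Optimized global efficiency of the cognitive-mode network
REFERENCE_GE_CM = {
    "control": {"N": (0.2951, 0.0482), "C": (0.3478, 0.0543), "I": (0.3207, 0.0634)},
    "migraine": {"N": (0.2821, 0.0275), "C": (0.2342, 0.0321), "I": (0.2784, 0.0287)},
    "ocd": {"N": (0.2350, 0.0662), "C": (0.2768, 0.0549), "I": (0.2548, 0.0549)},
    "schizo": {"N": (0.1793, 0.0527), "C": (0.1587, 0.0701), "I": (0.1624, 0.0635)},
}

# Optimized global efficiency of the default-mode network
REFERENCE_GE_DM = {
    "control": {"N": (0.1554, 0.0482), "C": (0.1621, 0.0543), "I": (0.1710, 0.0634)},
    "migraine": {"N": (0.2246, 0.0275), "C": (0.2210, 0.0321), "I": (0.2255, 0.0287)},
    "ocd": {"N": (0.2901, 0.0891), "C": (0.2728, 0.0662), "I": (0.2766, 0.0549)},
    "schizo": {"N": (0.2153, 0.0527), "C": (0.2183, 0.0701), "I": (0.2292, 0.0635)},
}

# Neurocognitive ratio NCR = CQ x GE_CM/GE_DM, per stimulus
REFERENCE_NCR = {
    "control": {"N": (225.97, 125.93), "C": (226.84, 80.88), "I": (176.85, 80.35)},
    "migraine": {"N": (104.00, 40.53), "C": (81.09, 28.04), "I": (80.41, 45.20)},
    "ocd": {"N": (57.68, 23.92), "C": (68.54, 27.39), "I": (45.88, 22.78)},
    "schizo": {"N": (49.48, 25.05), "C": (39.68, 15.37), "I": (25.48, 14.43)},
}

# Across-stimulus NCR means as published (for cross-checking the worked example)
REFERENCE_NCR_BAR = {
    "control": (209.89, 65.67),
    "migraine": (88.50, 33.97),
    "ocd": (57.36, 20.28),
    "schizo": (38.22, 14.52),
}

# Headline controls-vs-patients ROC of the across-stimulus means, percent
REFERENCE_ROC = {
    "CQ_bar": {"sensitivity": 100.0, "specificity": 77.6, "accuracy": 81.2, "auc": 89.3},
    "GE_bar": {"sensitivity": 92.3, "specificity": 89.6, "accuracy": 90.0, "auc": 95.1},
    "NCR_bar": {"sensitivity": 100.0, "specificity": 95.5, "accuracy": 96.3, "auc": 99.3},
}

def ge_cm_percent_reduction(patient_group: str, control_group: str = "control") -> float:
    """Mean over stimuli of the per-stimulus percent reduction in GE_CM of a
    patient group relative to controls, from the published group means."""
    reductions = [
        100.0 * (1.0 - REFERENCE_GE_CM[patient_group][st][0] / REFERENCE_GE_CM[control_group][st][0])
        for st in ("N", "C", "I")
    ]
    return float(sum(reductions) / len(reductions))


# Group-specific component subsets and count thresholds from the original
# optimization (subsets are 1-based eigencomponent indices of 16)
REFERENCE_SEARCH = {
    "control": {"cm_subset": tuple(range(1, 10)), "theta_cm": 43, "theta_dm": 32, "p_cm": 0.033},
    "migraine": {"cm_subset": (2, 3, 6, 7, 9, 16), "theta_cm": 40, "theta_dm": 28, "p_cm": 0.0017},
    "ocd": {"cm_subset": tuple(range(1, 13)) + (14, 16), "theta_cm": 38, "theta_dm": 48, "p_cm": 0.02},
    "schizo": {
        "cm_subset": tuple(range(1, 6)) + tuple(range(6, 10)) + (10, 12, 13, 14, 15, 16),
        "theta_cm": 27,
        "theta_dm": 41,
        "p_cm": 0.048,
    },
}
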