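"""Worked-example reference values for a published two-drug UV assay.

Per-sample values printed in the validation study this workflow models:
the 25-run mixture design layout, per-sample validation-set recoveries for
the three calibration models, standard-addition spike rows, spiked-plasma
recoveries, and the statistical critical values the study quotes.  These
serve as frozen oracles for the summary-statistics operations.
"""

# 25-run design: (sample_id, comp1 ug/mL, comp2 ug/mL); odd ids = calibration
DESIGN_TABLE = [
    (1, 9, 9), (2, 9, 1), (3, 1, 1), (4, 1, 17), (5, 17, 5),
    (6, 5, 17), (7, 17, 9), (8, 9, 5), (9, 5, 5), (10, 5, 13),
    (11, 13, 17), (12, 17, 13), (13, 13, 9), (14, 9, 17), (15, 17, 17),
    (16, 17, 1), (17, 1, 13), (18, 13, 1), (19, 1, 9), (20, 9, 13),
    (21, 13, 13), (22, 13, 5), (23, 5, 1), (24, 1, 5), (25, 5, 9),
]

# Validation-set percentage recoveries (12 samples) per model and component.
VALIDATION_RECOVERY = {
    ("cls", "comp1"): [99.98, 101.94, 101.91, 101.55, 101.83, 101.61,
                       101.77, 100.17, 100.03, 101.70, 101.46, 101.66],
    ("cls", "comp2"): [99.05, 99.59, 99.59, 99.55, 99.50, 99.48,
                       99.58, 99.03, 99.04, 99.50, 99.54, 99.57],
    ("pcr", "comp1"): [99.76, 100.01, 100.10, 100.02, 100.09, 100.07,
                       100.05, 99.83, 99.74, 100.04, 99.98, 99.99],
    ("pcr", "comp2"): [99.15, 100.04, 100.06, 100.16, 100.01, 100.08,
                       100.09, 99.22, 99.19, 100.03, 100.19, 100.10],
    ("pls", "comp1"): [99.76, 100.01, 100.10, 100.02, 100.09, 100.07,
                       100.05, 99.83, 99.74, 100.04, 99.98, 99.99],
    ("pls", "comp2"): [99.99, 100.05, 100.04, 100.01, 99.96, 99.94,
                       100.03, 99.98, 99.99, 99.96, 100.01, 100.03],
}

# Standard-addition spike rows for the CLS workflow:
# (base_taken, base_found, pure_added, pure_found) ug/mL.
STD_ADDITION_CLS_COMP1 = [
    (2.0, 1.99, 3.0, 3.02),
    (5.0, 4.98, 5.0, 4.98),
    (7.0, 7.09, 7.0, 7.09),
]
STD_ADDITION_CLS_COMP2 = [
    (4.0, 4.01, 4.0, 4.03),
    (6.0, 5.95, 6.0, 5.95),
    (8.0, 8.05, 8.0, 8.05),
]

# Spiked-plasma recoveries (5 samples) for the CLS workflow, component 1;
# the published summary quotes mean 94.26 with a +/- value of 1.16, which is
# the plain sample SD (not an RSD).
PLASMA_RECOVERY_CLS_COMP1 = [95.28, 95.54, 92.88, 93.35, 94.26]

# Quoted statistical critical values at P = 0.05 (n1 = n2 = 5).
T_CRITICAL_DF8 = 2.306
F_CRITICAL_DF4_4 = 6.388

# Eco-scale scores quoted for the three workflows.
ECO_SCORES = {"cls": 79, "pcr": 81, "pls": 78}
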