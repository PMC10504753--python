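"""Published summary statistics of the survey cohort this package emulates.

The package models a cross-sectional survey of Chinese college students
screened for childhood sexual abuse (CSA) with the CTQ-SF, in which the
CSA-positive subsample (n = 3,479 of 96,218 screened) completed the GAD-7
and PHQ-9.  The raw item-level data are not publicly deposited, so these
printed summary tables serve two purposes: they calibrate the synthetic
cohort generator (item means, demographic composition), and they are the
inputs for the descriptive statistics that *are* exactly recomputable from
published counts (sex-by-category chi-squares, CSA prevalence and its
confidence interval).
"""

from __future__ import annotations

N_SCREENED = 96_218  # retained after attention/consistency exclusions
N_ENROLLED = 117_769  # before exclusions
N_CSA = 3_479  # CTQ-SF sexual-abuse subscale score >= 8
N_CSA_MALE = 1_699
N_CSA_FEMALE = 1_780

# Sex-by-category demographic counts within the CSA subsample
# (male column, female column), used for chi-square recomputation and as
# the default category probabilities of the synthetic covariate model.
DEMOGRAPHIC_COUNTS: dict[str, dict[str, list]] = {
    "residence": {
        "labels": ["city", "town_county"],
        "male": [850, 849],
        "female": [938, 842],
    },
    "ethnicity": {
        "labels": ["han", "other"],
        "male": [1548, 151],
        "female": [1571, 209],
    },
    "family_type": {
        "labels": ["nuclear", "three_generation", "other"],
        "male": [1124, 356, 219],
        "female": [1148, 295, 337],
    },
    "income_band": {
        "labels": ["<930", "930-2169", "2170-3565", ">3565"],
        "male": [498, 464, 262, 475],
        "female": [554, 583, 291, 352],
    },
    "only_child": {
        "labels": ["yes", "no"],
        "male": [965, 734],
        "female": [733, 1047],
    },
}

# GAD-7 / PHQ-9 item-level mean (SD) in the CSA subsample; targets for the
# synthetic generator's default latent thresholds.
GAD_ITEM_MEANS = [0.86, 0.79, 0.89, 0.81, 0.53, 0.76, 0.54]
GAD_ITEM_SDS = [0.73, 0.79, 0.82, 0.82, 0.70, 0.77, 0.71]
PHQ_ITEM_MEANS = [0.87, 0.83, 0.89, 1.01, 0.85, 0.77, 0.88, 0.53, 0.29]
PHQ_ITEM_SDS = [0.73, 0.69, 0.86, 0.80, 0.84, 0.79, 0.85, 0.72, 0.57]

# Reported nodewise predictability (share of variance explained by
# neighbors), for qualitative comparison only.
PREDICTABILITY = {
    "GAD1": 0.59, "GAD2": 0.66, "GAD3": 0.63, "GAD4": 0.60, "GAD5": 0.50,
    "GAD6": 0.57, "GAD7": 0.49,
    "PHQ1": 0.43, "PHQ2": 0.54, "PHQ3": 0.41, "PHQ4": 0.56, "PHQ5": 0.37,
    "PHQ6": 0.47, "PHQ7": 0.47, "PHQ8": 0.44, "PHQ9": 0.31,
}

SYMPTOM_LABELS = {
    "GAD1": "nervous", "GAD2": "control worry", "GAD3": "worry a lot",
    "GAD4": "relax", "GAD5": "restless", "GAD6": "irritable",
    "GAD7": "afraid",
    "PHQ1": "anhedonia", "PHQ2": "sad mood", "PHQ3": "sleep",
    "PHQ4": "energy", "PHQ5": "appetite", "PHQ6": "guilt",
    "PHQ7": "concentration", "PHQ8": "motor", "PHQ9": "suicide",
}
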