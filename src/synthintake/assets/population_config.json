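{
  "schema_version": 1,
  "description": "Synthetic regional population statistics for an adult (18-64) urban Canadian-style catchment. Structurally faithful to census-style tables (ethnicity, five age groups, sex, relationship status by age and sex, parental status by age and sex, disability prevalence by age and sex with ten type shares) but the numbers are illustrative placeholders, not any agency's published figures.",
  "reference_date": "2025-01-01",
  "ethnicity": {
    "labels": ["European", "East Asian", "South Asian", "Southeast Asian", "Indigenous", "Latin American", "Black", "West Asian / Middle Eastern", "Other / Multiple"],
    "probs": [0.45, 0.15, 0.12, 0.06, 0.05, 0.04, 0.04, 0.04, 0.05]
  },
  "age_groups": {
    "labels": ["18-24", "25-34", "35-44", "45-54", "55-64"],
    "probs": [0.14, 0.22, 0.20, 0.17, 0.27],
    "bounds": [[18, 24], [25, 34], [35, 44], [45, 54], [55, 64]]
  },
  "sex": {
    "labels": ["female", "male"],
    "probs": [0.504, 0.496]
  },
  "relationship_categories": ["Single", "Living-apart-together", "Married", "Common-law", "Divorced/Separated", "Widowed"],
  "relationship_by_age_sex": {
    "18-24|female": [0.70, 0.12, 0.04, 0.12, 0.02, 0.00],
    "18-24|male":   [0.76, 0.10, 0.03, 0.09, 0.02, 0.00],
    "25-34|female": [0.35, 0.10, 0.28, 0.22, 0.05, 0.00],
    "25-34|male":   [0.42, 0.10, 0.24, 0.19, 0.05, 0.00],
    "35-44|female": [0.18, 0.06, 0.48, 0.16, 0.11, 0.01],
    "35-44|male":   [0.22, 0.06, 0.46, 0.15, 0.10, 0.01],
    "45-54|female": [0.13, 0.05, 0.52, 0.12, 0.16, 0.02],
    "45-54|male":   [0.15, 0.05, 0.52, 0.12, 0.15, 0.01],
    "55-64|female": [0.10, 0.04, 0.52, 0.09, 0.19, 0.06],
    "55-64|male":   [0.12, 0.04, 0.55, 0.10, 0.17, 0.02]
  },
  "parental_by_age_sex": {
    "18-24|female": 0.06,
    "18-24|male":   0.03,
    "25-34|female": 0.34,
    "25-34|male":   0.25,
    "35-44|female": 0.68,
    "35-44|male":   0.60,
    "45-54|female": 0.78,
    "45-54|male":   0.74,
    "55-64|female": 0.82,
    "55-64|male":   0.79
  },
  "disability_any_by_age_sex": {
    "18-24|female": 0.24,
    "18-24|male":   0.17,
    "25-34|female": 0.26,
    "25-34|male":   0.19,
    "35-44|female": 0.26,
    "35-44|male":   0.20,
    "45-54|female": 0.29,
    "45-54|male":   0.24,
    "55-64|female": 0.35,
    "55-64|male":   0.30
  },
  "disability_type_shares": {
    "labels": ["Mental-health related", "Pain-related", "Seeing", "Learning", "Memory", "Mobility", "Flexibility", "Hearing", "Dexterity", "Developmental"],
    "probs": [0.16, 0.22, 0.06, 0.08, 0.07, 0.13, 0.12, 0.07, 0.05, 0.04]
  },
  "name_locale_weights": {
    "labels": ["en_CA", "zh", "hi_IN", "fil_PH", "fr_CA", "ko", "es", "fa_IR"],
    "probs": [0.55, 0.12, 0.10, 0.06, 0.05, 0.04, 0.04, 0.04]
  },
  "catalog": {
    "condition_to_meds": {
      "Major depressive disorder": ["sertraline 50 mg daily", "escitalopram 10 mg daily", "bupropion XL 150 mg daily", "venlafaxine XR 75 mg daily"],
      "Generalized anxiety disorder": ["escitalopram 10 mg daily", "buspirone 10 mg twice daily", "duloxetine 30 mg daily"],
      "Bipolar I disorder": ["lithium carbonate 600 mg daily", "quetiapine 300 mg nightly", "lamotrigine 100 mg daily"],
      "Post-traumatic stress disorder": ["paroxetine 20 mg daily", "prazosin 2 mg nightly", "sertraline 100 mg daily"],
      "Obsessive-compulsive disorder": ["fluoxetine 40 mg daily", "fluvoxamine 100 mg daily"],
      "Attention-deficit/hyperactivity disorder": ["methylphenidate ER 27 mg morning", "lisdexamfetamine 30 mg morning", "atomoxetine 40 mg daily"],
      "Panic disorder": ["sertraline 50 mg daily", "clonazepam 0.25 mg as needed"],
      "Social anxiety disorder": ["sertraline 50 mg daily", "propranolol 10 mg as needed"],
      "Borderline personality disorder": ["lamotrigine 100 mg daily", "quetiapine 50 mg nightly"],
      "Chronic insomnia disorder": ["trazodone 50 mg nightly", "zopiclone 5 mg nightly", "melatonin 3 mg nightly"]
    },
    "unconstrained_lists": {
      "allergies": ["no known allergies", "penicillin", "sulfa drugs", "peanuts", "shellfish", "latex", "seasonal pollen", "cat dander"],
      "supplements": ["none", "vitamin D", "multivitamin", "omega-3 fish oil", "magnesium", "iron", "vitamin B12", "probiotics"],
      "recreational_drugs": ["none", "alcohol socially", "cannabis occasionally", "cannabis daily", "tobacco daily", "nicotine vaping", "psilocybin rarely"],
      "visit_reasons": ["low mood for several months", "worsening anxiety and panic attacks", "trouble sleeping most nights", "difficulty concentrating at work", "grief after a recent loss", "stress at home affecting daily life", "medication review after side effects", "referral for a psychiatric intake assessment"]
    },
    "comorbidity": {
      "prob_any": 0.6,
      "count_weights": {"1": 0.6, "2": 0.3, "3": 0.1}
    }
  }
}
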