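"""Canonical checkbox codebook for ACVS-style referral forms.

The assessment form captures presenting symptoms and relevant history as
physician-completed checkboxes.  Each entry below pairs a feature name with
the Bernoulli rate at which the synthetic cohort generator checks the box
for true TIA/minor-stroke referrals versus mimic referrals.  The bundled
example classifier derives its coefficients from the same rates (log odds
ratios), so on synthetic streams it attains non-trivial discrimination by
construction.

All rates here are synthetic: they are plausibly ordered (vascular features
commoner in TIA, migrainous/syncopal features commoner in mimics) but are
not estimates from any clinical dataset.
"""

from __future__ import annotations

# name -> (rate given TIA/minor stroke, rate given mimic)
# 31 features have tia_rate > mimic_rate and hence a positive log odds
# ratio in the example classifier; the remaining 19 are mimic-leaning.
SYMPTOM_RATES: dict[str, tuple[float, float]] = {
    # focal deficits and vascular history: TIA-leaning (31 features)
    "unilateral_weakness": (0.45, 0.20),
    "speech_disturbance": (0.30, 0.18),
    "facial_droop": (0.25, 0.08),
    "dysarthria": (0.22, 0.10),
    "aphasia": (0.15, 0.05),
    "hemisensory_loss": (0.30, 0.15),
    "monocular_vision_loss": (0.08, 0.03),
    "hemianopia": (0.07, 0.03),
    "diplopia": (0.08, 0.05),
    "limb_ataxia": (0.10, 0.06),
    "gait_disturbance": (0.18, 0.12),
    "sudden_onset": (0.75, 0.45),
    "symptoms_resolved": (0.60, 0.40),
    "weakness_arm": (0.30, 0.12),
    "weakness_leg": (0.22, 0.10),
    "weakness_face": (0.20, 0.08),
    "numbness_arm": (0.25, 0.15),
    "numbness_leg": (0.15, 0.09),
    "clumsiness_hand": (0.12, 0.06),
    "hypertension_history": (0.65, 0.50),
    "atrial_fibrillation": (0.16, 0.08),
    "hyperlipidaemia_history": (0.48, 0.36),
    "smoking_history": (0.14, 0.09),
    "prior_stroke": (0.12, 0.06),
    "prior_tia": (0.15, 0.08),
    "carotid_stenosis": (0.06, 0.02),
    "ischemic_heart_disease": (0.18, 0.10),
    "peripheral_vascular_disease": (0.05, 0.02),
    "antiplatelet_use": (0.35, 0.25),
    "anticoagulant_use": (0.10, 0.06),
    "male_sex": (0.55, 0.44),
    # migrainous / syncopal / non-vascular: mimic-leaning (19 features)
    "headache": (0.15, 0.40),
    "migraine_history": (0.08, 0.30),
    "seizure_history": (0.02, 0.10),
    "syncope": (0.03, 0.15),
    "presyncope": (0.05, 0.18),
    "confusion": (0.08, 0.20),
    "memory_loss": (0.05, 0.15),
    "gradual_onset": (0.10, 0.30),
    "positive_visual_phenomena": (0.04, 0.20),
    "photophobia": (0.03, 0.15),
    "nausea": (0.08, 0.22),
    "vomiting": (0.04, 0.10),
    "isolated_vertigo": (0.06, 0.20),
    "tinnitus": (0.03, 0.10),
    "chest_pain": (0.03, 0.08),
    "anxiety_history": (0.08, 0.20),
    "migrating_paresthesia": (0.04, 0.15),
    "loss_of_consciousness": (0.02, 0.10),
    "generalized_weakness": (0.06, 0.18),
}

# 12 pairwise interaction terms for the example classifier, 8 of them with
# positive coefficients (co-occurring focal/vascular features reinforce a
# TIA call; clustered migrainous features reinforce a mimic call).
INTERACTION_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("unilateral_weakness", "speech_disturbance"): 0.30,
    ("weakness_arm", "weakness_face"): 0.25,
    ("hemisensory_loss", "weakness_arm"): 0.20,
    ("atrial_fibrillation", "prior_stroke"): 0.25,
    ("hypertension_history", "smoking_history"): 0.15,
    ("prior_tia", "carotid_stenosis"): 0.30,
    ("sudden_onset", "symptoms_resolved"): 0.20,
    ("dysarthria", "facial_droop"): 0.20,
    ("headache", "positive_visual_phenomena"): -0.35,
    ("headache", "photophobia"): -0.30,
    ("isolated_vertigo", "nausea"): -0.25,
    ("syncope", "loss_of_consciousness"): -0.30,
}

# Checkboxes whose realised values the generator ties to the ABCD2 clinical
# component instead of drawing independently from SYMPTOM_RATES.
SCORE_LINKED_SYMPTOMS = ("unilateral_weakness", "speech_disturbance")
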