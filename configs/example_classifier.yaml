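description: Synthetic example TIA/mimic classifier for simulation and testing only;
  not fitted to clinical data.
intercept: -1.692569697965167
main_effects:
  unilateral_weakness: 1.1856236656577395
  speech_disturbance: 0.6690496289808848
  facial_droop: 1.3437347467010947
  dysarthria: 0.9315582040049435
  aphasia: 1.2098379237783339
  hemisensory_loss: 0.8873031950009029
  monocular_vision_loss: 1.0337516544660688
  hemianopia: 0.8894093457373305
  diplopia: 0.502091943797236
  limb_ataxia: 0.5543107357057295
  gait_disturbance: 0.4760826753221177
  sudden_onset: 1.2992829841302609
  symptoms_resolved: 0.8109302162163285
  weakness_arm: 1.1451323043030026
  weakness_leg: 0.9315582040049435
  weakness_face: 1.056052674249314
  numbness_arm: 0.6359887667199968
  numbness_leg: 0.5790338737925244
  clumsiness_hand: 0.7591051483517427
  hypertension_history: 0.6190392084062236
  atrial_fibrillation: 0.7841189587656721
  hyperlipidaemia_history: 0.49532143723002525
  smoking_history: 0.49834496254238175
  prior_stroke: 0.7591051483517427
  prior_tia: 0.7077459799810979
  carotid_stenosis: 1.1402849850686776
  ischemic_heart_disease: 0.6808770879681307
  peripheral_vascular_disease: 0.9473813189441862
  antiplatelet_use: 0.479573080261886
  anticoagulant_use: 0.5543107357057295
  male_sex: 0.4418327522790395
  headache: -1.3291359472799422
  migraine_history: -1.595049174982001
  seizure_history: -1.6945957207744071
  syncope: -1.7414976344471669
  presyncope: -1.4280914897983517
  confusion: -1.056052674249314
  memory_loss: -1.2098379237783339
  gradual_onset: -1.3499267169490161
  positive_visual_phenomena: -1.791759469228055
  photophobia: -1.7414976344471669
  nausea: -1.1766806620379284
  vomiting: -0.9808292530117261
  isolated_vertigo: -1.3652409519220583
  tinnitus: -1.2788741124990537
  chest_pain: -1.0337516544660688
  anxiety_history: -1.056052674249314
  migrating_paresthesia: -1.4434527749598391
  loss_of_consciousness: -1.6945957207744071
  generalized_weakness: -1.2351878236738603
interactions:
- features:
  - unilateral_weakness
  - speech_disturbance
  coefficient: 0.3
- features:
  - weakness_arm
  - weakness_face
  coefficient: 0.25
- features:
  - hemisensory_loss
  - weakness_arm
  coefficient: 0.2
- features:
  - atrial_fibrillation
  - prior_stroke
  coefficient: 0.25
- features:
  - hypertension_history
  - smoking_history
  coefficient: 0.15
- features:
  - prior_tia
  - carotid_stenosis
  coefficient: 0.3
- features:
  - sudden_onset
  - symptoms_resolved
  coefficient: 0.2
- features:
  - dysarthria
  - facial_droop
  coefficient: 0.2
- features:
  - headache
  - positive_visual_phenomena
  coefficient: -0.35
- features:
  - headache
  - photophobia
  coefficient: -0.3
- features:
  - isolated_vertigo
  - nausea
  coefficient: -0.25
- features:
  - syncope
  - loss_of_consciousness
  coefficient: -0.3
codebook:
  unilateral_weakness: binary
  speech_disturbance: binary
  facial_droop: binary
  dysarthria: binary
  aphasia: binary
  hemisensory_loss: binary
  monocular_vision_loss: binary
  hemianopia: binary
  diplopia: binary
  limb_ataxia: binary
  gait_disturbance: binary
  sudden_onset: binary
  symptoms_resolved: binary
  weakness_arm: binary
  weakness_leg: binary
  weakness_face: binary
  numbness_arm: binary
  numbness_leg: binary
  clumsiness_hand: binary
  hypertension_history: binary
  atrial_fibrillation: binary
  hyperlipidaemia_history: binary
  smoking_history: binary
  prior_stroke: binary
  prior_tia: binary
  carotid_stenosis: binary
  ischemic_heart_disease: binary
  peripheral_vascular_disease: binary
  antiplatelet_use: binary
  anticoagulant_use: binary
  male_sex: binary
  headache: binary
  migraine_history: binary
  seizure_history: binary
  syncope: binary
  presyncope: binary
  confusion: binary
  memory_loss: binary
  gradual_onset: binary
  positive_visual_phenomena: binary
  photophobia: binary
  nausea: binary
  vomiting: binary
  isolated_vertigo: binary
  tinnitus: binary
  chest_pain: binary
  anxiety_history: binary
  migrating_paresthesia: binary
  loss_of_consciousness: binary
  generalized_weakness: binary
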