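# Observed pharmacokinetic study summaries used as workflow inputs.
# Each entry records the administered IV regimen and the observed plasma
# AUC to the last sampling time (ng/mL.h, 24 h window) for one study arm.
# Observed systemic clearance is derived as CL_obs = dose / AUC_obs.
# Monkey arms were 10-minute IV infusions; mouse and rat arms IV boluses;
# the human arm was a 6-hour IV infusion given daily for 7 days.
# "reference: true" marks, per compound, the monkey arm used for clearance
# derivation when a species has more than one dose level (the higher dose).

studies:
  - {compound: MTM,       species: mouse,  dose: 2.0,   dose_unit: mg/kg, route: bolus,    infusion_h: 0.0,    auc_obs: 1906,  reference: true}
  - {compound: MTM,       species: rat,    dose: 0.5,   dose_unit: mg/kg, route: bolus,    infusion_h: 0.0,    auc_obs: 173,   reference: true}
  - {compound: MTM,       species: monkey, dose: 6.94,  dose_unit: ug/kg, route: infusion, infusion_h: 0.1667, auc_obs: 90,    reference: false}
  - {compound: MTM,       species: monkey, dose: 13.18, dose_unit: ug/kg, route: infusion, infusion_h: 0.1667, auc_obs: 255,   reference: true}
  - {compound: MTM,       species: human,  dose: 13.0,  dose_unit: ug/kg, route: infusion, infusion_h: 6.0,    auc_obs: 136,   reference: true,
     n_doses: 7, interval_h: 24.0}
  - {compound: MTMSA-Trp, species: mouse,  dose: 2.0,   dose_unit: mg/kg, route: bolus,    infusion_h: 0.0,    auc_obs: 38563, reference: true}
  - {compound: MTMSA-Trp, species: rat,    dose: 0.5,   dose_unit: mg/kg, route: bolus,    infusion_h: 0.0,    auc_obs: 3486,  reference: true}
  - {compound: MTMSA-Trp, species: monkey, dose: 1.34,  dose_unit: ug/kg, route: infusion, infusion_h: 0.1667, auc_obs: 139,   reference: false}
  - {compound: MTMSA-Trp, species: monkey, dose: 4.19,  dose_unit: ug/kg, route: infusion, infusion_h: 0.1667, auc_obs: 181,   reference: true}
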