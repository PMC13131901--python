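# Mithramycin (MTM) — drug-specific model inputs.
# fup entries are fractions (not percent); BPR is the blood:plasma
# concentration ratio; spec_pstc is the specific permeability-surface-area
# product per mL of tissue cell volume, optimized against mouse IV plasma PK.
# The monkey BPR is assumed equal to the human in-silico value.

name: MTM
mw_g_per_mol: 1085.2
logp: 1.281
solubility_mg_per_ml: 0.965
solubility_ph: 5.359
pka: [10.79, 4.89]
fup:
  mouse: 0.0255
  rat: 0.1665
  monkey: 0.1186
  human: 0.1826
bpr:
  mouse: 0.626
  rat: 0.895
  monkey: 0.671
  human: 0.671
spec_pstc_ml_per_s_per_ml: 2.95e-2
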