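# MTMSA-Trp — tryptophan-conjugated mithramycin analog; drug-specific model
# inputs. Mouse and human fup were below the bioanalytical quantification
# limit (<1%) and are entered as 0.001 (0.1%). The monkey BPR of 0.02 was
# adjusted to describe observed monkey plasma PK (predominant partitioning
# into the plasma fraction of blood).

name: MTMSA-Trp
mw_g_per_mol: 1227.3
logp: 2.605
solubility_mg_per_ml: 0.416
solubility_ph: 5.721
pka: [13.45, 10.81, 6.79]
fup:
  mouse: 0.001
  rat: 0.0338
  monkey: 0.0106
  human: 0.001
bpr:
  mouse: 0.599
  rat: 0.936
  monkey: 0.02
  human: 0.661
spec_pstc_ml_per_s_per_ml: 1.23e-4
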