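# Tissue composition constants for tissue:plasma partition-coefficient (Kp)
# prediction by the Poulin & Theil tissue-composition method.
#
# Per-tissue volume fractions of neutral lipid (f_nl), phospholipid (f_ph)
# and water (f_w), taken from the published human composition compilations of
# Poulin & Theil (J Pharm Sci 2002) and applied to all species (species
# differences in tissue composition are small relative to the other
# uncertainties in this model and are not resolved here).
#
# ra is the tissue-to-plasma extracellular (interstitial) protein
# concentration ratio used to derive the tissue unbound fraction fut from the
# plasma unbound fraction fup:
#     fut = 1 / (1 + ((1 - fup)/fup) * ra)
# Interstitial albumin concentrations are commonly reported at roughly half
# the plasma concentration across well-perfused tissues; a uniform documented
# default of 0.5 is used and can be overridden per tissue.
#
# Adipose is handled by the method's adipose variant: drug binding to adipose
# interstitial protein is taken as negligible (fut = 1), so its ra is unused.

plasma:
  f_nl: 0.0035
  f_ph: 0.00225
  f_w: 0.945

tissues:
  lung:    {f_nl: 0.0030, f_ph: 0.0090,  f_w: 0.811, ra: 0.5}
  liver:   {f_nl: 0.0348, f_ph: 0.0252,  f_w: 0.751, ra: 0.5}
  kidney:  {f_nl: 0.0207, f_ph: 0.0162,  f_w: 0.783, ra: 0.5}
  gut:     {f_nl: 0.0487, f_ph: 0.0163,  f_w: 0.718, ra: 0.5}
  spleen:  {f_nl: 0.0201, f_ph: 0.0198,  f_w: 0.788, ra: 0.5}
  heart:   {f_nl: 0.0115, f_ph: 0.0166,  f_w: 0.758, ra: 0.5}
  brain:   {f_nl: 0.0510, f_ph: 0.0565,  f_w: 0.770, ra: 0.5}
  muscle:  {f_nl: 0.0238, f_ph: 0.0072,  f_w: 0.760, ra: 0.5}
  adipose: {f_nl: 0.7900, f_ph: 0.0020,  f_w: 0.180, ra: 0.5}
  skin:    {f_nl: 0.0284, f_ph: 0.0111,  f_w: 0.718, ra: 0.5}
  bone:    {f_nl: 0.0740, f_ph: 0.0011,  f_w: 0.439, ra: 0.5}
  rest:    {f_nl: 0.0238, f_ph: 0.0072,  f_w: 0.760, ra: 0.5}  # muscle-like lumped remainder
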