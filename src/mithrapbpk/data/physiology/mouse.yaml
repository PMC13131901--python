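# Mouse whole-body physiology (reference adult mouse, 0.025 kg).
# Organ weights and regional blood flows: Brown et al. 1997 (Toxicol Ind
# Health 13:407) fractional compilations; cardiac output 14 mL/min (Brown et
# al. 1997); GFR 0.28 mL/min (Davies & Morris 1993, Pharm Res 10:1093).
# Volumes are fractions of body weight (tissue density taken as 1 g/mL);
# flows are fractions of cardiac output. The lung receives the entire
# cardiac output in series; non-lung flow fractions sum to 1. Liver flow is
# the hepatic-artery fraction only — portal inflow arrives via gut + spleen.
# "rest" lumps the remaining perfused carcass. Extracellular fractions
# (vascular + interstitial space) follow the tissue-water compilations of
# Rodgers & Rowland 2006.

species: mouse
body_weight_kg: 0.025
cardiac_output_mL_per_h: 840.0
gfr_mL_per_h: 16.8
blood_volume_frac_bw: 0.049

tissues:
  lung:    {volume_frac_bw: 0.007, flow_frac_co: 1.000, extracellular_fraction: 0.336}
  liver:   {volume_frac_bw: 0.055, flow_frac_co: 0.020, extracellular_fraction: 0.163}
  kidney:  {volume_frac_bw: 0.017, flow_frac_co: 0.091, extracellular_fraction: 0.273}
  gut:     {volume_frac_bw: 0.042, flow_frac_co: 0.141, extracellular_fraction: 0.282}
  spleen:  {volume_frac_bw: 0.005, flow_frac_co: 0.010, extracellular_fraction: 0.207}
  heart:   {volume_frac_bw: 0.005, flow_frac_co: 0.066, extracellular_fraction: 0.313}
  brain:   {volume_frac_bw: 0.017, flow_frac_co: 0.033, extracellular_fraction: 0.162}
  muscle:  {volume_frac_bw: 0.384, flow_frac_co: 0.159, extracellular_fraction: 0.118}
  adipose: {volume_frac_bw: 0.070, flow_frac_co: 0.050, extracellular_fraction: 0.135}
  skin:    {volume_frac_bw: 0.165, flow_frac_co: 0.058, extracellular_fraction: 0.302}
  bone:    {volume_frac_bw: 0.107, flow_frac_co: 0.050, extracellular_fraction: 0.100}
  rest:    {volume_frac_bw: 0.030, flow_frac_co: 0.322, extracellular_fraction: 0.200}
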