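# Cynomolgus monkey whole-body physiology (reference 5 kg animal).
# Organ weights: non-human-primate compilations (Brown et al. 1997 and ICRP
# reference primate data); cardiac output 1086 mL/min and GFR 10.4 mL/min
# from Davies & Morris 1993 (5 kg monkey). See mouse.yaml for schema
# conventions.

species: monkey
body_weight_kg: 5.0
cardiac_output_mL_per_h: 65160.0
gfr_mL_per_h: 624.0
blood_volume_frac_bw: 0.065

tissues:
  lung:    {volume_frac_bw: 0.0068, flow_frac_co: 1.000, extracellular_fraction: 0.336}
  liver:   {volume_frac_bw: 0.027,  flow_frac_co: 0.039, extracellular_fraction: 0.163}
  kidney:  {volume_frac_bw: 0.0044, flow_frac_co: 0.138, extracellular_fraction: 0.273}
  gut:     {volume_frac_bw: 0.023,  flow_frac_co: 0.140, extracellular_fraction: 0.282}
  spleen:  {volume_frac_bw: 0.0017, flow_frac_co: 0.015, extracellular_fraction: 0.207}
  heart:   {volume_frac_bw: 0.0041, flow_frac_co: 0.055, extracellular_fraction: 0.313}
  brain:   {volume_frac_bw: 0.018,  flow_frac_co: 0.070, extracellular_fraction: 0.162}
  muscle:  {volume_frac_bw: 0.400,  flow_frac_co: 0.140, extracellular_fraction: 0.118}
  adipose: {volume_frac_bw: 0.080,  flow_frac_co: 0.040, extracellular_fraction: 0.135}
  skin:    {volume_frac_bw: 0.075,  flow_frac_co: 0.060, extracellular_fraction: 0.302}
  bone:    {volume_frac_bw: 0.070,  flow_frac_co: 0.050, extracellular_fraction: 0.100}
  rest:    {volume_frac_bw: 0.060,  flow_frac_co: 0.253, extracellular_fraction: 0.200}
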