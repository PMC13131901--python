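# Rat whole-body physiology (reference adult rat, 0.25 kg).
# Organ weights and regional blood flows: Brown et al. 1997 fractional
# compilations; cardiac output 74 mL/min and GFR 1.31 mL/min from
# Davies & Morris 1993. See mouse.yaml for schema conventions.

species: rat
body_weight_kg: 0.25
cardiac_output_mL_per_h: 4440.0
gfr_mL_per_h: 78.6
blood_volume_frac_bw: 0.064

tissues:
  lung:    {volume_frac_bw: 0.005,  flow_frac_co: 1.000, extracellular_fraction: 0.336}
  liver:   {volume_frac_bw: 0.034,  flow_frac_co: 0.021, extracellular_fraction: 0.163}
  kidney:  {volume_frac_bw: 0.0073, flow_frac_co: 0.141, extracellular_fraction: 0.273}
  gut:     {volume_frac_bw: 0.027,  flow_frac_co: 0.153, extracellular_fraction: 0.282}
  spleen:  {volume_frac_bw: 0.002,  flow_frac_co: 0.010, extracellular_fraction: 0.207}
  heart:   {volume_frac_bw: 0.0033, flow_frac_co: 0.049, extracellular_fraction: 0.313}
  brain:   {volume_frac_bw: 0.0057, flow_frac_co: 0.020, extracellular_fraction: 0.162}
  muscle:  {volume_frac_bw: 0.404,  flow_frac_co: 0.278, extracellular_fraction: 0.118}
  adipose: {volume_frac_bw: 0.070,  flow_frac_co: 0.070, extracellular_fraction: 0.135}
  skin:    {volume_frac_bw: 0.190,  flow_frac_co: 0.058, extracellular_fraction: 0.302}
  bone:    {volume_frac_bw: 0.073,  flow_frac_co: 0.122, extracellular_fraction: 0.100}
  rest:    {volume_frac_bw: 0.040,  flow_frac_co: 0.078, extracellular_fraction: 0.200}
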