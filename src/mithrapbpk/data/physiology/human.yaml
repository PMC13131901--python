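# Human whole-body physiology for a 13-year-old, 50 kg male — the reference
# individual for the first-in-human projections (pediatric/adolescent Ewing
# sarcoma setting).
# Organ-weight fractions: ICRP Publication 89 reference 13-year-old male,
# with adult fractional values where adolescent-specific values are not
# tabulated. Cardiac output 5.0 L/min (allometric CO ~ 0.275*BW^0.75 L/min
# at 50 kg); absolute GFR 100 mL/min, a documented constant for a 50 kg
# adolescent (normal-for-age eGFR ~ 100-120 mL/min/1.73 m^2), overridable
# from the run config. See mouse.yaml for schema conventions.

species: human
body_weight_kg: 50.0
cardiac_output_mL_per_h: 300000.0
gfr_mL_per_h: 6000.0
blood_volume_frac_bw: 0.074

tissues:
  lung:    {volume_frac_bw: 0.008,  flow_frac_co: 1.000, extracellular_fraction: 0.336}
  liver:   {volume_frac_bw: 0.026,  flow_frac_co: 0.065, extracellular_fraction: 0.163}
  kidney:  {volume_frac_bw: 0.0044, flow_frac_co: 0.190, extracellular_fraction: 0.273}
  gut:     {volume_frac_bw: 0.017,  flow_frac_co: 0.160, extracellular_fraction: 0.282}
  spleen:  {volume_frac_bw: 0.0026, flow_frac_co: 0.025, extracellular_fraction: 0.207}
  heart:   {volume_frac_bw: 0.0047, flow_frac_co: 0.040, extracellular_fraction: 0.313}
  brain:   {volume_frac_bw: 0.020,  flow_frac_co: 0.120, extracellular_fraction: 0.162}
  muscle:  {volume_frac_bw: 0.400,  flow_frac_co: 0.170, extracellular_fraction: 0.118}
  adipose: {volume_frac_bw: 0.150,  flow_frac_co: 0.050, extracellular_fraction: 0.135}
  skin:    {volume_frac_bw: 0.037,  flow_frac_co: 0.058, extracellular_fraction: 0.302}
  bone:    {volume_frac_bw: 0.070,  flow_frac_co: 0.042, extracellular_fraction: 0.100}
  rest:    {volume_frac_bw: 0.080,  flow_frac_co: 0.080, extracellular_fraction: 0.200}
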