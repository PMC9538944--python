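# Species / scenario physiology parameter sets.
# body_mass in kg wet weight, temperature in degrees C, fractions unitless,
# hepatocellularity in 1e6 cells per g liver, do_saturation as a fraction of
# dissolved-oxygen saturation.
trout_reference:
  species: trout
  body_mass: 0.010
  temperature: 15.0
  lipid_fraction: 0.05
  liver_fraction: 0.015
  hepatocellularity: 510.0
  hepatic_flow_fraction: 0.259
  do_saturation: 1.0

trout_study:
  species: trout
  body_mass: 0.0185
  temperature: 12.0
  lipid_fraction: 0.0908
  liver_fraction: 0.015
  hepatocellularity: 510.0
  hepatic_flow_fraction: 0.259
  do_saturation: 0.91

carp_study:
  species: carp
  body_mass: 0.0446
  temperature: 21.0
  lipid_fraction: 0.0957
  liver_fraction: 0.0174
  hepatocellularity: 510.0
  hepatic_flow_fraction: 0.259
  do_saturation: 0.77
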