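# Reference organ masses for an adult male mouse, used for allometric
# scaling: mass(organ) = reference_mass × (body_mass / reference_body_mass)^exponent.
# Tumor mass is taken from the study rows (or caliper volume × 1.0 g/cm³),
# never from this table.
reference_body_mass_g: 25.0
default_allometric_exponent: 1.0
organs:
  liver:   {reference_mass_g: 1.30}
  spleen:  {reference_mass_g: 0.10}
  kidneys: {reference_mass_g: 0.40}
  lungs:   {reference_mass_g: 0.15}
  heart:   {reference_mass_g: 0.14}
  blood:   {reference_mass_g: 1.80}
  bone:    {reference_mass_g: 2.60}
  muscle:  {reference_mass_g: 9.80}
  skin:    {reference_mass_g: 3.00}
  brain:   {reference_mass_g: 0.42}
  stomach: {reference_mass_g: 0.45}
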