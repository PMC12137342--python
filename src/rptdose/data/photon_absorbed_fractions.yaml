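# SYNTHETIC approximate photon absorbed fractions for unit-density spheres,
# generated from a mean-chord attenuation model
#   phi ≈ 1 − exp(−µ_en · 4r/3),  µ_en ≈ 0.03 cm⁻¹ (water, few-hundred-keV photons)
# with r the sphere radius for the given mass. Intended as an order-of-magnitude
# option (photon_model="table"); the default dosimetry neglects photons entirely
# (photon_model="escape"). Interpolation is linear in log(mass).
masses_g:  [0.05,   0.1,    0.2,    0.5,    1.0,    2.0,    5.0,    10.0]
phi_photon: [0.0091, 0.0114, 0.0143, 0.0195, 0.0245, 0.0308, 0.0415, 0.0521]
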