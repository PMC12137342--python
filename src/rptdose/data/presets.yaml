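# SYNTHETIC kinetic presets for the four study arms (tumor model × nuclide).
# These are qualitative emulations of the described kinetics — tumor uptake
# peaking at the 24 h sample with retention through 72 h; early-peaking liver
# for Lu-177 versus late (120–192 h) liver accumulation for Ac-225;
# hepatobiliary-dominant normal-tissue uptake — NOT fits to any measured data.
# amplitude: fraction of injected activity per gram (biexponential prefactor)
# k_uptake, k_clear: 1/h. Biological clearance is slow (k_clear well below the
# physical decay constant) consistent with the agent's prolonged retention.
trampc1-lu177:
  radionuclide: Lu-177
  tumor_model: TRAMP-C1
  organs:
    tumor:   {amplitude: 0.070, k_uptake: 0.20, k_clear: 0.0010}
    liver:   {amplitude: 0.180, k_uptake: 0.30, k_clear: 0.0010}
    spleen:  {amplitude: 0.090, k_uptake: 0.25, k_clear: 0.0010}
    kidneys: {amplitude: 0.080, k_uptake: 0.30, k_clear: 0.0010}
    lungs:   {amplitude: 0.060, k_uptake: 0.35, k_clear: 0.0010}
    heart:   {amplitude: 0.030, k_uptake: 0.35, k_clear: 0.0010}
    blood:   {amplitude: 0.120, k_uptake: 2.00, k_clear: 0.0300}
    bone:    {amplitude: 0.030, k_uptake: 0.20, k_clear: 0.0010}
    muscle:  {amplitude: 0.015, k_uptake: 0.20, k_clear: 0.0010}

trampc1-ac225:
  radionuclide: Ac-225
  tumor_model: TRAMP-C1
  organs:
    tumor:   {amplitude: 0.070, k_uptake: 0.20, k_clear: 0.0003}
    liver:   {amplitude: 0.200, k_uptake: 0.012, k_clear: 0.0005}
    spleen:  {amplitude: 0.080, k_uptake: 0.15, k_clear: 0.0003}
    kidneys: {amplitude: 0.070, k_uptake: 0.25, k_clear: 0.0003}
    lungs:   {amplitude: 0.050, k_uptake: 0.30, k_clear: 0.0003}
    heart:   {amplitude: 0.025, k_uptake: 0.35, k_clear: 0.0003}
    blood:   {amplitude: 0.100, k_uptake: 2.00, k_clear: 0.0300}
    bone:    {amplitude: 0.025, k_uptake: 0.20, k_clear: 0.0003}
    muscle:  {amplitude: 0.012, k_uptake: 0.20, k_clear: 0.0003}

myccap-lu177:
  radionuclide: Lu-177
  tumor_model: Myc-CaP
  organs:
    tumor:   {amplitude: 0.045, k_uptake: 0.20, k_clear: 0.0010}
    liver:   {amplitude: 0.120, k_uptake: 0.30, k_clear: 0.0010}
    spleen:  {amplitude: 0.060, k_uptake: 0.25, k_clear: 0.0010}
    kidneys: {amplitude: 0.055, k_uptake: 0.30, k_clear: 0.0010}
    lungs:   {amplitude: 0.040, k_uptake: 0.35, k_clear: 0.0010}
    heart:   {amplitude: 0.020, k_uptake: 0.35, k_clear: 0.0010}
    blood:   {amplitude: 0.080, k_uptake: 2.00, k_clear: 0.0300}
    bone:    {amplitude: 0.020, k_uptake: 0.20, k_clear: 0.0010}
    muscle:  {amplitude: 0.010, k_uptake: 0.20, k_clear: 0.0010}

myccap-ac225:
  radionuclide: Ac-225
  tumor_model: Myc-CaP
  organs:
    tumor:   {amplitude: 0.045, k_uptake: 0.20, k_clear: 0.0003}
    liver:   {amplitude: 0.130, k_uptake: 0.012, k_clear: 0.0005}
    spleen:  {amplitude: 0.055, k_uptake: 0.15, k_clear: 0.0003}
    kidneys: {amplitude: 0.045, k_uptake: 0.25, k_clear: 0.0003}
    lungs:   {amplitude: 0.035, k_uptake: 0.30, k_clear: 0.0003}
    heart:   {amplitude: 0.016, k_uptake: 0.35, k_clear: 0.0003}
    blood:   {amplitude: 0.065, k_uptake: 2.00, k_clear: 0.0300}
    bone:    {amplitude: 0.016, k_uptake: 0.20, k_clear: 0.0003}
    muscle:  {amplitude: 0.008, k_uptake: 0.20, k_clear: 0.0003}
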