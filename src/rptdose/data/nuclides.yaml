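# Decay data for Lu-177 and the Ac-225 series.
#
# Schema (see rptdose.nuclide_chain.validate_nuclide_records):
#   data_version: string
#   nuclides:
#     - name: identifier
#       half_life_s: seconds (null for a stable nuclide)
#       branches: [{daughter: name or STABLE, fraction: float}]  (empty for stable)
#       energy_MeV: {alpha, electron, photon}  mean MeV emitted per decay;
#         "electron" pools beta-mean, conversion and Auger electrons,
#         "photon" pools gamma and X-rays.
#
# Values are rounded mean-energy-per-decay figures in the style of
# evaluated decay-data compilations (ICRP-107-like). This file, not code,
# is the source of truth; swap it to change data versions.
data_version: "2026.1"
nuclides:
  - name: Lu-177
    half_life_s: 574300.8        # 6.647 d
    branches:
      - {daughter: Hf-177, fraction: 1.0}
    energy_MeV: {alpha: 0.0, electron: 0.1473, photon: 0.0334}
  - name: Hf-177
    half_life_s: null            # stable
    branches: []
    energy_MeV: {alpha: 0.0, electron: 0.0, photon: 0.0}

  - name: Ac-225
    half_life_s: 857088.0        # 9.920 d
    branches:
      - {daughter: Fr-221, fraction: 1.0}
    energy_MeV: {alpha: 5.7900, electron: 0.0216, photon: 0.0154}
  - name: Fr-221
    half_life_s: 286.1           # 4.77 min
    branches:
      - {daughter: At-217, fraction: 1.0}
    energy_MeV: {alpha: 6.3030, electron: 0.0101, photon: 0.0312}
  - name: At-217
    half_life_s: 0.0323
    branches:
      - {daughter: Bi-213, fraction: 1.0}
    energy_MeV: {alpha: 7.0669, electron: 0.0001, photon: 0.0002}
  - name: Bi-213
    half_life_s: 2735.4          # 45.59 min
    branches:
      - {daughter: Po-213, fraction: 0.9780}   # beta branch
      - {daughter: Tl-209, fraction: 0.0220}   # alpha branch
    energy_MeV: {alpha: 0.1290, electron: 0.4350, photon: 0.1320}
  - name: Po-213
    half_life_s: 4.2e-06
    branches:
      - {daughter: Pb-209, fraction: 1.0}
    energy_MeV: {alpha: 8.3760, electron: 0.0, photon: 0.0}
  - name: Tl-209
    half_life_s: 129.72          # 2.162 min
    branches:
      - {daughter: Pb-209, fraction: 1.0}
    energy_MeV: {alpha: 0.0, electron: 0.6590, photon: 1.9860}
  - name: Pb-209
    half_life_s: 11710.8         # 3.253 h
    branches:
      - {daughter: Bi-209, fraction: 1.0}
    energy_MeV: {alpha: 0.0, electron: 0.1979, photon: 0.0}
  - name: Bi-209
    half_life_s: null            # stable on any dosimetric timescale
    branches: []
    energy_MeV: {alpha: 0.0, electron: 0.0, photon: 0.0}
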