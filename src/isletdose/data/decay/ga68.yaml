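# Condensed emission line list for Ga-68 (beta-plus decay).
#
# Schema version 1; see in111.yaml for field meanings.  beta_plus lines
# carry the spectrum endpoint (endpoint_keV) and the tabulated mean
# energy (energy_keV); continuous energies are sampled from an
# allowed-transition Fermi shape calibrated so its mean equals
# energy_keV exactly.  The 511 keV annihilation photons are listed as a
# gamma line (yield 1.78); positron transport therefore does not add
# annihilation quanta a second time.
schema_version: 1
nuclide: Ga-68
half_life_h: 1.1285          # 67.71 minutes
lines:
  - {kind: gamma, energy_keV: 511.0, yield: 1.78}
  - {kind: gamma, energy_keV: 1077.0, yield: 0.032}
  - {kind: gamma, energy_keV: 1883.0, yield: 0.0014}
  - {kind: beta_plus, energy_keV: 836.0, endpoint_keV: 1899.0, yield: 0.88}
  - {kind: beta_plus, energy_keV: 353.0, endpoint_keV: 822.0, yield: 0.01}
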