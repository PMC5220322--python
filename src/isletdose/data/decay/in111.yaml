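# Condensed emission line list for In-111 (electron capture decay).
#
# Schema (version 1):
#   nuclide: label
#   half_life_h: physical half-life in hours
#   lines: [{kind, energy_keV, yield}, ...]
#     kind   one of gamma | auger_electron | ic_electron | beta_plus
#     yield  emissions per decay (group yields may exceed 1)
#
# The Auger cascade is condensed to its two dominant discrete energies
# (8.5 eV and 350 eV) plus one residual line placed so that the group
# reproduces the published group yield (14.7 electrons/decay) and the
# group mean energy per decay (6.75 keV).  The internal-conversion group
# keeps the four principal K/L conversion energies of the 171/245 keV
# transitions with yields solved so that the group yield is 0.16 and the
# group mean energy per decay is 26.0 keV.  Per-decay energy bookkeeping,
# which drives every S-value, is therefore preserved exactly.
schema_version: 1
nuclide: In-111
half_life_h: 67.2            # 2.80 days
lines:
  - {kind: gamma, energy_keV: 171.3, yield: 0.94}
  - {kind: gamma, energy_keV: 245.4, yield: 0.91}
  - {kind: auger_electron, energy_keV: 0.0085, yield: 7.4}
  - {kind: auger_electron, energy_keV: 0.35, yield: 6.0}
  - {kind: auger_electron, energy_keV: 3.5285384615384614, yield: 1.3}
  - {kind: ic_electron, energy_keV: 145.0, yield: 0.11697260273972603}
  - {kind: ic_electron, energy_keV: 171.0, yield: 0.013}
  - {kind: ic_electron, energy_keV: 218.0, yield: 0.020027397260273975}
  - {kind: ic_electron, energy_keV: 245.0, yield: 0.010}
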