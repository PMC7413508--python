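# Nuclide decay data used throughout the package.
# half_life_h: physical half-life in hours.
# electron_energy_mev: mean non-penetrating (beta + conversion/Auger) energy
#   emitted per decay, MeV. photon_energy_mev: mean photon energy per decay.
# 177Lu values are standard decay-data compilations (half-life 6.647 d).
Lu-177:
  half_life_h: 159.528
  electron_energy_mev: 0.147
  photon_energy_mev: 0.033
Y-90:
  half_life_h: 64.05
  electron_energy_mev: 0.933
  photon_energy_mev: 0.0
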