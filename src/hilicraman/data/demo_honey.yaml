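# Honey-like sample: injected-solution concentrations derived from a
# composition of Fru 39.9, Glu 26.5, Suc 0.9 wt% (Mal, Tre absent) after
# dissolving 1 g in 20 mL and injecting 1 mL.  Rank forced to 11 to hunt for
# minor components beyond the visually significant ones.
seed: 7
targets: [Fru, Glu, Suc, Mal, Tre]
sample_concentrations_mM:
  Fru: 110.7349
  Glu: 73.5457
  Suc: 1.3146
  Mal: 0.0
  Tre: 0.0
standards:
  Fru: {concentration_mM: 200.0, injected_mL: 1.0}
  Glu: {concentration_mM: 160.0, injected_mL: 1.0}
  Suc: {concentration_mM: 100.0, injected_mL: 1.0}
  Mal: {concentration_mM: 100.0, injected_mL: 1.0}
  Tre: {concentration_mM: 100.0, injected_mL: 1.0}
dilution: {mass_g: 1.0, volume_mL: 20.0, injected_mL: 1.0}
windows:
  Fru: [35.3, 38.0]
  Glu: [38.0, 40.7]
  Suc: [40.7, 43.3]
  Mal: [44.7, 47.3]
  Tre: [46.0, 49.0]
rank: 11
noise_sigma: 0.005
mask: [[368.0, 392.0], [908.0, 932.0], [1363.0, 1387.0]]
subtract_solvent: true
calibration_levels_mM: [5.0, 10.0, 15.0, 20.0, 25.0]
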