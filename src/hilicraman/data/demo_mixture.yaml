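# Five-sugar equimolar mixture (25 mM each), quantified against the
# single-standard runs.  Values are the default study conditions.
seed: 7
targets: [Fru, Glu, Suc, Mal, Tre]
sample_concentrations_mM: {Fru: 25.0, Glu: 25.0, Suc: 25.0, Mal: 25.0, Tre: 25.0}
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
rank: auto
noise_sigma: 0.005
mask: [[368.0, 392.0], [908.0, 932.0], [1363.0, 1387.0]]
subtract_solvent: true
calibration_levels_mM: [5.0, 10.0, 15.0, 20.0, 25.0]
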