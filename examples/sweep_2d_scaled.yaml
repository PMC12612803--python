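# Scaled 2-D sweep: pore-size and porosity dependence at 500 kHz.
# Desk-scale profile (2-D disks, 3.2 mm transverse extent); magnitudes are
# not comparable to full 3-D spheres, trends are.
pore_diameters_mm: [0.1, 0.3, 0.6]
porosities: [0.1, 0.25, 0.5]
frequencies: [500000.0]
source_kinds: [single_cycle_pulse]
methods: [group, phase]
dimensionality: 2
transverse_extent_mm: 3.2
seeds: [0, 1, 2]
porosity_tolerance: 0.03
durations_by_kind:
  single_cycle_pulse: 1.2e-05
output_root: sweep_2d_scaled_results
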