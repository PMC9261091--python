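# Reduced-morphology layer-5 pyramidal cell: four compartments forming the
# chain basal — soma — apical_trunk — apical_tuft.  Geometry and conductance
# densities (S/cm^2) are this package's defaults, fitted by hand to reproduce
# qualitative thick-tufted L5PC behaviour: adapting regular spiking, Ih sag,
# input resistance of a few tens of MOhm.
cell_type: L5PC
v_init: -75.0
channel_table: channels_l5pc.tsv
calcium:
  rest: 1.0e-4          # mM
  decay_tau: 80.0       # ms
  influx_scale: 5.0e-3  # mM cm^2 / (ms mA)
compartments:
  - name: basal
    length_um: 150.0
    diameter_um: 2.5
    axial_resistivity: 150.0
    capacitance: 1.5
    channels:
      leak: 5.0e-5
      Ih: 1.0e-4
  - name: soma
    length_um: 35.0
    diameter_um: 25.0
    axial_resistivity: 150.0
    capacitance: 1.0
    channels:
      NaT: 0.20
      NaP: 4.0e-4
      K_transient: 0.01
      K_persistent: 0.008
      Kv3: 0.10
      SK: 8.0e-3
      M: 1.2e-3
      Ih: 1.0e-4
      CaHVA: 6.0e-4
      CaLVA: 1.0e-4
      leak: 4.0e-5
  - name: apical_trunk
    length_um: 250.0
    diameter_um: 3.0
    axial_resistivity: 150.0
    capacitance: 1.5
    channels:
      leak: 5.0e-5
      Ih: 3.0e-4
  - name: apical_tuft
    length_um: 200.0
    diameter_um: 2.5
    axial_resistivity: 150.0
    capacitance: 1.5
    channels:
      leak: 6.0e-5
      Ih: 8.0e-4
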