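# Fast-spiking PV+ basket cell: single somatic compartment.
cell_type: FS_basket
v_init: -70.0
channel_table: channels_fs.tsv
compartments:
  - name: soma
    length_um: 30.0
    diameter_um: 30.0
    axial_resistivity: 150.0
    capacitance: 1.0
    channels:
      NaT: 0.10
      Kv3: 0.08
      leak: 1.0e-4
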