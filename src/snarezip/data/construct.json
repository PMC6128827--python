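{
  "dsdna_persistence_nm": 45.0,
  "dsdna_contour_per_bp_nm": 0.338,
  "dsdna_stretch_modulus_pn": 1200.0,
  "peptide_persistence_nm": 0.6,
  "peptide_contour_per_res_nm": 0.365,
  "helix_rise_per_res_nm": 0.15,
  "folded_axial_nm": {
    "FULLY_ZIPPERED": 2.0,
    "LINKER_OPEN": 2.468009,
    "HALF_ZIPPERED": 2.897477,
    "UNZIPPED": 5.609313,
    "SNAP25_OFF": 4.990455
  }
}
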