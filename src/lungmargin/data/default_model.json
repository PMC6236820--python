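{
  "version": "1.0",
  "reference_prescription_Gy_RBE": 50.4,
  "margins_mm": {
    "20": 11.0,
    "5": 22.0
  }
}
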