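{
  "class_names": [
    "A",
    "B",
    "C",
    "D",
    "E"
  ],
  "montage": [
    "Fp1",
    "Fp2",
    "F7",
    "F3",
    "Fz",
    "F4",
    "F8",
    "T3",
    "C3",
    "Cz",
    "C4",
    "T4",
    "T5",
    "P3",
    "Pz",
    "P4",
    "T6",
    "O1",
    "O2"
  ],
  "provenance": {
    "kind": "reference",
    "generator": "synthetic-canonical"
  }
}
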