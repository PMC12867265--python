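{
  "_comment": "Electron-ion interaction pseudopotential (EIIP) constants per ribonucleotide. Standard literature values as used by the common iLearn-style descriptor conventions.",
  "A": 0.126,
  "C": 0.134,
  "G": 0.0806,
  "U": 0.1335
}
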