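{
  "diabetes": [
    "diabetes",
    "MODY",
    "DM2",
    "T2D",
    "mellitus",
    "urophthisis",
    "glycuresis"
  ],
  "obesity": [
    "obesity",
    "obese",
    "obesitas",
    "adiposity",
    "adipositas",
    "adiposis",
    "corpulence",
    "corpulency",
    "fatness",
    "polysarcia"
  ]
}
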