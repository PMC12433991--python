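{
  "betts_russell": {
    "polar": "HKRDEYWTCSNQ",
    "charged": "DERHK",
    "negative": "DE",
    "positive": "RHK",
    "small": "AGCSPNDTV",
    "tiny": "AGCS",
    "hydrophobic": "HFWYILVMKTAGC",
    "aromatic": "HFWY",
    "aliphatic": "ILV"
  },
  "koolman_rohm": {
    "aliphatic": "GAVLI",
    "sulfur": "CM",
    "aromatic": "FYW",
    "neutral": "STNQ",
    "acidic": "DE",
    "basic": "HKR",
    "cyclic": "P"
  }
}
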