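{
  "_comment": [
    "Three-group physicochemical partitions of the 20 standard residues used",
    "by the composition/transition/distribution (CTD) descriptors. These are",
    "the classic Dubchak-style groupings: each attribute splits the alphabet",
    "into three disjoint, exhaustive groups (low / medium / high, or the",
    "attribute's natural categories). Override by passing a mapping of the",
    "same shape to EncoderConfig.ctd_groups."
  ],
  "hydrophobicity": {
    "code": "HB",
    "groups": ["RKEDQN", "GASTPHY", "CLVIMFW"],
    "labels": ["polar", "neutral", "hydrophobic"]
  },
  "vdw_volume": {
    "code": "VW",
    "groups": ["GASTPDC", "NVEQIL", "MHKFRYW"],
    "labels": ["0-2.78", "2.95-4.0", "4.03-8.08"]
  },
  "polarity": {
    "code": "PO",
    "groups": ["LIFWCMVY", "PATGS", "HQRKNED"],
    "labels": ["4.9-6.2", "8.0-9.2", "10.4-13.0"]
  },
  "polarizability": {
    "code": "PZ",
    "groups": ["GASDT", "CPNVEQIL", "KMHFRYW"],
    "labels": ["0-0.108", "0.128-0.186", "0.219-0.409"]
  },
  "charge": {
    "code": "CH",
    "groups": ["KR", "ANCQGHILMFPSTWYV", "DE"],
    "labels": ["positive", "neutral", "negative"]
  },
  "secondary_structure": {
    "code": "SS",
    "groups": ["EALMQKRH", "VIYCWFT", "GNPSD"],
    "labels": ["helix", "strand", "coil"]
  },
  "solvent_accessibility": {
    "code": "SA",
    "groups": ["ALFCGIVW", "RKQEND", "MSPTHY"],
    "labels": ["buried", "exposed", "intermediate"]
  }
}
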