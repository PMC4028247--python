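{
  "core_set_family_counts": {
    "COP-II": 8,
    "COP-I": 16,
    "CCV": 18,
    "Retromer/ESCRT": 20,
    "RabGTPase": 68,
    "Tethering": 45,
    "SNARE": 65
  },
  "literature_species_counts": {
    "arabidopsis": 212,
    "yeast": 45
  },
  "literature_overlap": 17,
  "three_species_class_counts": {
    "class_I": 416,
    "total": 527
  },
  "three_species_coorthologue_counts": {
    "yeast": 129,
    "arabidopsis": 340,
    "tomato": 307
  }
}
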