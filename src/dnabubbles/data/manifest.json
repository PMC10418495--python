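{
  "files": {
    "range_maximum.tsv": "a0c2c0a9870ecb4a6b3d2b36ff4efe7ac2a01b3a5af40ee7d8a69ecf640b386e",
    "range_minimum.tsv": "4e640f5a93a726697967c8161cc361d42274b15b90404f76b0ab00678a576031",
    "composition.tsv": "7cf616f1deab1f98164acd872871c6ab99a64ea487c37d592558e4a39e9030b3",
    "base_mechanics.yaml": "a882cfb8513e25017d8ea94df4ac460bca0dd447314db7d8c11fc5ec18e8f746"
  },
  "notes": {
    "range_maximum.tsv": "Published per-(energy, region) counts n and A-T tallies of substitution positions in the 'Maximum' range, long format; all_closed=1 marks '-' cells where every position of the gene part has Pi = 0.0 (n and at are 0 there).",
    "range_minimum.tsv": "Same layout for the 'Minimum' range.",
    "composition.tsv": "Region partition of the 980-bp gene with published A-T / G-C percentages.",
    "units": "energy in 1e-22 N*m, quoted as exact decimal strings"
  }
}
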