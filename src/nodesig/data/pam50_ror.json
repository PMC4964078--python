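{
  "name": "pam50",
  "centroid_file": "pam50_centroids_synthetic.tsv",
  "centroids_synthetic": true,
  "version": "nodesig-synthetic-1",
  "subtypes": ["LumA", "LumB", "Her2", "Basal", "Normal"],
  "ror_coefficients": {"Basal": 0.05, "Her2": 0.12, "LumA": -0.34, "LumB": 0.23},
  "default_exclusion": ["ANLN", "CDCA1", "CXXC5", "FOXC1", "TMEM45B", "UBE2T"],
  "notes": "The subtype-correlation ROR (ROR-S) combination coefficients are the published ones; the Normal-like subtype carries no coefficient. The centroid matrix is a synthetic stand-in structured by known subtype biology, not the published training centroids. default_exclusion lists the six genes whose probesets were unavailable on the arrays the scores were designed around."
}
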