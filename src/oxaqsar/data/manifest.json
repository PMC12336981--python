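{
 "files": {
  "candidate_properties.csv": "64d229f5b46400783cb09a744681472a30389276ec9180242095b55cb9b03ff4",
  "candidates.csv": "9184ac634b0507d6054872311acf5aeb22105834a478917549e5c7996befbf6a",
  "descriptor_panel.csv": "17d8cc8d746364c9f1a84daa5585add8bd09ab96722259400b745607b411ee3c",
  "modeling_records.csv": "382ebd1866ad2dbb2d3842ca5f08d1e6efdb28835f8def11cdc5da4c5739b58d",
  "published_predictions.csv": "5f67411e6e7dddd6940778dde33d0efd1761566e5d54080273395dd19bfe1c31",
  "test_pairs.csv": "98c35cd225ff23d5b7d507af0453cfa1079bf588869735492e19780b2a3507f1"
 },
 "format": 1,
 "notes": "31 of 33 panel compounds appear in the modeling table; two compounds were excluded from modeling (identities not recorded at source). Modeling records are keyed by modeling-table row order, which does not align with panel numbering; no join is defined."
}
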