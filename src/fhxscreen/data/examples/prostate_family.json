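{
  "id": "proband",
  "relation": "self",
  "sex": "female",
  "age": 40,
  "relatives": [
    {
      "id": "father",
      "relation": "father",
      "sex": "male",
      "age": 68,
      "cancers": [
        {"type": "prostate", "age_at_dx": 54, "primary_index": 1}
      ]
    },
    {
      "id": "brother",
      "relation": "brother",
      "sex": "male",
      "age": 55,
      "cancers": [
        {"type": "prostate", "age_at_dx": 53, "primary_index": 1}
      ]
    }
  ]
}
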