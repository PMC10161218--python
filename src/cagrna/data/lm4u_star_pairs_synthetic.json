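{
  "name": "lm4U* (synthetic stand-in pairing table)",
  "note": "Synthetic illustrative register for the destabilized fourU thermometer hairpin control (C23U context). Only the canonical base-pair count (14) is anchored; positions are placeholders, not the real secondary structure.",
  "n_canonical_pairs": 14,
  "pairs": [
    {"i": 1, "j": 36, "kind": "canonical"},
    {"i": 2, "j": 35, "kind": "canonical"},
    {"i": 3, "j": 34, "kind": "canonical"},
    {"i": 4, "j": 33, "kind": "canonical"},
    {"i": 5, "j": 32, "kind": "canonical"},
    {"i": 6, "j": 31, "kind": "canonical"},
    {"i": 7, "j": 30, "kind": "canonical"},
    {"i": 9, "j": 28, "kind": "canonical"},
    {"i": 10, "j": 27, "kind": "canonical"},
    {"i": 11, "j": 26, "kind": "canonical"},
    {"i": 12, "j": 25, "kind": "canonical"},
    {"i": 13, "j": 24, "kind": "canonical"},
    {"i": 14, "j": 23, "kind": "wobble-context"},
    {"i": 15, "j": 22, "kind": "canonical"},
    {"i": 16, "j": 21, "kind": "canonical"}
  ]
}
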