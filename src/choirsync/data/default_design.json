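{
  "voices": ["soprano", "altus", "tenor", "bassus"],
  "singers_per_voice": 2,
  "conditions": ["modern", "touch", "no_touch"],
  "n_frequency_components": 10,
  "pieces": [
    {"name": "Agnus Dei I",   "unit": "Agnus",   "repeats_per_voice": {"soprano": 6, "altus": 6, "tenor": 6, "bassus": 6}},
    {"name": "Agnus Dei II",  "unit": "Agnus",   "repeats_per_voice": {"soprano": 6, "altus": 0, "tenor": 0, "bassus": 6}},
    {"name": "Agnus Dei III", "unit": "Agnus",   "repeats_per_voice": {"soprano": 4, "altus": 4, "tenor": 4, "bassus": 4}},
    {"name": "Kyrie I",       "unit": "Kyrie",   "repeats_per_voice": {"soprano": 2, "altus": 2, "tenor": 2, "bassus": 2}},
    {"name": "Kyrie II",      "unit": "Kyrie",   "repeats_per_voice": {"soprano": 2, "altus": 2, "tenor": 2, "bassus": 2}},
    {"name": "Gloria",        "unit": "Kyrie",   "repeats_per_voice": {"soprano": 2, "altus": 2, "tenor": 2, "bassus": 2}},
    {"name": "Virgo prudentissima", "unit": "Josquin", "repeats_per_voice": {"soprano": 6, "altus": 6, "tenor": 6, "bassus": 6}},
    {"name": "D'ung aultre amer",   "unit": "Josquin", "repeats_per_voice": {"soprano": 3, "altus": 3, "tenor": 3, "bassus": 3}}
  ],
  "blocks": ["Agnus", "Agnus", "Agnus", "Kyrie", "Kyrie", "Josquin", "Josquin", "Josquin"]
}
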