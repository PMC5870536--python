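{
  "_note": [
    "RECONSTRUCTED PLACEHOLDER - verify before use on real data.",
    "The four Areas are the protein segments whose 3D structure differs",
    "between Claisen-cyclizing (R-4-C, chalcone synthase) and",
    "aldol-cyclizing (R-4-A, stilbene synthase) plant type III PKSs,",
    "numbered on the Medicago sativa CHS2 crystal structure.  The exact",
    "residue ranges are not shipped with this package: edit start/end",
    "below after checking them against the published CHS2/STS structural",
    "comparison, and set reference_id to the id of the CHS2 row in your",
    "alignment.  The synthetic benchmark does NOT use this file (its Area",
    "map is generated with the data)."
  ],
  "reference_id": "CHS2_MEDSA",
  "segments": [
    {"name": "Area1", "start": 95, "end": 106},
    {"name": "Area2", "start": 130, "end": 136},
    {"name": "Area3", "start": 191, "end": 202},
    {"name": "Area4", "start": 368, "end": 373}
  ]
}
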