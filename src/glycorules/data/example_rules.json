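[
 {
  "schema_version": 1,
  "mass_group": 425.18,
  "topology_rules": [],
  "isomer_rules": {
   "": [
    {
     "rule_id": "EX-425-1",
     "isomer": "GalNAc(a1-3)GalNAc-ol",
     "conditions": [
      {
       "feature_kind": "ratio",
       "bin": 730,
       "mz": 365.1,
       "denominator_bin": 634,
       "denominator_mz": 317.1,
       "comparator": ">",
       "threshold": 1.5
      }
     ],
     "confidence": null,
     "coverage": null,
     "n_test": 0,
     "fragments": ["m/z 365.1: A-type cross-ring candidate (reducing-end alditol, -C2H4O2)", "m/z 317.1: unassigned"],
     "flags": ["transcribed"]
    }
   ]
  },
  "ruleless_classes": [],
  "provenance": {
   "source": "literature-transcribed example: intensity ratio m/z 365.1 / m/z 317.1 above 1.5 indicates the core 5 HexNAc2 isomer; below, core 3"
  }
 },
 {
  "schema_version": 1,
  "mass_group": 530.21,
  "topology_rules": [],
  "isomer_rules": {
   "": [
    {
     "rule_id": "EX-530-1",
     "isomer": "Gal(b1-4)GlcNAc(b1-3)Fuc-ol",
     "conditions": [
      {
       "feature_kind": "bin",
       "bin": 700,
       "mz": 350.1,
       "comparator": ">",
       "threshold": null
      }
     ],
     "confidence": 1.0,
     "coverage": 1.0,
     "n_test": 0,
     "fragments": ["m/z 350.1: Z-ion retaining HexNAc1dHex1 on the reduced core fucose (topologically impossible in the O-GalNAc isomer)"],
     "flags": ["transcribed", "threshold-not-printed"]
    }
   ]
  },
  "ruleless_classes": [],
  "provenance": {
   "source": "literature-transcribed example: prominent m/z 350.1 indicates the O-Fuc isomer of Hex1HexNAc1dHex1; reported at 100% confidence and coverage at the best intensity threshold (threshold value not printed)"
  }
 },
 {
  "schema_version": 1,
  "mass_group": 733.29,
  "topology_rules": [
   {
    "rule_id": "EX-733-T1",
    "isomer": "Fuc(??-?)[GlcNAc(??-?)]Gal(??-?)GalNAc-ol",
    "conditions": [
     {
      "feature_kind": "bin",
      "bin": 768,
      "mz": 384.2,
      "comparator": ">",
      "threshold": null
     }
    ],
    "confidence": null,
    "coverage": null,
    "n_test": 0,
    "fragments": ["m/z 384.2: Y-ion retaining the core 1 Gal-GalNAc-ol epitope"],
    "flags": ["transcribed", "threshold-not-printed"]
   }
  ],
  "isomer_rules": {},
  "ruleless_classes": [],
  "provenance": {
   "source": "literature-transcribed example: presence of the m/z 384.2 Y-ion (core 1 epitope) separates core 1 isomers within Hex1HexNAc2dHex1; exact thresholds for the m/z 359 / 510.2 / 409.1 splits are not printed in the source text and are omitted"
  }
 }
]
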