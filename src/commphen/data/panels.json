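{
  "panels": {
    "scfa": [
      "butyrate_via_pyruvate",
      "butyrate_via_succinate",
      "butyrate_via_lysine",
      "butyrate_via_glutamate",
      "propionate_via_succinate",
      "propionate_via_acrylate",
      "propionate_via_propanediol",
      "propionate_via_threonine"
    ],
    "vitamins": [
      "vitamin_B1",
      "vitamin_B2",
      "vitamin_B3",
      "vitamin_B5",
      "vitamin_B6",
      "vitamin_B7",
      "vitamin_B9",
      "vitamin_B12",
      "vitamin_K",
      "vitamin_Q",
      "lipoate"
    ],
    "amino_acids": [
      "aa_Ala", "aa_Arg", "aa_Asn", "aa_Asp", "aa_Cys",
      "aa_Gln", "aa_Glu", "aa_Gly", "aa_His", "aa_Ile",
      "aa_Leu", "aa_Lys", "aa_Met", "aa_Phe", "aa_Pro",
      "aa_Ser", "aa_Thr", "aa_Trp", "aa_Tyr", "aa_Val"
    ],
    "sugars": [
      "sugar_Glc", "sugar_Gal", "sugar_Fru", "sugar_Man", "sugar_GlcA",
      "sugar_GalA", "sugar_Xyl", "sugar_Ara", "sugar_Rha", "sugar_Rib"
    ]
  },
  "pathway_sets": {
    "butyrate": {
      "members": [
        "butyrate_via_pyruvate",
        "butyrate_via_succinate",
        "butyrate_via_lysine",
        "butyrate_via_glutamate"
      ],
      "contexts": {
        "control": ["butyrate_via_lysine", "butyrate_via_glutamate"],
        "herb": [
          "butyrate_via_pyruvate",
          "butyrate_via_succinate",
          "butyrate_via_lysine",
          "butyrate_via_glutamate"
        ]
      }
    },
    "propionate": {
      "members": [
        "propionate_via_succinate",
        "propionate_via_acrylate",
        "propionate_via_propanediol",
        "propionate_via_threonine"
      ],
      "contexts": {
        "control": [
          "propionate_via_succinate",
          "propionate_via_acrylate",
          "propionate_via_propanediol",
          "propionate_via_threonine"
        ],
        "herb": [
          "propionate_via_succinate",
          "propionate_via_acrylate",
          "propionate_via_propanediol",
          "propionate_via_threonine"
        ]
      }
    }
  }
}
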