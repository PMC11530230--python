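{
 "metadata": {
  "min_support": 200,
  "mass_fraction": 0.6,
  "theta_percentile": 75.0,
  "provenance": "omegamap toy reference set (make_reference_set, n=300, seed=20240901)",
  "note": "bundled default, estimated from synthetic folded-domain-like toy structures; NOT publication-grade. Re-estimate from a curated PDB collection for production analyses."
 },
 "entries": [
  {
   "d_lo": 9.299999999999999,
   "d_hi": 12.459999999999999,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 205,
   "aa_i": "A",
   "aa_j": "T",
   "range": "long"
  },
  {
   "d_lo": 4.92,
   "d_hi": 10.5,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 33975,
   "aa_i": "ANY",
   "aa_j": "ANY",
   "range": "long"
  },
  {
   "d_lo": 4.32395493836398,
   "d_hi": 5.363954938363981,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 8567,
   "aa_i": "ANY",
   "aa_j": "ANY",
   "range": "1"
  },
  {
   "d_lo": 5.4951277248355375,
   "d_hi": 7.375127724835539,
   "preferred_rotation": [
    -0.7563066574633635,
    0.4045205343027634,
    -0.5141536348524092,
    0.003068708532373497
   ],
   "theta_max": 2.1064981677587973,
   "alpha_max": 0.9400000000000008,
   "support_count": 8267,
   "aa_i": "ANY",
   "aa_j": "ANY",
   "range": "2"
  },
  {
   "d_lo": 4.982388643265862,
   "d_hi": 8.402388643265866,
   "preferred_rotation": [
    -0.027876425948690966,
    0.015980333279470207,
    -0.02849683112309735,
    0.9990773065386609
   ],
   "theta_max": 1.6409120203703496,
   "alpha_max": 1.7100000000000017,
   "support_count": 7967,
   "aa_i": "ANY",
   "aa_j": "ANY",
   "range": "3"
  },
  {
   "d_lo": 2.6562681082255573,
   "d_hi": 7.876268108225554,
   "preferred_rotation": [
    -0.018286293781943685,
    0.0049772165525252465,
    -0.011026096503180247,
    -0.9997596030901691
   ],
   "theta_max": 1.7973179895296882,
   "alpha_max": 2.6099999999999985,
   "support_count": 7309,
   "aa_i": "ANY",
   "aa_j": "ANY",
   "range": "4"
  },
  {
   "d_lo": 9.557461934574366,
   "d_hi": 12.91746193457437,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 201,
   "aa_i": "C",
   "aa_j": "G",
   "range": "long"
  },
  {
   "d_lo": 9.793775510772488,
   "d_hi": 12.993775510772487,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 209,
   "aa_i": "C",
   "aa_j": "H",
   "range": "long"
  },
  {
   "d_lo": 9.336464999339892,
   "d_hi": 12.616464999339895,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 202,
   "aa_i": "D",
   "aa_j": "H",
   "range": "long"
  },
  {
   "d_lo": 9.145943999201537,
   "d_hi": 12.50594399920154,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 219,
   "aa_i": "G",
   "aa_j": "T",
   "range": "long"
  },
  {
   "d_lo": 5.148334368686616,
   "d_hi": 10.408334368686614,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 208,
   "aa_i": "H",
   "aa_j": "M",
   "range": "long"
  },
  {
   "d_lo": 8.786667931368761,
   "d_hi": 12.36666793136876,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 203,
   "aa_i": "H",
   "aa_j": "P",
   "range": "long"
  },
  {
   "d_lo": 9.058382029686388,
   "d_hi": 12.658382029686388,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 210,
   "aa_i": "H",
   "aa_j": "S",
   "range": "long"
  },
  {
   "d_lo": 5.3,
   "d_hi": 10.76,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 223,
   "aa_i": "L",
   "aa_j": "T",
   "range": "long"
  },
  {
   "d_lo": 9.685002767618158,
   "d_hi": 12.625002767618158,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 201,
   "aa_i": "M",
   "aa_j": "V",
   "range": "long"
  },
  {
   "d_lo": 9.24,
   "d_hi": 12.66,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 217,
   "aa_i": "P",
   "aa_j": "T",
   "range": "long"
  },
  {
   "d_lo": 9.264196999054885,
   "d_hi": 12.804196999054888,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 200,
   "aa_i": "Q",
   "aa_j": "S",
   "range": "long"
  },
  {
   "d_lo": 9.36,
   "d_hi": 12.58,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 211,
   "aa_i": "R",
   "aa_j": "T",
   "range": "long"
  },
  {
   "d_lo": 9.294927852668891,
   "d_hi": 12.434927852668888,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 201,
   "aa_i": "R",
   "aa_j": "W",
   "range": "long"
  },
  {
   "d_lo": 4.245371580513275,
   "d_hi": 10.28537158051328,
   "preferred_rotation": null,
   "theta_max": null,
   "alpha_max": 0.0,
   "support_count": 205,
   "aa_i": "T",
   "aa_j": "Y",
   "range": "long"
  }
 ]
}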