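{
  "description": "Published cross-tabulation matrices of clinical (rows) vs consensus imaging (columns) posture labels. table1: full 28-rater panel, 4-category (28 images per variant). table2: binary, items split at the median vote entropy (14 images per stratum). table3: binary, consensus recomputed from experience subgroups (<10 years: 16 raters; >10 years: 12 raters; 28 images each).",
  "tables": [
    {"table_id": "table1", "variant": "S", "stratum": "all",
     "categories": ["IDEAL", "KL", "SB", "FB"],
     "counts": [[4, 0, 0, 3], [0, 3, 0, 4], [0, 2, 3, 2], [3, 0, 2, 2]]},
    {"table_id": "table1", "variant": "G", "stratum": "all",
     "categories": ["IDEAL", "KL", "SB", "FB"],
     "counts": [[5, 1, 0, 1], [0, 3, 2, 2], [2, 3, 1, 1], [3, 1, 2, 1]]},
    {"table_id": "table2", "variant": "S", "stratum": "low_entropy",
     "categories": ["IDEAL", "NON_IDEAL"],
     "counts": [[2, 1], [0, 11]]},
    {"table_id": "table2", "variant": "S", "stratum": "high_entropy",
     "categories": ["IDEAL", "NON_IDEAL"],
     "counts": [[2, 2], [3, 7]]},
    {"table_id": "table2", "variant": "G", "stratum": "low_entropy",
     "categories": ["IDEAL", "NON_IDEAL"],
     "counts": [[3, 1], [0, 10]]},
    {"table_id": "table2", "variant": "G", "stratum": "high_entropy",
     "categories": ["IDEAL", "NON_IDEAL"],
     "counts": [[2, 1], [5, 6]]},
    {"table_id": "table3", "variant": "S", "stratum": "lt10y",
     "categories": ["IDEAL", "NON_IDEAL"],
     "counts": [[6, 1], [2, 19]]},
    {"table_id": "table3", "variant": "S", "stratum": "gt10y",
     "categories": ["IDEAL", "NON_IDEAL"],
     "counts": [[2, 5], [3, 18]]},
    {"table_id": "table3", "variant": "G", "stratum": "lt10y",
     "categories": ["IDEAL", "NON_IDEAL"],
     "counts": [[5, 2], [5, 16]]},
    {"table_id": "table3", "variant": "G", "stratum": "gt10y",
     "categories": ["IDEAL", "NON_IDEAL"],
     "counts": [[5, 2], [2, 19]]}
  ]
}
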