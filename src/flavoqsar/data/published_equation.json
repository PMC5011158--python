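{
  "schema_version": 1,
  "model_id": "builtin:flavonoid-pgp-2016",
  "response": "pFAR",
  "terms": [
    ["RDF_PiChg_86", -0.613],
    ["RDF_SigChg_76", 0.461],
    ["3DACorr_TotChg_9", -0.283],
    ["RDF_LpEN_54", 0.207],
    ["3DACorr_PiChg_9", -0.284],
    ["RDF_SigChg_57", -0.197]
  ],
  "intercept": -0.416,
  "n_training": 23,
  "statistics": {
    "R": 0.963,
    "R2": 0.927,
    "R2_adj": 0.900,
    "SEE": 0.197,
    "F": 33.849,
    "q2_loo": 0.927
  },
  "sha256_of_terms": "a3053ec540ccbaffad19adbf846d23b28974c628613b3a748a5e47297e49a968"
}
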