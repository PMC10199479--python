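{
 "svm": {
  "full": [
   {"kernel": ["linear"],
    "C": [0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]},
   {"kernel": ["rbf"],
    "C": [0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0],
    "gamma": [0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]}
  ],
  "reduced": [
   {"kernel": ["linear"], "C": [0.01, 1.0, 100.0]},
   {"kernel": ["rbf"], "C": [0.01, 1.0, 100.0], "gamma": [0.001, 0.1, "scale"]}
  ]
 },
 "rf": {
  "full": [
   {"n_estimators": [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000,
                     1100, 1200, 1300, 1400, 1500, 1600, 1700, 1800, 1900, 2000],
    "max_depth": [10, 20, 30, null],
    "min_samples_leaf": [1, 2, 3, 5],
    "min_samples_split": [2, 3, 5]}
  ],
  "reduced": [
   {"n_estimators": [100, 500, 1500],
    "max_depth": [10, 30, null],
    "min_samples_leaf": [1, 3],
    "min_samples_split": [2]}
  ]
 }
}
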