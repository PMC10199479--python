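{
 "algorithm": "rf",
 "preprocessing": ["polynomial", "minmax"],
 "hyperparameters": {
  "n_estimators": 1500,
  "max_depth": 30,
  "min_samples_leaf": 3,
  "min_samples_split": 2,
  "max_features": "sqrt",
  "criterion": "entropy"
 },
 "seed": 0
}
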