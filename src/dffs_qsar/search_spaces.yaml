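# Hyperparameter search spaces per regressor family.
# Each entry: parameter -> {type: int|float|logfloat|choice, low/high or values}.
# Trial 1 of any search always uses the family's published defaults, so a
# budgeted search can only improve (or tie) the cross-validated score.
bagged_forest:
  n_estimators: {type: int, low: 100, high: 500}
  max_depth: {type: choice, values: [null, 8, 12, 16, 24]}
  max_features: {type: choice, values: [1.0, 0.5, 0.3, sqrt]}
  min_samples_leaf: {type: int, low: 1, high: 8}
boosted_trees:
  n_estimators: {type: int, low: 100, high: 600}
  max_depth: {type: int, low: 3, high: 9}
  learning_rate: {type: logfloat, low: 0.01, high: 0.3}
  subsample: {type: float, low: 0.6, high: 1.0}
  colsample_bytree: {type: float, low: 0.6, high: 1.0}
  reg_lambda: {type: logfloat, low: 0.1, high: 10.0}
hist_boosted_trees:
  n_estimators: {type: int, low: 100, high: 600}
  num_leaves: {type: int, low: 15, high: 127}
  learning_rate: {type: logfloat, low: 0.01, high: 0.3}
  min_child_samples: {type: int, low: 5, high: 50}
  subsample: {type: float, low: 0.6, high: 1.0}
  colsample_bytree: {type: float, low: 0.6, high: 1.0}
cascade_forest:
  n_estimators_per_forest: {type: int, low: 50, high: 200}
  max_layers: {type: int, low: 1, high: 6}
  min_samples_leaf: {type: int, low: 1, high: 8}
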