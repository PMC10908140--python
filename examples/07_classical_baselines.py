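"""Classical-classifier baselines: grid search + feature importance.

The eight classical algorithms run behind a grid-search harness whose
default grids contain the published winning hyperparameters; tree
ensembles additionally expose impurity-based feature importance (the "most
crucial points in the EEG").
"""

from capseeg.classic_ml import GridSpec, feature_importance, grid_search_fit
from capseeg.data import SynthConfig, stratified_split, synth_generate, \
    to_binary

data = to_binary(synth_generate(SynthConfig(n_per_class=50, seed=4)))
train_set, test_set = stratified_split(data, 0.25, seed=0)

spec = GridSpec("ETC", grid={"n_estimators": [50, 150],
                             "min_samples_split": [2, 4],
                             "random_state": [20]}, cv_folds=5)
est, best = grid_search_fit(spec, train_set)
acc = (est.predict(test_set.signals) == test_set.labels).mean()
print(f"ETC best params: {best}")
print(f"ETC test accuracy: {100 * acc:.2f}%")

top = feature_importance(est, top_n=10)
print("top-10 most informative segment positions (sample index, importance):")
for idx, imp in top:
    print(f"  sample {idx:3d}  {imp:.4f}")
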