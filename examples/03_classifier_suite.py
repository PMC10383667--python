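"""Cross-validate several registry algorithms on one gene subset.

Every algorithm in the 23-entry registry answers the same contract: 10-fold
cross-validated accuracy on the training split, then confusion-matrix
metrics on the held-out test split.
"""

from ibdsig import (
    CONTROL_VS_IBD,
    SimulationConfig,
    correlation_screen,
    cross_validate,
    encode_labels,
    fit_and_evaluate,
    generate_study,
    get_spec,
    registry_list,
    split_train_test,
    top_q_filter,
)

study, _ = generate_study(SimulationConfig(
    n_samples=200, n_genes=150, n_informative=10, effect_size=1.5, seed=3))
y, kept = encode_labels(study, CONTROL_VS_IBD)
split = split_train_test(study, kept, seed=3)
pos = {k: i for i, k in enumerate(kept)}
y_tr = y[[pos[i] for i in split.train]]
y_te = y[[pos[i] for i in split.test]]
X_tr = study.expression[:, split.train]
X_te = study.expression[:, split.test]

subset = top_q_filter(correlation_screen(X_tr, y_tr), q=10)
print(f"registry holds {len(registry_list())} algorithms; evaluating 5 on "
      f"{len(subset)} genes\n")
print(f"{'algorithm':<22}{'cv_acc':>8}{'test_acc':>10}{'sens':>7}{'spec':>7}")
for key in ("bagged_trees", "linear_svm", "coarse_knn", "simple_tree", "subspace_knn"):
    spec = get_spec(key, seed=1)
    cv = cross_validate(spec, X_tr, y_tr, k_folds=10, seed=1, subset=subset)
    te = fit_and_evaluate(spec, subset, X_tr, y_tr, X_te, y_te, seed=1,
                          cv_accuracy=cv.cv_accuracy)
    print(f"{key:<22}{cv.cv_accuracy:>8.3f}{te.accuracy:>10.3f}"
          f"{te.sensitivity:>7.3f}{te.specificity:>7.3f}")

# Sensitivity is the true-positive rate on IBD samples (label 1), specificity
# the true-negative rate on controls; accuracy pools both.
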