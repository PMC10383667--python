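# Frozen default hyperparameters for the 23-algorithm registry.
# The names are the conventional point-and-click presets: Fine/Medium/Coarse
# KNN differ in k; Complex/Medium/Simple trees in the split budget; the
# Gaussian SVMs in kernel scale (multiples of sqrt(n_features)); ensembles
# use 30 learners. Retune here, not in code.
complex_tree:        {label: "Complex Tree",          max_splits: 100}
medium_tree:         {label: "Medium Tree",           max_splits: 20}
simple_tree:         {label: "Simple Tree",           max_splits: 4}
linear_discriminant: {label: "Linear Discriminant"}
quadratic_discriminant: {label: "Quadratic Discriminant", reg_param: 0.1}
logistic_regression: {label: "Logistic Regression",   max_iter: 1000}
linear_svm:          {label: "Linear SVM",            C: 1.0}
quadratic_svm:       {label: "Quadratic SVM",         C: 1.0, degree: 2}
cubic_svm:           {label: "Cubic SVM",             C: 1.0, degree: 3}
fine_gaussian_svm:   {label: "Fine Gaussian SVM",     C: 1.0, kernel_scale_factor: 0.25}
medium_gaussian_svm: {label: "Medium Gaussian SVM",   C: 1.0, kernel_scale_factor: 1.0}
coarse_gaussian_svm: {label: "Coarse Gaussian SVM",   C: 1.0, kernel_scale_factor: 4.0}
fine_knn:            {label: "Fine KNN",              k: 1}
medium_knn:          {label: "Medium KNN",            k: 10}
coarse_knn:          {label: "Coarse KNN",            k: 100}
cosine_knn:          {label: "Cosine KNN",            k: 10, metric: cosine}
cubic_knn:           {label: "Cubic KNN",             k: 10, minkowski_p: 3}
weighted_knn:        {label: "Weighted KNN",          k: 10, weights: distance}
boosted_trees:       {label: "Boosted Trees",         n_estimators: 30, max_splits: 20}
bagged_trees:        {label: "Bagged Trees",          n_estimators: 30}
subspace_discriminant: {label: "Subspace Discriminant", n_estimators: 30, subspace_fraction: 0.5}
subspace_knn:        {label: "Subspace KNN",          n_estimators: 30, subspace_fraction: 0.5, k: 1}
rusboosted_trees:    {label: "RUSBoosted Trees",      n_estimators: 30, max_splits: 20}
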