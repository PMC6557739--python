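"""Train an extreme learning machine and cross-validate it.

The ELM draws its hidden layer once at random and solves the output
weights in closed form (minimum-norm least squares).  With as many
hidden neurons as training samples it interpolates the training set;
with a small hidden layer it generalizes.
"""

import numpy as np

from scipso import kfold_cv_accuracy, predict, train_elm

rng = np.random.default_rng(0)
n = 40
X = rng.normal(size=(n, 4))
labels = np.repeat([1, 2], n // 2)
X[:, 0] += np.where(labels == 1, -2.0, 2.0)  # one informative feature

full = train_elm(X, labels, n_hidden=n, seed=1)
print("training accuracy with N_H = n (interpolation):",
      np.mean(predict(full, X) == labels))

res = kfold_cv_accuracy(X, labels, k=5, n_hidden=10, seed=1)
print(f"5-fold CV accuracy with N_H = 10: {res.mean_accuracy:.3f} "
      f"(folds: {[round(a, 2) for a in res.fold_accuracies]})")
# interpolation prints 1.0 by construction; the CV number is the honest
# estimate of out-of-sample accuracy and is what the pipeline optimizes
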