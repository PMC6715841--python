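"""Train SVM and CNN classifiers and trace an SVM learning curve.

Uses sampled populations of two species, trains both model kinds with
100 supervisor data per class, evaluates on 50 held-out cells per
class, then sweeps the number of supervisor data.
Run: python examples/04_train_and_learning_curve.py
"""

import crif
from crif.classify import evaluate, learning_curve, split_train_test, train_cnn, train_svm

cfg = crif.SpectralConfig()
signatures = crif.example_signatures(cfg)

a = crif.sample_catalog(signatures["pseudomonas_like"], 300, cv=0.1, seed=5, config=cfg)
b = crif.sample_catalog(signatures["paenibacillus_like"], 300, cv=0.1, seed=6, config=cfg)
pooled = crif.merge_catalogs([a, b])

train, test = split_train_test(pooled, n_train=100, n_test=50, seed=0)
svm = train_svm(train)
svm_acc, cm = evaluate(svm, test)
print(f"SVM held-out accuracy: {svm_acc:.3f}")
print(f"confusion matrix (rows=predicted, cols=true):\n{cm.counts}")

cnn = train_cnn(train, epochs=20, seed=0)
cnn_acc, _ = evaluate(cnn, test)
print(f"CNN held-out accuracy (20 epochs): {cnn_acc:.3f}")

curve = learning_curve(pooled, "svm", n_list=(2, 10, 50, 100), repeats=10, seed=1)
for n, m, s in zip(curve.n_train, curve.mean_accuracy, curve.sd_accuracy):
    print(f"  n_train={n:>3}: accuracy {m:.3f} +/- {s:.3f}")
# Accuracy rises with the number of supervisor data and saturates once
# the classes' signature difference dominates the within-class scatter.
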