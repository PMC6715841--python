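"""Supervised cell-type classification from innate fluorescence signatures.

Implements the study protocol: SVM (on 192-dimensional feature vectors)
and a 4-layer CNN (on the 6 x 32 matrices) trained with a varying
number of labeled cells ("supervisor data", 2-200), evaluated on 50
held-out cells per class, with learning curves averaged over
independently trained models and multi-class growth-stage confusion
matrices reported with per-class accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from sklearn.svm import SVC

from .catalog import HyperspectrumCatalog, merge_catalogs
from .nn import SmallCNN
from .spectra import feature_matrix, laplacian_filter


# ---------------------------------------------------------------------------
# containers


@dataclass
class ConfusionMatrix:
    """K x K counts with rows = predicted class, columns = true class."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape must match class count")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    def column_sums(self) -> np.ndarray:
        """Number of test instances per true class."""
        return self.counts.sum(axis=0)


def per_class_accuracy(cm: ConfusionMatrix, rounded: bool = False) -> dict[str, float]:
    """Diagonal count over true-class (column) total, per class.

    With ``rounded=True`` values are half-up rounded to 2 decimals for
    display (exact integer-ratio rounding, so e.g. 62/80 -> 0.78).
    """
    sums = cm.column_sums()
    if np.any(sums == 0):
        zero = [c for c, s in zip(cm.classes, sums) if s == 0]
        raise ValueError(f"no test instances for class(es) {zero}")
    out = {}
    for j, name in enumerate(cm.classes):
        if rounded:
            val = Decimal(int(cm.counts[j, j])) / Decimal(int(sums[j]))
            out[name] = float(val.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
        else:
            out[name] = float(cm.counts[j, j] / sums[j])
    return out


@dataclass
class ClassifierModel:
    """A trained SVM or CNN plus everything needed to reuse it coherently."""

    kind: str  # svm | cnn
    classes: list[str]  # lexicographic order
    feature_mode: str
    normalization: str
    n_train_per_class: int
    seed: int
    model: object
    metadata: dict = field(default_factory=dict)

    def _cnn_inputs(self, catalog: HyperspectrumCatalog) -> np.ndarray:
        mats = catalog.matrices().astype(float)
        if self.normalization == "max1":
            maxima = mats.reshape(len(mats), -1).max(axis=1)
            if np.any(maxima == 0):
                raise ValueError("cannot max-normalize an all-zero hyperspectrum")
            mats = mats / maxima[:, None, None]
        elif self.normalization == "sum1":
            sums = mats.reshape(len(mats), -1).sum(axis=1)
            mats = mats / sums[:, None, None]
        if self.feature_mode == "laplacian":
            mats = np.stack([laplacian_filter(m) for m in mats])
        return mats

    def predict(self, catalog: HyperspectrumCatalog) -> list[str]:
        if self.kind == "svm":
            X, _ = feature_matrix(catalog, self.feature_mode, self.normalization)
            return list(self.model.predict(X))
        idx = self.model.predict(self._cnn_inputs(catalog))
        return [self.classes[i] for i in idx]

    def predict_scores(self, catalog: HyperspectrumCatalog) -> np.ndarray:
        """(n, K) decision scores aligned with ``classes``."""
        if self.kind == "svm":
            X, _ = feature_matrix(catalog, self.feature_mode, self.normalization)
            df = self.model.decision_function(X)
            if df.ndim == 1:  # binary: expand to two columns
                return np.column_stack([-df, df])
            return df
        return self.model.predict_scores(self._cnn_inputs(catalog))


@dataclass
class LearningCurve:
    n_train: list[int]
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    repeats: int
    n_test: int
    kind: str = "svm"

    def __post_init__(self) -> None:
        self.mean_accuracy = np.asarray(self.mean_accuracy, dtype=float)
        self.sd_accuracy = np.asarray(self.sd_accuracy, dtype=float)
        if np.any(self.mean_accuracy < 0) or np.any(self.mean_accuracy > 1):
            raise ValueError("accuracies must lie in [0, 1]")
        if np.any(self.sd_accuracy < 0):
            raise ValueError("SDs must be non-negative")


# ---------------------------------------------------------------------------
# splitting


def _subset(catalog: HyperspectrumCatalog, idx: np.ndarray) -> HyperspectrumCatalog:
    entries = [catalog.entries[i] for i in idx]
    labels = [catalog.labels[i] for i in idx] if catalog.labels is not None else None
    return HyperspectrumCatalog(entries, labels, catalog.config, dict(catalog.provenance))


def split_train_test(
    catalog: HyperspectrumCatalog,
    n_train: int,
    n_test: int = 50,
    seed: int = 0,
    per_class: bool = True,
) -> tuple[HyperspectrumCatalog, HyperspectrumCatalog]:
    """Disjoint train/test draws without replacement, per class.

    ``n_train`` and ``n_test`` count cells per class (the held-out
    evaluation uses 50 per class by default).  Deterministic given
    ``seed``.
    """
    if catalog.labels is None:
        raise ValueError("split_train_test needs a labeled catalog")
    rng = np.random.default_rng(seed)
    labels = np.asarray(catalog.labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    if per_class:
        for cls in sorted(set(labels)):
            pool = np.flatnonzero(labels == cls)
            if len(pool) < n_train + n_test:
                raise ValueError(
                    f"class {cls!r} has {len(pool)} cells; needs n_train + n_test = {n_train + n_test}"
                )
            chosen = rng.choice(pool, size=n_train + n_test, replace=False)
            train_idx.extend(chosen[:n_train])
            test_idx.extend(chosen[n_train:])
    else:
        pool = np.arange(len(labels))
        if len(pool) < n_train + n_test:
            raise ValueError("population smaller than n_train + n_test")
        chosen = rng.choice(pool, size=n_train + n_test, replace=False)
        train_idx = list(chosen[:n_train])
        test_idx = list(chosen[n_train:])
    return _subset(catalog, np.array(sorted(train_idx))), _subset(catalog, np.array(sorted(test_idx)))


# ---------------------------------------------------------------------------
# training / evaluation


def train_svm(
    catalog: HyperspectrumCatalog,
    seed: int = 0,
    feature_mode: str = "laplacian",
    normalization: str = "max1",
    kernel: str = "rbf",
    C: float = 1.0,
) -> ClassifierModel:
    """Fit an RBF-kernel SVM on 192-dimensional feature vectors.

    gamma follows the usual variance scaling ('scale'); a linear kernel
    is available via ``kernel``.
    """
    X, labels = feature_matrix(catalog, feature_mode, normalization)
    if labels is None:
        raise ValueError("training catalog must be labeled")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training needs at least 2 classes")
    svc = SVC(kernel=kernel, C=C, gamma="scale", decision_function_shape="ovr")
    svc.fit(X, np.asarray(labels))
    n_per = min(labels.count(c) for c in classes)
    return ClassifierModel(
        "svm", classes, feature_mode, normalization, n_per, seed, svc,
        {"kernel": kernel, "C": C, "gamma": "scale"},
    )


def train_cnn(
    catalog: HyperspectrumCatalog,
    epochs: int = 100,
    steps_per_epoch: int = 100,
    seed: int = 0,
    feature_mode: str = "raw",
    normalization: str = "max1",
    batch_size: int = 10,
    lr: float = 1e-3,
) -> ClassifierModel:
    """Train the 4-layer CNN on 6 x 32 hyperspectrum matrices.

    The schedule is ``epochs`` epochs of ``steps_per_epoch`` minibatch
    training cycles (minibatches drawn with replacement, size 10).
    """
    if catalog.labels is None:
        raise ValueError("training catalog must be labeled")
    classes = sorted(set(catalog.labels))
    if len(classes) < 2:
        raise ValueError("training needs at least 2 classes")
    y = np.array([classes.index(l) for l in catalog.labels])
    net = SmallCNN(len(classes), seed=seed, lr=lr, batch_size=batch_size)
    model = ClassifierModel(
        "cnn", classes, feature_mode, normalization,
        min(list(catalog.labels).count(c) for c in classes), seed, net,
        {"epochs": epochs, "steps_per_epoch": steps_per_epoch,
         "batch_size": batch_size, "lr": lr},
    )
    if epochs > 0:
        net.fit(model._cnn_inputs(catalog), y, epochs=epochs, steps_per_epoch=steps_per_epoch)
    return model


def evaluate(model: ClassifierModel, test: HyperspectrumCatalog) -> tuple[float, ConfusionMatrix]:
    """Held-out accuracy and confusion matrix (rows = predicted, cols = true)."""
    if len(test) == 0:
        raise ValueError("empty test set")
    if test.labels is None:
        raise ValueError("test catalog must be labeled")
    predicted = model.predict(test)
    k = len(model.classes)
    index = {c: i for i, c in enumerate(model.classes)}
    counts = np.zeros((k, k), dtype=int)
    correct = 0
    for pred, true in zip(predicted, test.labels):
        if true not in index:
            raise ValueError(f"test label {true!r} unknown to the model")
        counts[index[pred], index[true]] += 1
        correct += pred == true
    return correct / len(test), ConfusionMatrix(counts, list(model.classes))


def _fit_kind(train: HyperspectrumCatalog, kind: str, seed: int, **kwargs) -> ClassifierModel:
    if kind == "svm":
        allowed = {k: v for k, v in kwargs.items()
                   if k in ("feature_mode", "normalization", "kernel", "C")}
        return train_svm(train, seed=seed, **allowed)
    if kind == "cnn":
        allowed = {k: v for k, v in kwargs.items()
                   if k in ("feature_mode", "normalization", "epochs",
                            "steps_per_epoch", "batch_size", "lr")}
        return train_cnn(train, seed=seed, **allowed)
    raise ValueError(f"unknown model kind {kind!r}")


def learning_curve(
    catalogs,
    kind: str = "svm",
    n_list: tuple[int, ...] = (2, 5, 10, 50, 100, 200),
    repeats: int = 100,
    n_test: int = 50,
    seed: int = 0,
    **model_kwargs,
) -> LearningCurve:
    """Mean +/- SD held-out accuracy vs number of supervisor data.

    For each n in ``n_list``, ``repeats`` models are trained on
    independent splits (distinct seeds derived from the root seed) and
    evaluated on ``n_test`` held-out cells per class.
    """
    catalog = merge_catalogs(list(catalogs)) if isinstance(catalogs, (list, tuple)) else catalogs
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(n_list) * repeats)
    means, sds = [], []
    for i, n in enumerate(n_list):
        accs = []
        for r in range(repeats):
            child = children[i * repeats + r]
            split_seed, model_seed = (int(s) for s in child.generate_state(2) % (2**31))
            train, test = split_train_test(catalog, n, n_test, seed=split_seed)
            model = _fit_kind(train, kind, model_seed, **model_kwargs)
            acc, _ = evaluate(model, test)
            accs.append(acc)
        means.append(np.mean(accs))
        sds.append(np.std(accs))
    return LearningCurve(list(n_list), np.array(means), np.array(sds), repeats, n_test, kind)


def multiclass_protocol(
    stage_catalogs: dict[str, HyperspectrumCatalog],
    kind: str = "svm",
    n_train: int = 100,
    n_test: int = 50,
    seed: int = 0,
    **model_kwargs,
) -> tuple[ConfusionMatrix, dict[str, float]]:
    """Joint multi-class (e.g. six growth stages) training and evaluation.

    One model is trained on all classes pooled; the confusion matrix
    uses the rows-predicted / columns-true convention and per-class
    accuracy is the diagonal over the column sum.
    """
    if len(stage_catalogs) < 2:
        raise ValueError("need at least 2 classes")
    pooled = merge_catalogs([cat.with_label(stage) for stage, cat in sorted(stage_catalogs.items())])
    ss = np.random.SeedSequence(seed)
    split_seed, model_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    train, test = split_train_test(pooled, n_train, n_test, seed=split_seed)
    model = _fit_kind(train, kind, model_seed, **model_kwargs)
    _, cm = evaluate(model, test)
    return cm, per_class_accuracy(cm)


def mixed_stage_protocol(
    species_stage_catalogs: dict[str, dict[str, HyperspectrumCatalog]],
    kind: str = "svm",
    n_train_per_stage: int = 50,
    n_test: int = 50,
    seed: int = 0,
    **model_kwargs,
) -> dict[str, float]:
    """Species classification robust to growth stage.

    Training pools all stages of each species; evaluation reports the
    two-class accuracy separately for each held-out stage, emulating a
    classifier that must work regardless of the physiological status of
    the test cells.  Returns stage -> accuracy.
    """
    species = sorted(species_stage_catalogs)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    stages = sorted(species_stage_catalogs[species[0]])
    for sp in species[1:]:
        if sorted(species_stage_catalogs[sp]) != stages:
            raise ValueError("all species must share the same stage keys")
    ss = np.random.SeedSequence(seed)
    train_parts = []
    test_parts: dict[str, list[HyperspectrumCatalog]] = {st: [] for st in stages}
    for sp in species:
        for st in stages:
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            cat = species_stage_catalogs[sp][st].with_label(sp)
            train, test = split_train_test(cat, n_train_per_stage, n_test, seed=child_seed)
            train_parts.append(train)
            test_parts[st].append(test)
    model_seed = int(ss.generate_state(1)[0] % (2**31))
    model = _fit_kind(merge_catalogs(train_parts), kind, model_seed, **model_kwargs)
    out = {}
    for st in stages:
        acc, _ = evaluate(model, merge_catalogs(test_parts[st]))
        out[st] = acc
    return out
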