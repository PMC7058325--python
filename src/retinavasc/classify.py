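"""Small CNN hypertension classifier and its cross-validation protocol.

The network is deliberately small to limit overfitting on modest cohorts:
five convolution stages (conv -> batch-norm -> ReLU -> max-pool), with the
fifth pooling stage being a global max pool over the final feature maps,
followed by two fully connected stages with dropout and a softmax over the
two classes.

The evaluation protocol is nested: records are randomly partitioned into
five equal folds; each fold serves once as the held-out test set while the
remaining four folds form the development set, which is itself split 75/25
into a training and a validation part. Augmentation (random crop from the
resize side down to the input side, horizontal/vertical flips, brightness
jitter) is applied to training images only; validation and test images are
resized to the input side and passed through unchanged.

When two images share a subject id (two eyes of one patient), grouping mode
keeps them in the same fold so no subject straddles the train/test boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._nn.layers import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Dense,
    Dropout,
    GlobalMaxPool,
    MaxPool2d,
    ReLU,
    softmax,
    softmax_cross_entropy,
)
from ._nn.network import Sequential
from .evaluate import POSITIVE, auc, confusion, metrics
from .exceptions import ConfigurationError, DataError, ModelError
from .preprocessing import resize_square
from .synthetic import FundusImage

N_CONV_STAGES = 5
N_DENSE_STAGES = 2


@dataclass
class ClassifierConfig:
    """Architecture and training hyper-parameters.

    ``pool_sizes`` has one entry per conv stage; the final entry must be 0,
    the sentinel for the global max pooling that replaces a spatial pool
    after the last convolution. ``epochs`` defaults to a desk-scale budget;
    300 (enhanced) / 500 (segmented) are the full-scale presets.
    """

    conv_filters: tuple = (16, 32, 64, 64, 64)
    kernel_sizes: tuple = (3, 3, 3, 3, 3)
    strides: tuple = (1, 1, 1, 1, 1)
    pool_sizes: tuple = (2, 2, 2, 2, 0)
    dense_units: tuple = (64, 2)
    dropout_rates: tuple = (0.5, 0.5)
    input_side: int = 224
    train_resize_side: int = 256
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    brightness_jitter: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("conv_filters", "kernel_sizes", "strides", "pool_sizes"):
            if len(getattr(self, name)) != N_CONV_STAGES:
                raise ConfigurationError(f"{name} must have {N_CONV_STAGES} entries")
        if len(self.dense_units) != N_DENSE_STAGES or len(self.dropout_rates) != N_DENSE_STAGES:
            raise ConfigurationError(
                f"dense_units and dropout_rates must have {N_DENSE_STAGES} entries"
            )
        if self.dense_units[-1] != 2:
            raise ConfigurationError("final dense stage must have 2 units (two classes)")
        if self.pool_sizes[-1] != 0:
            raise ConfigurationError(
                "last pool_sizes entry must be 0 (global max pooling stage)"
            )
        if not self.input_side < self.train_resize_side:
            raise ConfigurationError("input_side must be < train_resize_side")
        if any(not 0 <= r < 1 for r in self.dropout_rates):
            raise ConfigurationError("dropout rates must lie in [0, 1)")


def desk_config(**overrides) -> ClassifierConfig:
    """Desk-scale preset: smaller filters and sides for CPU-budget runs."""
    base = dict(
        conv_filters=(8, 12, 16, 16, 16),
        dense_units=(32, 2),
        dropout_rates=(0.1, 0.1),
        input_side=128,
        train_resize_side=144,
        epochs=12,
        batch_size=16,
        learning_rate=3e-3,
    )
    base.update(overrides)
    return ClassifierConfig(**base)


def build_cnn(config: ClassifierConfig) -> Sequential:
    """Assemble the network; ``net.gradcam_index`` marks the last conv ReLU."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    layers = []
    in_ch = 1
    final_relu_index = None
    for i in range(N_CONV_STAGES):
        layers.append(
            Conv2d(in_ch, config.conv_filters[i], config.kernel_sizes[i],
                   stride=config.strides[i], rng=rng)
        )
        layers.append(BatchNorm2d(config.conv_filters[i]))
        layers.append(ReLU())
        final_relu_index = len(layers) - 1
        if config.pool_sizes[i] > 1:
            layers.append(MaxPool2d(config.pool_sizes[i]))
        elif config.pool_sizes[i] == 0:
            layers.append(GlobalMaxPool())
        in_ch = config.conv_filters[i]
    dropout_rng = np.random.default_rng(config.seed + 1)
    layers.append(Dropout(config.dropout_rates[0], rng=dropout_rng))
    layers.append(Dense(config.conv_filters[-1], config.dense_units[0], rng=rng))
    layers.append(ReLU())
    layers.append(Dropout(config.dropout_rates[1], rng=dropout_rng))
    layers.append(Dense(config.dense_units[0], config.dense_units[1], rng=rng))
    net = Sequential(layers)
    net.gradcam_index = final_relu_index
    return net


def count_parameters(net: Sequential) -> int:
    return int(sum(p.size for p, _ in net.params()))


# ---------------------------------------------------------------------------
# fold planning


@dataclass
class FoldPlan:
    k: int
    n: int
    assignments: np.ndarray  # record index -> fold index
    folds: list = field(default_factory=list)  # dicts: test/dev/train/val arrays


def _stratified_take(groups_by_label, total_target, rng):
    """Pick groups per label (shuffled) until the per-label quota is met.

    Quotas follow largest-remainder apportionment of ``total_target`` over
    the label sizes, so the selection is class-balanced even at small n.
    """
    labels = sorted(groups_by_label)
    sizes = {lab: sum(len(g) for g in groups_by_label[lab]) for lab in labels}
    n = sum(sizes.values())
    raw = {lab: total_target * sizes[lab] / n for lab in labels}
    quota = {lab: int(np.floor(raw[lab])) for lab in labels}
    remainder = total_target - sum(quota.values())
    for lab in sorted(labels, key=lambda l: raw[l] - quota[l], reverse=True):
        if remainder <= 0:
            break
        quota[lab] += 1
        remainder -= 1
    picked = []
    for lab in labels:
        glist = [groups_by_label[lab][i] for i in rng.permutation(len(groups_by_label[lab]))]
        count = 0
        for group in glist:
            if count >= quota[lab]:
                break
            picked.extend(group)
            count += len(group)
    return np.sort(np.array(picked, dtype=int))


def make_fold_plan(labels, subjects=None, k: int = 5,
                   group_by_subject: bool = True, seed: int = 0,
                   val_fraction: float = 0.25) -> FoldPlan:
    """Nested k-fold plan with a 75/25 train/validation split per fold.

    The random partition is stratified by class (shuffled within class,
    dealt round-robin over folds) so every fold is evaluable; with grouping
    enabled, subject groups are balanced greedily per class instead and
    exact size parity is best-effort.
    """
    labels = np.asarray(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    if subjects is None or not group_by_subject:
        groups = [[i] for i in range(n)]
        subjects = None
    else:
        subjects = np.asarray(subjects)
        if subjects.size != n:
            raise DataError("subjects and labels length mismatch")
        by_subject = {}
        for i, s in enumerate(subjects):
            by_subject.setdefault(s, []).append(i)
        groups = list(by_subject.values())
    if k > len(groups):
        raise DataError(f"k={k} exceeds the number of groups ({len(groups)})")

    by_label = {}
    for group in groups:
        by_label.setdefault(labels[group[0]], []).append(group)

    assignments = np.empty(n, dtype=int)
    if subjects is None:
        # deal the per-class shuffles round-robin: overall fold sizes differ
        # by at most one and each class spreads evenly
        seq = []
        for lab in sorted(by_label):
            glist = by_label[lab]
            for i in rng.permutation(len(glist)):
                seq.append(glist[i][0])
        for pos, idx in enumerate(seq):
            assignments[idx] = pos % k
    else:
        sizes = np.zeros(k, dtype=int)
        for lab in sorted(by_label):
            glist = by_label[lab]
            shuffled = [glist[i] for i in rng.permutation(len(glist))]
            shuffled.sort(key=len, reverse=True)  # stable within equal sizes
            class_counts = np.zeros(k, dtype=int)
            for group in shuffled:
                # spread each class over folds first, balance sizes second
                f = min(range(k), key=lambda j: (class_counts[j], sizes[j]))
                class_counts[f] += 1
                sizes[f] += len(group)
                for idx in group:
                    assignments[idx] = f

    folds = []
    for f in range(k):
        test = np.flatnonzero(assignments == f)
        dev = np.flatnonzero(assignments != f)
        target_val = int(round(val_fraction * dev.size))
        dev_by_label = {}
        for i in dev:
            key = (labels[i], None if subjects is None else subjects[i])
            dev_by_label.setdefault(labels[i], {}).setdefault(key[1] or i, []).append(i)
        groups_by_label = {
            lab: list(members.values()) for lab, members in dev_by_label.items()
        }
        val = _stratified_take(groups_by_label, target_val, rng)
        train = np.sort(np.setdiff1d(dev, val))
        folds.append({"test": test, "dev": dev, "train": train, "val": val})
    return FoldPlan(k=k, n=n, assignments=assignments, folds=folds)


# ---------------------------------------------------------------------------
# augmentation


def augment(pixels: np.ndarray, config: ClassifierConfig, rng) -> np.ndarray:
    """Random crop to the input side, random flips, brightness jitter."""
    side = config.input_side
    h, w = pixels.shape
    if h < side or w < side:
        raise DataError("augment input smaller than the crop side")
    y0 = int(rng.integers(h - side + 1))
    x0 = int(rng.integers(w - side + 1))
    out = pixels[y0 : y0 + side, x0 : x0 + side]
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    factor = 1.0 + config.brightness_jitter * rng.uniform(-1.0, 1.0)
    return np.clip(out * factor, 0.0, 1.0)


# ---------------------------------------------------------------------------
# the estimator


def _image_pixels(obj) -> np.ndarray:
    if isinstance(obj, FundusImage) or hasattr(obj, "pixels"):
        return np.asarray(obj.pixels, dtype=np.float64)
    return np.asarray(obj, dtype=np.float64)


class CNNClassifier:
    """Scikit-learn style wrapper around the small CNN.

    Construct from a :class:`ClassifierConfig` (``from_config``) or with the
    equivalent keyword arguments. ``fit`` takes images of at least
    ``train_resize_side`` after internal resizing, a label per image, and
    optional subject ids for the grouped 75/25 development split.

    Fitted attributes: ``net_``, ``classes_``, ``history_`` (dict with
    per-epoch train and validation loss), ``train_indices_`` /
    ``val_indices_`` (the instrumented split, letting callers verify that
    validation images never pass through augmentation).
    """

    def __init__(self, **kwargs):
        config = kwargs.pop("config", None)
        if config is not None and kwargs:
            raise ConfigurationError("pass either config or keyword fields, not both")
        self.config = config or ClassifierConfig(**kwargs)

    @classmethod
    def from_config(cls, config: ClassifierConfig) -> "CNNClassifier":
        return cls(config=config)

    def get_params(self, deep=True):
        return dataclasses.asdict(self.config)

    def set_params(self, **params):
        self.config = dataclasses.replace(self.config, **params)
        return self

    # -- helpers -----------------------------------------------------------

    def _resized(self, X, side):
        out = []
        for img in X:
            px = _image_pixels(img)
            if px.shape != (side, side):
                px = resize_square(px, side)
            out.append(px)
        return out

    def _encode_labels(self, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise DataError("training split must contain exactly two classes")
        # order classes so that the positive class is column/index 1
        if POSITIVE in classes:
            classes = np.array([c for c in classes if c != POSITIVE] + [POSITIVE])
        self.classes_ = classes
        lookup = {c: i for i, c in enumerate(classes)}
        return np.array([lookup[v] for v in y], dtype=int)

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, subjects=None):
        cfg = self.config
        cfg.validate()
        y_enc = self._encode_labels(y)
        n = len(X)
        rng = np.random.default_rng(cfg.seed)

        # stratified (and optionally grouped) 75/25 train/validation split
        y_arr = np.asarray(y)
        groups_by_label: dict = {}
        if subjects is not None:
            subj = np.asarray(subjects)
            for i in range(n):
                groups_by_label.setdefault(y_arr[i], {}).setdefault(subj[i], []).append(i)
            groups_by_label = {lab: list(m.values()) for lab, m in groups_by_label.items()}
        else:
            for i in range(n):
                groups_by_label.setdefault(y_arr[i], []).append([i])
        val_idx = _stratified_take(groups_by_label, int(round(0.25 * n)), rng)
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        if np.unique(y_enc[train_idx]).size < 2:
            raise DataError("training split must contain exactly two classes")
        self.train_indices_ = train_idx
        self.val_indices_ = val_idx

        big = self._resized(X, cfg.train_resize_side)
        val_images = np.asarray(
            self._resized([X[i] for i in val_idx], cfg.input_side), dtype=np.float32
        )[:, None]
        val_labels = y_enc[val_idx]

        self.net_ = build_cnn(cfg)
        opt = Adam(self.net_.params(), lr=cfg.learning_rate)
        aug_rng = np.random.default_rng(cfg.seed + 2)
        self.history_ = {"train_loss": [], "val_loss": []}
        for _ in range(cfg.epochs):
            order = rng.permutation(train_idx.size)
            losses = []
            for start in range(0, train_idx.size, cfg.batch_size):
                batch = train_idx[order[start : start + cfg.batch_size]]
                xb = np.asarray(
                    [augment(big[i], cfg, aug_rng) for i in batch], dtype=np.float32
                )[:, None]
                logits = self.net_.forward(xb, train=True)
                loss, dlogits = softmax_cross_entropy(logits, y_enc[batch])
                self.net_.backward(dlogits)
                opt.step()
                losses.append(loss)
            self.history_["train_loss"].append(float(np.mean(losses)))
            if val_images.size:
                val_logits = self._forward_eval(val_images)
                val_loss, _ = softmax_cross_entropy(val_logits, val_labels)
            else:
                val_loss = float("nan")
            self.history_["val_loss"].append(val_loss)
        return self

    def _forward_eval(self, x, batch: int = 32):
        self._check_fitted()
        outs = []
        for start in range(0, x.shape[0], batch):
            outs.append(self.net_.forward(x[start : start + batch], train=False))
        return np.concatenate(outs, axis=0)

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise ModelError("classifier is not trained; call fit() first")

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X):
        """Class probabilities, columns ordered as ``classes_``."""
        imgs = np.asarray(
            self._resized(X, self.config.input_side), dtype=np.float32
        )[:, None]
        return softmax(self._forward_eval(imgs))

    def decision_scores(self, X) -> np.ndarray:
        """Per-image probability of the hypertension (positive) class."""
        proba = self.predict_proba(X)
        pos_col = int(np.flatnonzero(self.classes_ == POSITIVE)[0]) if POSITIVE in self.classes_ else 1
        return proba[:, pos_col]

    def predict(self, X, threshold: float = 0.5):
        scores = self.decision_scores(X)
        pos_col = int(np.flatnonzero(self.classes_ == POSITIVE)[0]) if POSITIVE in self.classes_ else 1
        neg_col = 1 - pos_col
        return np.where(scores >= threshold, self.classes_[pos_col], self.classes_[neg_col])


    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Weights as a single .npz plus a JSON sidecar with config/classes."""
        import hashlib
        import json
        from pathlib import Path

        self._check_fitted()
        path = Path(path)
        np.savez(path, **{f"arr_{i}": a for i, a in enumerate(self.net_.state())})
        npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
        sidecar = {
            "config": dataclasses.asdict(self.config),
            "classes": [str(c) for c in self.classes_],
            "weights_sha256": hashlib.sha256(npz_path.read_bytes()).hexdigest(),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "CNNClassifier":
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        payload = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in sidecar["config"].items()
        }
        model = cls(config=ClassifierConfig(**payload))
        model.net_ = build_cnn(model.config)
        model.classes_ = np.array(sidecar["classes"])
        npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
        with np.load(npz_path) as data:
            for i, arr in enumerate(model.net_.state()):
                arr[...] = data[f"arr_{i}"]
        return model


def train_classifier(images, labels, config: ClassifierConfig | None = None,
                     subjects=None) -> CNNClassifier:
    """Fit a classifier on a development set; returns the fitted estimator."""
    config = config or desk_config()
    return CNNClassifier.from_config(config).fit(images, labels, subjects=subjects)


def cross_validate(images, labels, subjects, config: ClassifierConfig,
                   plan: FoldPlan | None = None, k: int = 5,
                   group_by_subject: bool = True, threshold: float = 0.5):
    """Run the full nested k-fold protocol.

    Returns (fold_reports, fold_scores, models, plan); fold_scores are the
    held-out hypertension scores with their record indices, so downstream
    attribution can find the correctly classified test images.
    """
    labels = np.asarray(labels)
    if plan is None:
        plan = make_fold_plan(labels, subjects=subjects, k=k,
                              group_by_subject=group_by_subject, seed=config.seed)
    reports, fold_scores, models = [], [], []
    for f, fold in enumerate(plan.folds):
        fold_cfg = dataclasses.replace(config, seed=config.seed + 101 * f)
        dev = np.concatenate([fold["train"], fold["val"]])
        model = CNNClassifier.from_config(fold_cfg).fit(
            [images[i] for i in dev],
            labels[dev],
            subjects=None if subjects is None else np.asarray(subjects)[dev],
        )
        test = fold["test"]
        scores = model.decision_scores([images[i] for i in test])
        counts = confusion(scores, labels[test], threshold)
        reports.append(metrics(counts, auc_value=auc(scores, labels[test]), fold=f))
        fold_scores.append({"indices": test, "scores": scores, "labels": labels[test]})
        models.append(model)
    return reports, fold_scores, models, plan
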