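"""U-Net vessel segmentation: patch-trained, applied full-image.

The segmenter is an encoder-decoder network with skip connections trained
on square patches sampled from (image, mask) pairs — half of the patches
centred on vessel pixels so the foreground class is well represented — with
per-pixel binary cross-entropy. Inference runs the fully convolutional
network on the whole (reflect-padded) image, so no tiling seams appear.

Applying the trained model to an enhanced cohort yields the vessel-only
"segmented" variant of the dataset: binary images that retain nothing but
vascular morphology.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from ._nn.layers import Adam, bce_with_logits, sigmoid
from ._nn.network import UNet
from .exceptions import ConfigurationError, DataError, ModelError
from .synthetic import FundusImage


@dataclass
class SegmenterConfig:
    depth: int = 2
    base_filters: int = 8
    patch_side: int = 32
    patches_per_image: int = 24
    epochs: int = 12
    batch_size: int = 16
    learning_rate: float = 2e-3
    binarize_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if self.patch_side % (2**self.depth):
            raise ConfigurationError("patch_side must be divisible by 2**depth")
        if not 0 < self.binarize_threshold < 1:
            raise ConfigurationError("binarize_threshold must be in (0, 1)")


def _pixels(obj) -> np.ndarray:
    if isinstance(obj, FundusImage):
        return obj.pixels
    if hasattr(obj, "pixels"):
        return obj.pixels
    return np.asarray(obj)


class UNetSegmenter(BaseEstimator):
    """Scikit-learn style estimator wrapping the patch-trained U-Net.

    Parameters mirror :class:`SegmenterConfig`. Fitted attributes:

    net_ : the underlying network
    history_ : per-epoch mean training loss
    """

    def __init__(self, depth=2, base_filters=8, patch_side=32, patches_per_image=24,
                 epochs=12, batch_size=16, learning_rate=2e-3,
                 binarize_threshold=0.5, seed=0):
        self.depth = depth
        self.base_filters = base_filters
        self.patch_side = patch_side
        self.patches_per_image = patches_per_image
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.binarize_threshold = binarize_threshold
        self.seed = seed

    @classmethod
    def from_config(cls, config: SegmenterConfig) -> "UNetSegmenter":
        return cls(**dataclasses.asdict(config))

    def _config(self) -> SegmenterConfig:
        return SegmenterConfig(**{f.name: getattr(self, f.name)
                                  for f in dataclasses.fields(SegmenterConfig)})

    # -- training ----------------------------------------------------------

    def _sample_patches(self, images, masks, rng):
        """Patch bank: half vessel-centred, half uniform, over all pairs."""
        side = self.patch_side
        xs, ys = [], []
        for img, msk in zip(images, masks):
            h, w = img.shape
            if h < side or w < side:
                raise DataError(f"image {h}x{w} smaller than patch_side {side}")
            vr, vc = np.nonzero(msk)
            for j in range(self.patches_per_image):
                if j % 2 == 0 and vr.size:
                    k = rng.integers(vr.size)
                    cy = int(np.clip(vr[k] - side // 2, 0, h - side))
                    cx = int(np.clip(vc[k] - side // 2, 0, w - side))
                else:
                    cy = int(rng.integers(h - side + 1))
                    cx = int(rng.integers(w - side + 1))
                xs.append(img[cy : cy + side, cx : cx + side])
                ys.append(msk[cy : cy + side, cx : cx + side])
        x = np.asarray(xs, dtype=np.float32)[:, None]
        y = np.asarray(ys, dtype=np.float32)[:, None]
        return x, y

    def fit(self, X, y):
        """Train on (image, mask) pairs.

        X : sequence of 2-D float images in [0, 1]
        y : sequence of aligned binary masks
        """
        cfg = self._config()
        cfg.validate()
        images = [np.asarray(_pixels(i), dtype=np.float32) for i in X]
        masks = [np.asarray(_pixels(m)) for m in y]
        if not images:
            raise DataError("need at least one training pair")
        for img, msk in zip(images, masks):
            if img.shape != msk.shape:
                raise DataError("image and mask dimensions misaligned")
        rng = np.random.default_rng(self.seed)
        self.net_ = UNet(depth=self.depth, base_filters=self.base_filters,
                         seed=self.seed)
        opt = Adam(self.net_.params(), lr=self.learning_rate)
        px, py = self._sample_patches(images, masks, rng)
        n = px.shape[0]
        self.history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.net_.forward(px[idx], train=True)
                loss, dlogits = bce_with_logits(logits, py[idx])
                self.net_.backward(dlogits)
                opt.step()
                losses.append(loss)
            self.history_.append(float(np.mean(losses)))
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise ModelError("segmenter is not trained; call fit() first")

    def predict_proba_map(self, image) -> np.ndarray:
        """Per-pixel vessel probability, same shape as the input image."""
        self._check_fitted()
        img = np.asarray(_pixels(image), dtype=np.float32)
        h, w = img.shape
        mult = 2**self.depth
        ph = (-h) % mult
        pw = (-w) % mult
        padded = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
        logits = self.net_.forward(padded[None, None], train=False)
        return sigmoid(logits[0, 0, :h, :w]).astype(np.float64)

    def predict_map(self, image) -> np.ndarray:
        return (self.predict_proba_map(image) >= self.binarize_threshold).astype(np.uint8)

    def predict(self, X):
        return np.stack([self.predict_map(img) for img in X])

    def predict_proba(self, X):
        return np.stack([self.predict_proba_map(img) for img in X])

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Single-file .npz weights + JSON config sidecar (hash-addressed)."""
        self._check_fitted()
        path = Path(path)
        arrays = {f"arr_{i}": a for i, a in enumerate(self.net_.state())}
        np.savez(path, **arrays)
        blob = path.read_bytes() if path.suffix == ".npz" else Path(str(path) + ".npz").read_bytes()
        sidecar = {
            "config": dataclasses.asdict(self._config()),
            "weights_sha256": hashlib.sha256(blob).hexdigest(),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "UNetSegmenter":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        model = cls(**sidecar["config"])
        model.net_ = UNet(depth=model.depth, base_filters=model.base_filters,
                          seed=model.seed)
        npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
        with np.load(npz_path) as data:
            for i, arr in enumerate(model.net_.state()):
                arr[...] = data[f"arr_{i}"]
        model.history_ = []
        return model


def train_segmenter(pairs, config: SegmenterConfig | None = None) -> UNetSegmenter:
    """Train a segmenter on (FundusImage, VesselMask) pairs."""
    config = config or SegmenterConfig()
    images = [p[0] for p in pairs]
    masks = [p[1] for p in pairs]
    return UNetSegmenter.from_config(config).fit(images, masks)


def segment(model: UNetSegmenter, image) -> np.ndarray:
    """Vessel-probability map for one image."""
    return model.predict_proba_map(image)


def dice(pred, truth) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 when both are empty."""
    a = np.asarray(_pixels(pred)).astype(bool)
    b = np.asarray(_pixels(truth)).astype(bool)
    if a.shape != b.shape:
        raise DataError("shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def make_segmented_dataset(model: UNetSegmenter, cohort, threshold: float | None = None,
                           binarize: bool = True):
    """Vessel-only variant of a cohort (provenance = "segmented").

    Record count and labels pass through unchanged; each image becomes the
    model's segmentation, binarized at ``threshold`` by default (a
    probability-map passthrough is available with ``binarize=False``).
    """
    thr = model.binarize_threshold if threshold is None else threshold
    out = dataclasses.replace(cohort)
    out.records = []
    for rec in cohort.records:
        prob = model.predict_proba_map(rec.image)
        pixels = (prob >= thr).astype(np.float64) if binarize else prob
        image = FundusImage(pixels=pixels, label=rec.label,
                            subject_id=rec.subject_id, provenance="segmented")
        out.records.append(dataclasses.replace(rec, image=image))
    return out
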