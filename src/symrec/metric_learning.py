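"""Deep metric learning of recurrence-image embeddings.

A twin-branch ("Siamese") convolutional encoder — two identical branches with
shared weights — maps each 128×128 recurrence image to a 128-dimensional
embedding.  Training minimizes the contrastive loss

    L(d, y) = (1 − y)·½·d² + y·½·max(0, m − d)²

where d is the Euclidean distance between the two embeddings of a pair,
y = 0 for a same-class pair and y = 1 for a different-class pair, and
m is the margin (default 1.0).  Same-class pairs are pulled together and
different-class pairs pushed at least m apart, producing an embedding space
in which cognitive-status classes form separated clusters.

Architecture (fixed — it is part of the method): input 128×128×1 →
Conv 32×(3×3) ReLU → MaxPool 2×2 → Conv 64×(3×3) ReLU → MaxPool 2×2 →
Flatten → Dense 128 ReLU.  Optimized with Adam at learning rate 0.001.
The network is implemented in pure numpy (see ``symrec._nn``); one master
seed fans out to weight initialization, pair sampling and batch shuffling,
so training is reproducible on a fixed BLAS backend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import Adam, ConvEncoder

EMBED_DIM = 128
INPUT_HW = 128


@dataclass(frozen=True)
class EncoderSpec:
    """The fixed twin-branch architecture; deviations are rejected."""

    input_hw: int = INPUT_HW
    conv_filters: tuple[int, int] = (32, 64)
    kernel: int = 3
    pool: int = 2
    embed_dim: int = EMBED_DIM


@dataclass(frozen=True)
class PairSample:
    """Indices of two recurrence images plus the dissimilarity label.

    y = 0: both images share a class; y = 1: they differ.
    """

    index_a: int
    index_b: int
    y: int


@dataclass
class TrainConfig:
    """Contrastive-training hyperparameters.

    margin and learning_rate default to the method's stated values (1.0,
    0.001).  epochs/batch_size/pairs are artifact defaults: `n_pairs=None`
    means 4 × the number of training images.  Training stops early when the
    monitored loss — validation loss when a held-out pair set is supplied,
    training loss otherwise — fails to improve by `min_delta` for `patience`
    epochs, and the weights of the best monitored epoch are restored.  With
    tiny corpora the contrastive objective can memorize the training images
    within a few epochs, so monitoring held-out pairs is what keeps the
    embedding space generalizable.
    """

    margin: float = 1.0
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 20
    n_pairs: int | None = None
    patience: int = 3
    min_delta: float = 1e-4
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def contrastive_loss(d, y, m: float = 1.0):
    """Contrastive loss for distance d and dissimilarity label y (margin m).

    Accepts scalars or arrays; d must be non-negative.
    """
    d = np.asarray(d, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if m <= 0:
        raise ValueError("margin must be positive")
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    loss = (1.0 - y) * 0.5 * d**2 + y * 0.5 * np.maximum(0.0, m - d) ** 2
    return float(loss) if loss.ndim == 0 else loss


def generate_pairs(labels, n_pairs: int, seed: int = 0) -> list[PairSample]:
    """Sample a balanced list of same-class / different-class index pairs.

    Exactly ``n_pairs/2`` pairs get y=0 (same class, split as evenly as
    possible between the classes) and ``n_pairs/2`` get y=1.  Sampling is
    without replacement while enough distinct pairs exist, and never pairs an
    image with itself.  Reproducible under `seed`.
    """
    labels = np.asarray(labels)
    if n_pairs < 2 or n_pairs % 2:
        raise ValueError("n_pairs must be a positive even integer")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {list(classes)}")
    idx_by_class = [np.flatnonzero(labels == c) for c in classes]
    for c, idx in zip(classes, idx_by_class):
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 images; cannot form same-class pairs")
    rng = np.random.default_rng(seed)

    def _sample(candidates: np.ndarray, count: int) -> np.ndarray:
        if count <= len(candidates):
            pick = rng.choice(len(candidates), size=count, replace=False)
        else:
            pick = rng.choice(len(candidates), size=count, replace=True)
        return candidates[pick]

    n_same = n_pairs // 2
    quota = [n_same // 2 + (n_same % 2), n_same // 2]
    pairs: list[PairSample] = []
    for idx, q in zip(idx_by_class, quota):
        cand = np.array([(a, b) for i, a in enumerate(idx) for b in idx[i + 1 :]])
        for a, b in _sample(cand, q):
            pairs.append(PairSample(int(a), int(b), 0))
    cand = np.array([(a, b) for a in idx_by_class[0] for b in idx_by_class[1]])
    for a, b in _sample(cand, n_pairs - n_same):
        pairs.append(PairSample(int(a), int(b), 1))
    return pairs


def build_encoder(spec: EncoderSpec = EncoderSpec(), seed: int = 0) -> ConvEncoder:
    """Instantiate the encoder; the architecture is fixed by the method."""
    if spec != EncoderSpec():
        raise ValueError(f"encoder architecture is fixed; got deviating spec {spec}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return ConvEncoder(rng, input_hw=spec.input_hw, filters=spec.conv_filters,
                       embed_dim=spec.embed_dim)


def _pair_gradient(ea, eb, y, margin):
    """Loss value and dL/d(ea) for a batch of embedding pairs (mean reduction)."""
    diff = ea - eb
    d = np.sqrt(np.sum(diff * diff, axis=1))
    per = (1.0 - y) * 0.5 * d**2 + y * 0.5 * np.maximum(0.0, margin - d) ** 2
    # dL/dd: y=0 -> d;  y=1, d<m -> -(m-d);  else 0.  Chain through d.
    coef = np.where(
        y == 0, 1.0, np.where(d < margin, -(margin - d) / np.maximum(d, 1e-12), 0.0)
    )
    grad = (coef / len(d))[:, None] * diff
    return float(per.mean()), grad.astype(np.float32)


def _pair_loss(encoder, images, pairs: list[PairSample], margin: float) -> float:
    """Mean contrastive loss of `pairs` under the current encoder (no grad)."""
    idx = np.unique([i for p in pairs for i in (p.index_a, p.index_b)])
    emb = {int(i): e for i, e in zip(idx, embed(encoder, images[idx]))}
    d = np.array([
        np.linalg.norm(emb[p.index_a].astype(np.float64) - emb[p.index_b])
        for p in pairs
    ])
    y = np.array([p.y for p in pairs])
    return float(np.mean(contrastive_loss(d, y, margin)))


def train_siamese(images: np.ndarray, pairs: list[PairSample],
                  config: TrainConfig = TrainConfig(),
                  val_pairs: list[PairSample] | None = None):
    """Train the twin-branch encoder with contrastive loss.

    `images` is the (n, 128, 128) stack the pair indices refer to.  When
    `val_pairs` (indices into the same stack, disjoint images) is given,
    early stopping monitors the validation loss and the best-validation
    weights are restored; otherwise the training loss is monitored.  Returns
    ``(encoder, history)`` where history records the per-epoch mean training
    (and validation) loss plus the hyperparameters used.
    """
    if not pairs:
        raise ValueError("empty pair list")
    images = np.asarray(images, dtype=np.float32)
    ss = np.random.SeedSequence(config.seed).spawn(2)
    encoder = ConvEncoder(np.random.default_rng(ss[0]))
    shuffle_rng = np.random.default_rng(ss[1])
    opt = Adam(encoder.layers, lr=config.learning_rate)

    ia = np.array([p.index_a for p in pairs])
    ib = np.array([p.index_b for p in pairs])
    yy = np.array([p.y for p in pairs], dtype=np.float64)

    history = {
        "loss": [],
        "val_loss": [] if val_pairs else None,
        "margin": config.margin,
        "learning_rate": config.learning_rate,
        "batch_size": config.batch_size,
        "n_pairs": len(pairs),
    }
    best = np.inf
    best_weights = None
    stale = 0
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(pairs), config.batch_size):
            sel = order[start : start + config.batch_size]
            # forward each distinct image once; gradients accumulate per image,
            # which is algebraically identical to the naive two-branch pass
            uniq, inv = np.unique(np.concatenate([ia[sel], ib[sel]]), return_inverse=True)
            emb = encoder.forward(images[uniq], train=True)
            ea = emb[inv[: len(sel)]].astype(np.float64)
            eb = emb[inv[len(sel) :]].astype(np.float64)
            loss, ga = _pair_gradient(ea, eb, yy[sel], config.margin)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite contrastive loss at epoch {_epoch}: {loss}"
                )
            demb = np.zeros((len(uniq), encoder.embed_dim), dtype=np.float32)
            np.add.at(demb, inv[: len(sel)], ga)
            np.add.at(demb, inv[len(sel) :], -ga)
            encoder.backward(demb)
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history["loss"].append(epoch_loss)
        if val_pairs:
            monitored = _pair_loss(encoder, images, val_pairs, config.margin)
            history["val_loss"].append(monitored)
        else:
            monitored = epoch_loss
        if best - monitored > config.min_delta:
            best = monitored
            best_weights = encoder.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_weights is not None:
        encoder.set_weights(best_weights)
    return encoder, history


def embed(encoder: ConvEncoder, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Embed a stack of recurrence images; order preserved, deterministic."""
    images = np.asarray(images, dtype=np.float32)
    out = np.empty((images.shape[0], encoder.embed_dim), dtype=np.float32)
    for start in range(0, images.shape[0], batch_size):
        out[start : start + batch_size] = encoder.forward(images[start : start + batch_size])
    return out


def save_encoder(encoder: ConvEncoder, path: str | Path, config: TrainConfig | None = None,
                 fingerprint: str = "") -> None:
    """Checkpoint encoder weights plus a JSON of the training configuration."""
    path = Path(path)
    np.savez_compressed(path, **encoder.get_weights())
    meta = {"config": asdict(config) if config else None, "data_fingerprint": fingerprint}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_encoder(path: str | Path) -> ConvEncoder:
    data = np.load(Path(path).with_suffix(".npz"))
    encoder = ConvEncoder(np.random.default_rng(0))
    encoder.set_weights({k: data[k] for k in data.files})
    return encoder


class SiameseEncoder(TransformerMixin, BaseEstimator):
    """sklearn-style transformer learning the contrastive embedding space.

    fit(X, y) holds out a stratified `validation_fraction` of the labeled
    image stack X of shape (n, 128, 128), samples balanced pairs from the
    remaining images, and trains the twin-branch encoder with early stopping
    on the held-out pair loss (best-validation weights restored); transform(X)
    returns (n, 128) embeddings.

    Parameters mirror :class:`TrainConfig`; ``n_pairs=None`` uses 4 × the
    number of training images.  When a class is too small to spare two
    validation images, all images are used for training and the training
    loss is monitored instead.
    """

    def __init__(self, margin: float = 1.0, learning_rate: float = 0.001,
                 batch_size: int = 32, epochs: int = 20, n_pairs: int | None = None,
                 patience: int = 3, min_delta: float = 1e-4,
                 validation_fraction: float = 0.2, random_state: int = 0):
        self.margin = margin
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.n_pairs = n_pairs
        self.patience = patience
        self.min_delta = min_delta
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _split(self, y: np.ndarray, rng: np.random.Generator):
        """Stratified train/validation indices; no validation if too small."""
        train_idx, val_idx = [], []
        for c in self.classes_:
            idx = np.flatnonzero(y == c)
            n_val = int(round(self.validation_fraction * len(idx)))
            if n_val < 2 or len(idx) - n_val < 2:
                return np.arange(len(y)), np.array([], dtype=int)
            pick = rng.permutation(len(idx))
            val_idx.extend(idx[pick[:n_val]])
            train_idx.extend(idx[pick[n_val:]])
        return np.sort(train_idx), np.sort(val_idx)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        split_seed, pair_seed, val_seed, train_seed = (
            int(s) % (2**31)
            for s in np.random.SeedSequence(self.random_state).generate_state(4)
        )
        train_idx, val_idx = self._split(y, np.random.default_rng(split_seed))

        def remap(pairs, index):
            return [PairSample(int(index[p.index_a]), int(index[p.index_b]), p.y)
                    for p in pairs]

        n_pairs = self.n_pairs if self.n_pairs is not None else 4 * len(train_idx)
        n_pairs += n_pairs % 2
        pairs = remap(generate_pairs(y[train_idx], n_pairs, seed=pair_seed), train_idx)
        val_pairs = None
        if len(val_idx):
            n_val_pairs = 2 * len(val_idx) + (2 * len(val_idx)) % 2
            val_pairs = remap(
                generate_pairs(y[val_idx], n_val_pairs, seed=val_seed), val_idx
            )
        config = TrainConfig(
            margin=self.margin, learning_rate=self.learning_rate,
            batch_size=self.batch_size, epochs=self.epochs,
            patience=self.patience, min_delta=self.min_delta,
            validation_fraction=self.validation_fraction, seed=train_seed,
        )
        self.encoder_, self.history_ = train_siamese(X, pairs, config, val_pairs=val_pairs)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "encoder_"):
            raise RuntimeError("SiameseEncoder is not fitted")
        return embed(self.encoder_, np.asarray(X, dtype=np.float32))
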