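"""Image embeddings: convolutional features and triplet-loss fine-tuning.

Projection images are represented by the pooled penultimate features of a
convolutional backbone.  The ``tiny-cnn`` backbone (three conv blocks +
global average pool, seeded random weights, no downloads) is the default;
requesting a pretrained backbone (AlexNet, VGG-11, DenseNet, ResNet-18,
EfficientNet-B1/B7, ResNet-50) raises an explicit error directing to the
tiny-cnn fallback when its weights are not available locally.

Fine-tuning uses a Siamese triplet scheme: three weight-shared encoders
embed an anchor A, a positive P of the same particle class and a negative
N of a different class, and minimise

    L(A, P, N) = max(d(f(A), f(P)) - d(f(A), f(N)) + margin, 0)

with d the squared Euclidean distance (FaceNet convention; an unsquared
variant is available) and margin 0.5 by default.  The conv backbone stays
frozen; the trainable encoder head is three dense layers (512, 256, 256)
with ReLU + batch-norm on the first two, trained with Adam.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import Adam, BatchNorm, Dense, ReLU, Sequential
from .simulate import ProjectionSet

__all__ = [
    "PRETRAINED_BACKBONES",
    "BackboneUnavailableError",
    "TripletSpec",
    "SiameseConfig",
    "pretrained_embed",
    "generate_triples",
    "triplet_loss",
    "split_complexes",
    "train_siamese",
    "siamese_embed",
    "TinyCNNEmbedder",
    "SiameseEmbedder",
    "save_encoder",
    "load_encoder",
]

PRETRAINED_BACKBONES = (
    "alexnet", "vgg11", "densenet", "resnet18", "efficientnet-b1",
    "efficientnet-b7", "resnet50-pretrained",
)


class BackboneUnavailableError(RuntimeError):
    pass


@dataclass
class TripletSpec:
    """(anchor, positive, negative) index triples; label(A)=label(P)!=label(N)."""

    triples: list[tuple[int, int, int]]

    def __len__(self):
        return len(self.triples)

    def validate(self, labels) -> None:
        labels = np.asarray(labels)
        for a, p, n in self.triples:
            if a == p or labels[a] != labels[p] or labels[a] == labels[n]:
                raise ValueError(f"invalid triple ({a}, {p}, {n})")


@dataclass
class SiameseConfig:
    backbone: str = "tiny-cnn"
    head_dims: tuple = (512, 256, 256)
    margin: float = 0.5
    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 2
    freeze_until: str = "backbone"
    squared: bool = True
    l2_normalize: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _prep_images(images: np.ndarray) -> np.ndarray:
    """Per-image min-max scale to [0,1], replicate to 3 channels, centre."""
    images = np.asarray(images, dtype=float)
    lo = images.min(axis=(1, 2), keepdims=True)
    hi = images.max(axis=(1, 2), keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    x = (images - lo) / span
    x = np.repeat(x[..., None], 3, axis=-1)  # grayscale -> RGB
    return (x - 0.5) / 0.5


def _conv3x3(x: np.ndarray, K: np.ndarray) -> np.ndarray:
    # x: (B, H, W, Cin), K: (3, 3, Cin, Cout); same padding
    from numpy.lib.stride_tricks import sliding_window_view

    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (B,H,W,Cin,3,3)
    return np.einsum("bhwcij,ijcf->bhwf", win, K)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    B, H, W, C = x.shape
    x = x[:, : H - H % 2, : W - W % 2]
    return x.reshape(B, H // 2, 2, W // 2, 2, C).max(axis=(2, 4))


class TinyCNNEmbedder(BaseEstimator, TransformerMixin):
    """Frozen random-weight conv backbone: 3 conv blocks + global pooling.

    Produces a 32-d feature vector per image.  Weights are drawn once
    from ``random_state`` (He initialisation) and never trained, so the
    transform is deterministic.
    """

    feature_dim = 32

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y=None):
        rng = np.random.default_rng(self.random_state)
        chans = [3, 8, 16, 32]
        self.kernels_ = [
            rng.normal(0, np.sqrt(2.0 / (9 * cin)), size=(3, 3, cin, cout))
            for cin, cout in zip(chans[:-1], chans[1:])
        ]
        return self

    def transform(self, X) -> np.ndarray:
        images = X.images if isinstance(X, ProjectionSet) else np.asarray(X)
        if not hasattr(self, "kernels_"):
            self.fit(images)
        x = _prep_images(images)
        feats = []
        for s in range(0, len(x), 16):  # bounded memory
            h = x[s:s + 16]
            for i, K in enumerate(self.kernels_):
                h = np.maximum(_conv3x3(h, K), 0)
                if i < 2:
                    h = _maxpool2(h)
            feats.append(h.mean(axis=(1, 2)))
        return np.vstack(feats)


def pretrained_embed(
    ps, backbone: str = "tiny-cnn", seed: int = 0
) -> np.ndarray:
    """Penultimate pooled features of the requested backbone, one row per
    image.  Only ``tiny-cnn`` runs without downloaded weights."""
    if backbone == "tiny-cnn":
        return TinyCNNEmbedder(random_state=seed).fit_transform(ps)
    if backbone in PRETRAINED_BACKBONES:
        raise BackboneUnavailableError(
            f"pretrained weights for {backbone!r} are not available in this "
            "installation; use backbone='tiny-cnn' (seeded, no download) "
            "instead"
        )
    raise ValueError(f"unknown backbone {backbone!r}")


def generate_triples(
    labels, n_negatives: int = 10, mode: str = "random", seed: int = 0
) -> TripletSpec:
    """Triples from ground-truth classes.

    ``random``: for each unordered same-class pair, ``n_negatives``
    negatives drawn uniformly (with replacement) from the other classes.
    ``per_class``: one negative from each other class per pair.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = [c for c in np.unique(labels)]
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to form triples")
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    triples = []
    for c in classes:
        members = by_class[c]
        others = np.flatnonzero(labels != c)
        for a, p in combinations(members.tolist(), 2):
            if mode == "random":
                negs = rng.choice(others, size=n_negatives, replace=True)
            elif mode == "per_class":
                negs = [int(rng.choice(by_class[o])) for o in classes
                        if o != c]
            else:
                raise ValueError(f"unknown mode {mode!r}")
            triples.extend((a, p, int(nn)) for nn in negs)
    return TripletSpec(triples=triples)


def _pair_dist(e1: np.ndarray, e2: np.ndarray, squared: bool) -> np.ndarray:
    d2 = np.sum((e1 - e2) ** 2, axis=-1)
    return d2 if squared else np.sqrt(d2 + 1e-12)


def triplet_loss(eA, eP, eN, margin: float = 0.5,
                 squared: bool = True) -> float:
    """max(d(A,P) - d(A,N) + margin, 0), d = (squared) Euclidean distance."""
    eA, eP, eN = (np.asarray(e, dtype=float) for e in (eA, eP, eN))
    return float(
        np.maximum(
            _pair_dist(eA, eP, squared) - _pair_dist(eA, eN, squared)
            + margin, 0.0,
        ).mean()
    )


def split_complexes(labels, train_frac: float = 0.7, seed: int = 0):
    """Disjoint 70-30 split of the *classes* into train and test sets."""
    classes = sorted(np.unique(np.asarray(labels)).tolist())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(classes))
    n_train = int(round(train_frac * len(classes)))
    n_train = min(max(n_train, 1), len(classes) - 1)
    train = {classes[i] for i in order[:n_train]}
    test = {classes[i] for i in order[n_train:]}
    return train, test


class _Encoder:
    """Frozen conv backbone + trainable dense head + feature scaling."""

    def __init__(self, backbone: TinyCNNEmbedder, head: Sequential,
                 feat_mean, feat_std, l2_normalize: bool, image_shape):
        self.backbone = backbone
        self.head = head
        self.feat_mean = feat_mean
        self.feat_std = feat_std
        self.l2_normalize = l2_normalize
        self.image_shape = image_shape

    def features(self, images: np.ndarray) -> np.ndarray:
        f = self.backbone.transform(images)
        return (f - self.feat_mean) / self.feat_std

    def embed_features(self, feats: np.ndarray, training=False) -> np.ndarray:
        z = self.head.forward(feats, training=training)
        if self.l2_normalize:
            z = z / (np.linalg.norm(z, axis=1, keepdims=True) + 1e-12)
        return z

    def __call__(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images)
        if images.shape[1:] != self.image_shape:
            raise ValueError(
                f"image size {images.shape[1:]} differs from training size "
                f"{self.image_shape}"
            )
        return self.embed_features(self.features(images), training=False)


def _build_head(n_in: int, dims, rng) -> Sequential:
    layers = []
    for i, d in enumerate(dims):
        layers.append(Dense(n_in, d, rng))
        if i < len(dims) - 1:
            layers.append(ReLU())
            layers.append(BatchNorm(d))
        n_in = d
    return Sequential(layers)


def train_siamese(
    ps: ProjectionSet,
    triples: TripletSpec,
    cfg: SiameseConfig | None = None,
) -> tuple[_Encoder, dict]:
    """Train the triplet head; returns (encoder, per-epoch loss history).

    Triples are split 80-20 into train/validation.  Only the dense head
    is updated — all backbone layers (``freeze_until='backbone'``) stay
    frozen.  Aborts with diagnostics if the loss becomes NaN.
    """
    cfg = cfg or SiameseConfig()
    if len(triples) == 0:
        raise ValueError("empty triples")
    if cfg.backbone != "tiny-cnn":
        pretrained_embed(ps, cfg.backbone)  # raises with guidance
    rng = np.random.default_rng(cfg.seed)
    backbone = TinyCNNEmbedder(random_state=cfg.seed).fit(ps.images)
    raw = backbone.transform(ps.images)
    mean = raw.mean(axis=0)
    std = np.where(raw.std(axis=0) > 0, raw.std(axis=0), 1.0)
    encoder = _Encoder(backbone, _build_head(raw.shape[1], cfg.head_dims, rng),
                       mean, std, cfg.l2_normalize, ps.images.shape[1:])
    feats = (raw - mean) / std

    trip = np.asarray(triples.triples, dtype=int)
    order = rng.permutation(len(trip))
    n_val = int(round(0.2 * len(trip)))
    val, train = trip[order[:n_val]], trip[order[n_val:]]
    if len(train) == 0:
        train, val = val, train
    opt = Adam(encoder.head.params, lr=cfg.learning_rate)
    history = {"train_loss": [], "val_loss": []}

    def batch_loss_grad(batch, training):
        B = len(batch)
        x = feats[batch.reshape(-1)]  # (3B, d) as [A0,P0,N0,A1,...]
        z = encoder.head.forward(x, training=training)
        if cfg.l2_normalize:
            z = z / (np.linalg.norm(z, axis=1, keepdims=True) + 1e-12)
        zA, zP, zN = z[0::3], z[1::3], z[2::3]
        dAP = _pair_dist(zA, zP, cfg.squared)
        dAN = _pair_dist(zA, zN, cfg.squared)
        viol = dAP - dAN + cfg.margin
        active = viol > 0
        loss = float(np.maximum(viol, 0).mean())
        if not training:
            return loss, None
        gz = np.zeros_like(z)
        scale = active[:, None] / B
        if cfg.squared:
            gz[0::3] = scale * (2 * (zA - zP) - 2 * (zA - zN))
            gz[1::3] = scale * (-2 * (zA - zP))
            gz[2::3] = scale * (2 * (zA - zN))
        else:
            uAP = (zA - zP) / (dAP[:, None] + 1e-12)
            uAN = (zA - zN) / (dAN[:, None] + 1e-12)
            gz[0::3] = scale * (uAP - uAN)
            gz[1::3] = scale * (-uAP)
            gz[2::3] = scale * uAN
        return loss, gz

    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(train))
        losses = []
        for s in range(0, len(train), cfg.batch_size):
            batch = train[perm[s:s + cfg.batch_size]]
            loss, gz = batch_loss_grad(batch, training=True)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf triplet loss at epoch {epoch}, step {s}: "
                    f"lr={cfg.learning_rate}, margin={cfg.margin}"
                )
            encoder.head.backward(gz)
            opt.step(encoder.head.grads)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if len(val):
            history["val_loss"].append(batch_loss_grad(val, False)[0])
        else:
            history["val_loss"].append(float("nan"))
    return encoder, history


def siamese_embed(encoder: _Encoder, ps) -> np.ndarray:
    """n x 256 embedding matrix from a trained encoder (inference mode)."""
    images = ps.images if isinstance(ps, ProjectionSet) else np.asarray(ps)
    return encoder(images)


class SiameseEmbedder(BaseEstimator, TransformerMixin):
    """Estimator facade: ``fit(ProjectionSet-or-images, labels)`` trains
    the triplet head on the given class labels, ``transform`` embeds.

    Fitted attributes: ``encoder_``, ``history_`` (per-epoch train and
    validation triplet loss).
    """

    def __init__(
        self,
        margin: float = 0.5,
        learning_rate: float = 1e-4,
        epochs: int = 10,
        batch_size: int = 2,
        n_negatives: int = 10,
        triple_mode: str = "random",
        head_dims: tuple = (512, 256, 256),
        squared: bool = True,
        l2_normalize: bool = False,
        random_state: int = 0,
    ):
        self.margin = margin
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.n_negatives = n_negatives
        self.triple_mode = triple_mode
        self.head_dims = head_dims
        self.squared = squared
        self.l2_normalize = l2_normalize
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, ProjectionSet):
            ps = X
            y = ps.labels if y is None else y
        else:
            ps = ProjectionSet(images=np.asarray(X), labels=y)
        if y is None:
            raise ValueError("Siamese training requires class labels")
        triples = generate_triples(
            y, self.n_negatives, self.triple_mode, self.random_state
        )
        triples.validate(y)
        cfg = SiameseConfig(
            margin=self.margin,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            head_dims=self.head_dims,
            squared=self.squared,
            l2_normalize=self.l2_normalize,
            seed=self.random_state,
        )
        self.encoder_, self.history_ = train_siamese(ps, triples, cfg)
        return self

    def transform(self, X) -> np.ndarray:
        return siamese_embed(self.encoder_, X)


def save_encoder(path, encoder: _Encoder) -> None:
    state = {
        "kernels": encoder.backbone.kernels_,
        "seed": encoder.backbone.random_state,
        "head_state": encoder.head.state(),
        "head_dims": [l.W.shape for l in encoder.head.layers
                      if isinstance(l, Dense)],
        "feat_mean": encoder.feat_mean,
        "feat_std": encoder.feat_std,
        "l2_normalize": encoder.l2_normalize,
        "image_shape": encoder.image_shape,
    }
    Path(path).write_bytes(pickle.dumps(state))


def load_encoder(path) -> _Encoder:
    state = pickle.loads(Path(path).read_bytes())
    backbone = TinyCNNEmbedder(random_state=state["seed"])
    backbone.kernels_ = state["kernels"]
    rng = np.random.default_rng(0)
    dims = [shape[1] for shape in state["head_dims"]]
    head = _build_head(state["head_dims"][0][0], dims, rng)
    head.load_state(state["head_state"])
    enc = _Encoder(backbone, head, state["feat_mean"], state["feat_std"],
                   state["l2_normalize"], tuple(state["image_shape"]))
    return enc
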