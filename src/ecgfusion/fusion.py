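"""Feature fusion, the hybrid classifier, training and k-fold evaluation.

The hybrid model runs each image through two branches — the residual
network (feature vector from the global average pool) and the slim-stem
transformer (flattened last hidden states through a dense reduction to
the same width) — concatenates the two equal-length vectors, and
classifies through a hidden dense layer with dropout and a softmax
output. Both branches and the head train jointly with Adam on
categorical cross-entropy; a ``freeze_resnet`` flag supports staged
training of the transformer branch against fixed residual features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .hvit import EncoderConfig, HViTEncoder, ViTFeatureHead
from .io import LabeledImageSet
from .metrics import MetricsReport, compute_metrics
from .nn import Adam, Dense, Dropout, Layer, ReLU, Sequential, softmax, softmax_cross_entropy
from .resnet import ResNetConfig, ResNetFeatureExtractor
from .slim import SlimConfig, SlimStem

__all__ = [
    "FusionConfig", "TrainConfig", "HybridModelConfig", "HybridModel",
    "build_hybrid_model", "reduced_model_config", "fuse_predict",
    "train", "kfold_evaluate",
]


@dataclass
class FusionConfig:
    hidden_sizes: list[int] = field(default_factory=lambda: [256])
    dropout: float = 0.35
    n_classes: int = 12
    activation: str = "relu"


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0
    weight_decay: float = 0.0
    freeze_resnet: bool = False

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")


@dataclass
class HybridModelConfig:
    """Joint configuration of both branches and the fusion head."""

    input_size: int = 224
    in_channels: int = 3
    slim: SlimConfig | None = None
    encoder: EncoderConfig | None = None
    resnet: ResNetConfig | None = None
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def resolve(self) -> tuple[SlimConfig, EncoderConfig, ResNetConfig]:
        slim = self.slim or SlimConfig(input_size=self.input_size,
                                       in_channels=self.in_channels)
        n_patches = (slim.input_size // 16) ** 2
        enc = self.encoder or EncoderConfig(embed_dim=slim.final_channels,
                                            n_patches=n_patches)
        res = self.resnet or ResNetConfig(input_size=self.input_size,
                                          in_channels=self.in_channels)
        if enc.embed_dim != slim.final_channels:
            raise ValueError("encoder embed_dim must equal slim final_channels")
        if enc.n_patches != n_patches:
            raise ValueError("encoder n_patches must match the slim output grid")
        if slim.input_size != res.input_size or self.input_size != slim.input_size:
            raise ValueError("branch input sizes must agree")
        return slim, enc, res


def reduced_model_config(input_size: int = 48, n_classes: int = 12) -> HybridModelConfig:
    """A narrow configuration for desk-scale experiments: same topology,
    small widths, shallow (reference-4 minus 2 = 2 layer) encoder."""
    slim = SlimConfig(stage_channels=[8, 12, 16, 24], final_channels=48,
                      input_size=input_size, in_channels=1, se_reduction=4)
    enc = EncoderConfig(reference_depth=4, embed_dim=48, heads=4,
                        mlp_ratio=2.0, n_patches=(input_size // 16) ** 2)
    res = ResNetConfig(initial_filters=8, blocks_per_stage=[1, 1, 1, 1],
                       input_size=input_size, in_channels=1)
    fusion = FusionConfig(hidden_sizes=[48], dropout=0.1, n_classes=n_classes)
    return HybridModelConfig(input_size=input_size, in_channels=1,
                             slim=slim, encoder=enc, resnet=res, fusion=fusion)


class HybridModel(Layer):
    """Two-branch feature extractor plus fusion classification head."""

    def __init__(self, cfg: HybridModelConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg = cfg or HybridModelConfig()
        rng = rng or np.random.default_rng(0)
        slim_cfg, enc_cfg, res_cfg = cfg.resolve()
        self.stem = SlimStem(slim_cfg, rng=rng)
        self.encoder = HViTEncoder(enc_cfg, rng=rng)
        self.resnet = ResNetFeatureExtractor(res_cfg, rng=rng)
        d_res = self.resnet.feature_dim
        self.vit_head = ViTFeatureHead(enc_cfg.n_patches, enc_cfg.embed_dim,
                                       d_res, rng=rng)
        # build-time parity contract: equal halves in the concatenation
        assert self.vit_head.d_out == d_res
        self.feature_dim = d_res
        layers: list[Layer] = []
        width = 2 * d_res
        for h in cfg.fusion.hidden_sizes:
            layers += [Dense(width, h, rng=rng), ReLU(),
                       Dropout(cfg.fusion.dropout, rng=rng)]
            width = h
        layers.append(Dense(width, cfg.fusion.n_classes, rng=rng))
        self.head = Sequential(*layers)
        self.freeze_resnet = False

    def params(self):
        ps = (self.stem.params() + self.encoder.params()
              + self.vit_head.params() + self.head.params())
        if not self.freeze_resnet:
            ps = self.resnet.params() + ps
        return ps

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Concatenated (f_resnet, f_vit) feature batch: (N, 2*D)."""
        f_res = self.resnet.forward(x, train)
        h = self.encoder.forward(self.stem.forward(x, train), train)
        f_vit = self.vit_head.forward(h, train)
        return np.concatenate([f_res, f_vit], axis=1)

    def forward(self, x, train=False):
        return self.head.forward(self.features(x, train), train)

    def backward(self, dlogits):
        dfeat = self.head.backward(dlogits)
        d = self.feature_dim
        df_res, df_vit = dfeat[:, :d], dfeat[:, d:]
        dh = self.vit_head.backward(df_vit)
        dfmap = self.encoder.backward(dh)
        dx = self.stem.backward(dfmap)
        if not self.freeze_resnet:
            dx = dx + self.resnet.backward(df_res)
        return dx

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False), axis=-1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        # argmax ties break toward the lower class index
        return self.predict_proba(x).argmax(axis=1)


def build_hybrid_model(cfg: HybridModelConfig | None = None,
                       seed: int = 0) -> HybridModel:
    return HybridModel(cfg, rng=np.random.default_rng(seed))


def fuse_predict(f_res: np.ndarray, f_vit: np.ndarray, head: Sequential) -> np.ndarray:
    """Softmax class probabilities from the two feature vectors."""
    f_res = np.asarray(f_res, dtype=float).ravel()
    f_vit = np.asarray(f_vit, dtype=float).ravel()
    if f_res.shape != f_vit.shape:
        raise ValueError(
            f"feature halves must have equal length "
            f"({f_res.shape[0]} vs {f_vit.shape[0]}): branch parity is a "
            f"build-time contract")
    z = np.concatenate([f_res, f_vit])[None]
    return softmax(head.forward(z), axis=-1)[0]


def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train(model: HybridModel, dataset: LabeledImageSet,
          cfg: TrainConfig | None = None) -> dict:
    """Train in place; returns a history of per-epoch loss and accuracy."""
    cfg = cfg or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if len(np.unique(dataset.labels)) < 2:
        raise ValueError("training needs at least two classes")
    x = dataset.images.transpose(0, 3, 1, 2)
    y = dataset.labels
    model.freeze_resnet = cfg.freeze_resnet
    rng = np.random.default_rng(cfg.seed)
    # re-seed dropout so training is reproducible for a given seed
    for layer in _iter_dropout(model):
        layer.rng = np.random.default_rng(rng.integers(2 ** 31 - 1))
    opt = Adam(model.params(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    history = {"loss": [], "accuracy": []}
    for _epoch in range(cfg.epochs):
        losses, hits, seen = [], 0, 0
        for idx in _as_batches(len(y), cfg.batch_size, rng):
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {_epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == yb).sum())
            seen += len(yb)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(hits / seen)
    return history


def _iter_dropout(layer: Layer):
    if isinstance(layer, Dropout):
        yield layer
    for attr in vars(layer).values() if hasattr(layer, "__dict__") else []:
        if isinstance(attr, Layer):
            yield from _iter_dropout(attr)
        elif isinstance(attr, list):
            for a in attr:
                if isinstance(a, Layer):
                    yield from _iter_dropout(a)


def kfold_evaluate(dataset: LabeledImageSet, model_builder,
                   cfg: TrainConfig | None = None, k: int = 10,
                   seed: int = 0) -> tuple[list[MetricsReport], pd.DataFrame]:
    """Stratified k-fold cross-validation with per-fold re-initialization.

    ``model_builder(seed)`` must return a fresh model. Returns one
    metrics report per fold plus the class x fold table of one-vs-rest
    per-class accuracies.
    """
    cfg = cfg or TrainConfig()
    y = dataset.labels
    counts = np.bincount(y, minlength=len(dataset.class_names))
    for ci, c in enumerate(counts):
        if 0 < c < k:
            raise ValueError(
                f"class {dataset.class_names[ci]!r} has {c} samples, "
                f"fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    table = np.zeros((len(dataset.class_names), k))
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = model_builder(seed + fold)
        sub = LabeledImageSet(images=dataset.images[tr], labels=y[tr],
                              class_names=dataset.class_names)
        fold_cfg = TrainConfig(**{**vars(cfg), "seed": cfg.seed + fold})
        train(model, sub, fold_cfg)
        xt = dataset.images[te].transpose(0, 3, 1, 2)
        probs = model.predict_proba(xt)
        rep = compute_metrics(y[te], probs.argmax(axis=1), probs,
                              class_names=dataset.class_names, fold_id=fold)
        reports.append(rep)
        table[:, fold] = [m.accuracy for m in rep.per_class]
    frame = pd.DataFrame(table, index=dataset.class_names,
                         columns=[f"fold_{i + 1}" for i in range(k)])
    return reports, frame
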