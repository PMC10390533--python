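"""Backbone, embedder and classifier for cell-death phenotype prediction.

The model has three serial parts: a convolutional backbone mapping a
4-channel crop to a feature vector, an embedder (fully connected stack)
mapping features to a low-dimensional embedding that the supervised
contrastive loss consumes after L2 normalisation, and a 3-node classifier
head trained with cross-entropy on the pre-normalisation embedding.

Backbones are pluggable through a registry. The shipped "tiny-cnn"
(three stride-2 conv blocks, feature_dim 64) trains from scratch on a CPU
and is what the tests and synthetic experiments use; an ImageNet-pretrained
backbone such as EfficientNet-b0 can be registered by the caller, with
:func:`adapt_first_layer` converting its RGB first-layer kernel to the
4-channel cell-painting input.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import nn


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "tiny-cnn"
    feature_dim: int = 64
    pretrained: bool = False
    input_channels: int = 4

    def __post_init__(self) -> None:
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")


@dataclass(frozen=True)
class HeadSpec:
    embedder_widths: tuple[int, ...] = (512, 128)
    classifier_widths: tuple[int, ...] = (64,)
    n_classes: int = 3
    l2_normalize_embedding: bool = True

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")

    @property
    def embedding_dim(self) -> int:
        return self.embedder_widths[-1]


def _build_tiny_cnn(
    spec: BackboneSpec, rng: np.random.Generator, frozen_batchnorm: bool
) -> nn.Sequential:
    c = spec.input_channels
    widths = (16, 32, spec.feature_dim)
    layers: list[nn.Layer] = []
    cin = c
    for w in widths:
        layers += [
            nn.Conv2d(cin, w, kernel_size=3, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(w, frozen=frozen_batchnorm),
            nn.ReLU(),
        ]
        cin = w
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers)


BackboneBuilder = Callable[[BackboneSpec, np.random.Generator, bool], nn.Layer]

_BACKBONES: dict[str, BackboneBuilder] = {"tiny-cnn": _build_tiny_cnn}


def register_backbone(name: str, builder: BackboneBuilder) -> None:
    """Register an additional backbone builder (e.g. a pretrained network)."""
    _BACKBONES[name] = builder


def adapt_first_layer(kernel_3ch: np.ndarray) -> np.ndarray:
    """Adapt an RGB first-layer conv kernel to 4-channel input.

    Channels 0-2 are copied verbatim; the fourth channel receives the
    element-wise mean of the three. Applied to an input whose fourth channel
    is all zero, the adapted convolution reproduces the original 3-channel
    convolution exactly.
    """
    kernel_3ch = np.asarray(kernel_3ch)
    if kernel_3ch.ndim != 4 or kernel_3ch.shape[1] != 3:
        raise ValueError(f"expected (out, 3, kh, kw) kernel, got shape {kernel_3ch.shape}")
    fourth = kernel_3ch.mean(axis=1, keepdims=True)
    return np.concatenate([kernel_3ch, fourth], axis=1)


def _build_mlp(
    in_dim: int, widths: tuple[int, ...], rng: np.random.Generator
) -> nn.Sequential:
    layers: list[nn.Layer] = []
    cur = in_dim
    for i, w in enumerate(widths):
        if i > 0:
            layers.append(nn.ReLU())
        layers.append(nn.Linear(cur, w, rng=rng))
        cur = w
    return nn.Sequential(*layers)


@dataclass
class ModelOutput:
    features: np.ndarray  # (N, feature_dim)
    embedding: np.ndarray  # (N, embedding_dim), pre-normalisation
    z: np.ndarray  # (N, embedding_dim), L2-normalised (== embedding if disabled)
    logits: np.ndarray  # (N, n_classes)


class PhenotypeModel:
    """backbone -> embedder -> {L2-normalised embedding, classifier logits}."""

    def __init__(
        self,
        backbone_spec: BackboneSpec,
        head_spec: HeadSpec,
        seed: int = 0,
        frozen_batchnorm: bool = True,
    ) -> None:
        if backbone_spec.name not in _BACKBONES:
            raise KeyError(
                f"backbone {backbone_spec.name!r} is not registered; available: "
                f"{sorted(_BACKBONES)}. Pretrained backbones must be supplied via "
                "register_backbone()."
            )
        rng = np.random.default_rng(seed)
        self.backbone_spec = backbone_spec
        self.head_spec = head_spec
        self.frozen_batchnorm = frozen_batchnorm
        self.backbone = _BACKBONES[backbone_spec.name](backbone_spec, rng, frozen_batchnorm)
        self.embedder = _build_mlp(backbone_spec.feature_dim, head_spec.embedder_widths, rng)
        # classifier consumes the pre-normalisation embedder output
        self.classifier = _build_mlp(
            head_spec.embedding_dim, head_spec.classifier_widths + (head_spec.n_classes,), rng
        )
        self._norm_cache: tuple | None = None

    # -- core passes -----------------------------------------------------
    def params(self) -> list[nn.Param]:
        return self.backbone.params() + self.embedder.params() + self.classifier.params()

    def forward(self, images: np.ndarray, train: bool = False) -> ModelOutput:
        if images.ndim != 4 or images.shape[1] != self.backbone_spec.input_channels:
            raise ValueError(
                f"expected (N, {self.backbone_spec.input_channels}, s, s) images, "
                f"got shape {images.shape}"
            )
        feats = self.backbone.forward(images, train=train)
        emb = self.embedder.forward(feats, train=train)
        if self.head_spec.l2_normalize_embedding:
            z, norms = nn.l2_normalize(emb)
        else:
            z, norms = emb, np.ones((emb.shape[0], 1), dtype=emb.dtype)
        logits = self.classifier.forward(emb, train=train)
        if train:
            self._norm_cache = (emb, z, norms)
        return ModelOutput(features=feats, embedding=emb, z=z, logits=logits)

    def backward(self, d_logits: np.ndarray, d_z: np.ndarray | None = None) -> None:
        assert self._norm_cache is not None, "backward before forward(train=True)"
        emb, z, norms = self._norm_cache
        self._norm_cache = None
        d_emb = self.classifier.backward(d_logits)
        if d_z is not None:
            if self.head_spec.l2_normalize_embedding:
                d_emb = d_emb + nn.l2_normalize_backward(emb, z, norms, d_z)
            else:
                d_emb = d_emb + d_z
        d_feat = self.embedder.backward(d_emb)
        self.backbone.backward(d_feat)

    # -- state -----------------------------------------------------------
    def _iter_layers(self):
        for seq in (self.backbone, self.embedder, self.classifier):
            if isinstance(seq, nn.Sequential):
                yield from seq.layers
            else:
                yield seq

    def state_arrays(self) -> list[np.ndarray]:
        arrays: list[np.ndarray] = []
        for layer in self._iter_layers():
            for p in _layer_state(layer):
                arrays.append(p)
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model needs {len(own)}")
        it = iter(arrays)
        for layer in self._iter_layers():
            _set_layer_state(layer, it)


def _layer_state(layer: nn.Layer) -> list[np.ndarray]:
    if isinstance(layer, (nn.Conv2d, nn.Linear)):
        return [layer.weight.value, layer.bias.value]
    if isinstance(layer, nn.BatchNorm2d):
        return [layer.gamma.value, layer.beta.value, layer.running_mean, layer.running_var]
    return []


def _set_layer_state(layer: nn.Layer, it) -> None:
    if isinstance(layer, (nn.Conv2d, nn.Linear)):
        layer.weight.value = next(it).copy()
        layer.bias.value = next(it).copy()
        layer.weight.grad = np.zeros_like(layer.weight.value)
        layer.bias.grad = np.zeros_like(layer.bias.value)
    elif isinstance(layer, nn.BatchNorm2d):
        layer.gamma.value = next(it).copy()
        layer.beta.value = next(it).copy()
        layer.running_mean = next(it).copy()
        layer.running_var = next(it).copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def embed(model: PhenotypeModel, images: np.ndarray) -> np.ndarray:
    """Eval-mode embeddings; unit row norm when L2 normalisation is on."""
    return model.forward(images, train=False).z


def classify(model: PhenotypeModel, embeddings: np.ndarray) -> np.ndarray:
    """Logits of the classifier head on (pre-normalisation) embeddings."""
    if embeddings.shape[1] != model.head_spec.embedding_dim:
        raise ValueError(
            f"expected embedding dim {model.head_spec.embedding_dim}, got {embeddings.shape[1]}"
        )
    return model.classifier.forward(embeddings, train=False)


def save_checkpoint(model: PhenotypeModel, path: str | Path, extra: dict | None = None) -> None:
    """Persist model weights plus the specs needed to rebuild it."""
    meta = {
        "backbone_spec": vars(model.backbone_spec)
        | {"name": model.backbone_spec.name},
        "head_spec": {
            "embedder_widths": list(model.head_spec.embedder_widths),
            "classifier_widths": list(model.head_spec.classifier_widths),
            "n_classes": model.head_spec.n_classes,
            "l2_normalize_embedding": model.head_spec.l2_normalize_embedding,
        },
        "frozen_batchnorm": model.frozen_batchnorm,
        "extra": extra or {},
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[PhenotypeModel, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        n = sum(1 for k in data.files if k.startswith("arr_"))
        arrays = [data[f"arr_{i}"] for i in range(n)]
    bspec = BackboneSpec(
        name=meta["backbone_spec"]["name"],
        feature_dim=meta["backbone_spec"]["feature_dim"],
        pretrained=meta["backbone_spec"]["pretrained"],
        input_channels=meta["backbone_spec"]["input_channels"],
    )
    hspec = HeadSpec(
        embedder_widths=tuple(meta["head_spec"]["embedder_widths"]),
        classifier_widths=tuple(meta["head_spec"]["classifier_widths"]),
        n_classes=meta["head_spec"]["n_classes"],
        l2_normalize_embedding=meta["head_spec"]["l2_normalize_embedding"],
    )
    model = PhenotypeModel(bspec, hspec, seed=0, frozen_batchnorm=meta["frozen_batchnorm"])
    model.load_state_arrays(arrays)
    return model, meta.get("extra", {})
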