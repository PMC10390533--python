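"""Training and evaluation of the cell-death phenotype classifier.

Training minimises lambda1 * L_sup + lambda2 * L_ce over batches composed
by the batch-aware sampler; each sampled field contributes one of its five
crops with stochastic augmentation. Evaluation is deterministic: per field,
class probabilities are averaged over the five crops, and wells are labelled
by majority voting over their fields. A k-NN cosine retrieval over training
embeddings and a plate-mixing diagnostic (fraction of nearest neighbours
from the sample's own plate) complete the toolkit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

from .augmentation import AugmentConfig, augment, five_crop
from .batch_sampler import SamplerConfig, make_batches
from .core_data import CLASS_LABELS, ExperimentManifest, ImageRecord, read_field_image
from .network import PhenotypeModel, softmax
from .objectives import EmbeddingBatch, LossConfig, cross_entropy, supcon_loss_and_grad

logger = logging.getLogger(__name__)

_LABEL_TO_INT = {c: i for i, c in enumerate(CLASS_LABELS)}


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1.25e-5
    epochs: int = 10
    optimizer: str = "adam"
    freeze_batchnorm: bool = True
    split_fraction: float = 0.8
    split_unit: str = "well"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.split_unit != "well":
            raise ValueError("only well-level splitting is supported")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class RetrievalConfig:
    k: int = 1
    metric: str = "cosine"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric != "cosine":
            raise ValueError("only cosine retrieval is supported")


@dataclass
class FieldPrediction:
    image_id: str
    probabilities: np.ndarray  # (3,), sums to 1
    label: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (len(CLASS_LABELS),) or abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
            raise ValueError(f"invalid probability vector {p}")
        self.probabilities = p


@dataclass
class WellPrediction:
    plate_id: str
    well_id: str
    votes: dict[str, int]
    label: str
    tie_broken: bool
    mean_probabilities: np.ndarray


@dataclass
class Gallery:
    """Reference embeddings for retrieval: training images and labels."""

    z: np.ndarray
    ids: Sequence[str]
    labels: Sequence[str]


@dataclass
class RetrievalHit:
    gallery_id: str
    label: str
    similarity: float


@dataclass
class EvalResult:
    accuracy: float
    macro_f1: float
    confusion: np.ndarray  # rows = true class, CLASS_LABELS order


@dataclass
class TrainResult:
    model: PhenotypeModel
    history: list[dict] = field(default_factory=list)

    def write_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.history:
                fh.write(json.dumps(row) + "\n")


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

class ImageCache:
    """Lazy in-memory cache of normalised field images keyed by path."""

    def __init__(self) -> None:
        self._data: dict[str, np.ndarray] = {}

    def get(self, record: ImageRecord) -> np.ndarray:
        img = self._data.get(record.path)
        if img is None:
            img = read_field_image(record).astype(np.float32)
            self._data[record.path] = img
        return img


def split_dataset(
    manifest: ExperimentManifest, cfg: TrainConfig
) -> tuple[ExperimentManifest, ExperimentManifest]:
    """Stratified 80/20 split at well granularity.

    All fields of a well land on the same side; strata are (class, plate)
    so both sides see every plate and class where counts allow. A class
    with a single well cannot be split and raises.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    wells_by_class: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for plate_id, well_id in manifest.wells():
        cls = manifest.well_label(plate_id, well_id)
        wells_by_class.setdefault(cls, {}).setdefault(plate_id, []).append((plate_id, well_id))

    train_wells: list[tuple[str, str]] = []
    test_wells: list[tuple[str, str]] = []
    for cls in sorted(wells_by_class):
        strata = wells_by_class[cls]
        n_total = sum(len(v) for v in strata.values())
        if n_total < 2:
            raise ValueError(f"class {cls!r} has only {n_total} well(s); cannot split")
        cls_train: list[tuple[str, str]] = []
        cls_test: list[tuple[str, str]] = []
        for plate_id in sorted(strata):
            wells = sorted(strata[plate_id])
            perm = rng.permutation(len(wells))
            n_test = int(round((1.0 - cfg.split_fraction) * len(wells)))
            for pos, j in enumerate(perm):
                (cls_test if pos < n_test else cls_train).append(wells[j])
        if not cls_test:
            cls_test.append(cls_train.pop())
        if not cls_train:
            cls_train.append(cls_test.pop())
        train_wells.extend(cls_train)
        test_wells.extend(cls_test)
    return manifest.subset(train_wells), manifest.subset(test_wells)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    manifest: ExperimentManifest,
    model: PhenotypeModel,
    loss_cfg: LossConfig | None = None,
    sampler_cfg: SamplerConfig | None = None,
    train_cfg: TrainConfig | None = None,
    augment_cfg: AugmentConfig | None = None,
    cache: ImageCache | None = None,
    batches_per_epoch: int | None = None,
) -> TrainResult:
    """Optimise the combined contrastive + cross-entropy objective.

    Batches come from the batch-aware sampler; each sampled field is
    represented by one randomly chosen crop of its five, stochastically
    augmented. Raises on non-finite loss, naming the offending batch.
    """
    loss_cfg = loss_cfg or LossConfig()
    sampler_cfg = sampler_cfg or SamplerConfig()
    train_cfg = train_cfg or TrainConfig()
    augment_cfg = augment_cfg or AugmentConfig(crop_size=128)
    cache = cache or ImageCache()

    from . import nn  # local import to keep module load light

    opt_cls = nn.Adam if train_cfg.optimizer == "adam" else nn.SGD
    opt = opt_cls(model.params(), lr=train_cfg.learning_rate)
    sampler_ss, augment_ss = np.random.SeedSequence(train_cfg.seed).spawn(2)
    sampler_rng = np.random.default_rng(sampler_ss)
    augment_rng = np.random.default_rng(augment_ss)

    labels_int = np.array([_LABEL_TO_INT[r.class_label] for r in manifest.images])
    plates = np.array([r.plate_id for r in manifest.images])

    history: list[dict] = []
    batch_counter = 0
    for epoch in range(train_cfg.epochs):
        sums = {"supcon": 0.0, "ce": 0.0, "total": 0.0, "correct": 0, "n": 0}
        for batch in make_batches(
            manifest, sampler_cfg, n_batches=batches_per_epoch, rng=sampler_rng
        ):
            x = np.stack(
                [
                    _training_crop(cache.get(manifest.images[i]), augment_cfg, augment_rng)
                    for i in batch
                ]
            )
            y = labels_int[batch]
            out = model.forward(x, train=True)
            ce, d_logits = cross_entropy(out.logits, y)
            if loss_cfg.lambda1 != 0.0:
                sup, d_z = supcon_loss_and_grad(
                    EmbeddingBatch(out.z, y, plates[batch]),
                    tau=loss_cfg.tau,
                    reduction=loss_cfg.reduction,
                )
                d_z = (loss_cfg.lambda1 * d_z).astype(np.float32)
            else:
                sup, d_z = 0.0, None
            total = loss_cfg.lambda1 * sup + loss_cfg.lambda2 * ce
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {batch_counter}: "
                    f"supcon={sup}, ce={ce}"
                )
            model.backward((loss_cfg.lambda2 * d_logits).astype(np.float32), d_z)
            opt.step()
            opt.zero_grad()
            sums["supcon"] += sup
            sums["ce"] += ce
            sums["total"] += total
            sums["correct"] += int((out.logits.argmax(axis=1) == y).sum())
            sums["n"] += len(batch)
            batch_counter += 1
        n_b = max(1, batch_counter - sum(h["n_batches"] for h in history))
        history.append(
            {
                "epoch": epoch,
                "supcon": sums["supcon"] / n_b,
                "ce": sums["ce"] / n_b,
                "total": sums["total"] / n_b,
                "train_accuracy": sums["correct"] / max(1, sums["n"]),
                "n_batches": n_b,
            }
        )
        logger.info(
            "epoch %d: total=%.4f supcon=%.4f ce=%.4f acc=%.3f",
            epoch, history[-1]["total"], history[-1]["supcon"],
            history[-1]["ce"], history[-1]["train_accuracy"],
        )
    return TrainResult(model=model, history=history)


def _training_crop(
    image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    crops = five_crop(image, cfg.crop_size, fallback=cfg.crop_fallback)
    crop = crops[int(rng.integers(len(crops)))]
    return augment(crop, cfg, rng)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _eval_crops(
    model: PhenotypeModel,
    manifest: ExperimentManifest,
    crop_size: int,
    cache: ImageCache | None,
    chunk_fields: int = 8,
):
    """Yield (records, ModelOutput-of-5-crops-per-field) in chunks."""
    cache = cache or ImageCache()
    recs = manifest.images
    for start in range(0, len(recs), chunk_fields):
        chunk = recs[start:start + chunk_fields]
        crops = [
            c
            for r in chunk
            for c in five_crop(cache.get(r), crop_size, fallback=True)
        ]
        out = model.forward(np.stack(crops), train=False)
        yield chunk, out


def predict_fields(
    model: PhenotypeModel,
    manifest: ExperimentManifest,
    crop_size: int = 128,
    cache: ImageCache | None = None,
) -> list[FieldPrediction]:
    """Deterministic per-field prediction, probabilities averaged over crops."""
    preds: list[FieldPrediction] = []
    for chunk, out in _eval_crops(model, manifest, crop_size, cache):
        probs = softmax(out.logits).reshape(len(chunk), 5, -1).mean(axis=1)
        probs /= probs.sum(axis=1, keepdims=True)
        for rec, p in zip(chunk, probs):
            preds.append(
                FieldPrediction(
                    image_id=rec.image_id,
                    probabilities=p,
                    label=CLASS_LABELS[int(p.argmax())],
                )
            )
    return preds


def compute_field_embeddings(
    model: PhenotypeModel,
    manifest: ExperimentManifest,
    crop_size: int = 128,
    cache: ImageCache | None = None,
) -> tuple[list[str], np.ndarray]:
    """One embedding per field: L2-renormalised mean of the 5 crop embeddings."""
    ids: list[str] = []
    zs: list[np.ndarray] = []
    for chunk, out in _eval_crops(model, manifest, crop_size, cache):
        z = out.z.reshape(len(chunk), 5, -1).mean(axis=1)
        z /= np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)
        ids.extend(r.image_id for r in chunk)
        zs.append(z)
    return ids, np.vstack(zs)


def export_embeddings(
    model: PhenotypeModel,
    manifest: ExperimentManifest,
    path: str | Path,
    crop_size: int = 128,
    cache: ImageCache | None = None,
) -> pd.DataFrame:
    """Write per-field embeddings as CSV (image_id, metadata, z_0..z_{d-1})."""
    ids, z = compute_field_embeddings(model, manifest, crop_size, cache)
    by_id = {r.image_id: r for r in manifest.images}
    df = pd.DataFrame(
        {
            "image_id": ids,
            "plate_id": [by_id[i].plate_id for i in ids],
            "well_id": [by_id[i].well_id for i in ids],
            "class_label": [by_id[i].class_label for i in ids],
        }
    )
    zdf = pd.DataFrame(z, columns=[f"z_{j}" for j in range(z.shape[1])])
    df = pd.concat([df, zdf], axis=1)
    df.to_csv(path, index=False)
    return df


def well_vote(
    predictions: Sequence[FieldPrediction], manifest: ExperimentManifest
) -> list[WellPrediction]:
    """Majority voting over the fields of each well.

    Vote ties are broken by the larger summed probability across the tied
    classes, then by the fixed order healthy < apoptosis < ferroptosis.
    """
    by_id = {r.image_id: r for r in manifest.images}
    grouped: dict[tuple[str, str], list[FieldPrediction]] = {}
    for pred in predictions:
        rec = by_id[pred.image_id]
        grouped.setdefault(rec.well_key, []).append(pred)

    out: list[WellPrediction] = []
    for (plate_id, well_id), preds in sorted(grouped.items()):
        votes = {c: 0 for c in CLASS_LABELS}
        for p in preds:
            votes[p.label] += 1
        mean_probs = np.mean([p.probabilities for p in preds], axis=0)
        top = max(votes.values())
        tied = [c for c in CLASS_LABELS if votes[c] == top]
        tie_broken = len(tied) > 1
        if tie_broken:
            summed = {c: mean_probs[_LABEL_TO_INT[c]] for c in tied}
            best = max(summed.values())
            tied = [c for c in tied if summed[c] == best]
        winner = tied[0]  # CLASS_LABELS order is the final tie-break
        out.append(
            WellPrediction(
                plate_id=plate_id,
                well_id=well_id,
                votes=votes,
                label=winner,
                tie_broken=tie_broken,
                mean_probabilities=mean_probs,
            )
        )
    return out


def evaluate(y_true: Sequence[str], y_pred: Sequence[str]) -> EvalResult:
    """Accuracy, macro-averaged F1 and the 3x3 confusion matrix (rows=true)."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    unknown = (set(y_true) | set(y_pred)) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    labels = list(CLASS_LABELS)
    return EvalResult(
        accuracy=float(accuracy_score(y_true, y_pred)),
        macro_f1=float(f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
    )


# ---------------------------------------------------------------------------
# embedding-space tools
# ---------------------------------------------------------------------------

def _unit_rows(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    return z / np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)


def retrieve(
    query_z: np.ndarray, gallery: Gallery, cfg: RetrievalConfig | None = None
) -> list[list[RetrievalHit]]:
    """Top-k gallery neighbours per query by cosine similarity.

    Ranked by descending similarity with deterministic tie-break on the
    gallery id.
    """
    cfg = cfg or RetrievalConfig()
    gz = _unit_rows(gallery.z)
    if cfg.k > gz.shape[0]:
        raise ValueError(f"k={cfg.k} exceeds gallery size {gz.shape[0]}")
    qz = _unit_rows(np.atleast_2d(query_z))
    if qz.shape[1] != gz.shape[1]:
        raise ValueError("query/gallery dimensionality mismatch")
    sims = qz @ gz.T
    ids = np.asarray(gallery.ids)
    labels = np.asarray(gallery.labels)
    results: list[list[RetrievalHit]] = []
    for row in sims:
        order = np.lexsort((ids, -row))[: cfg.k]
        results.append(
            [RetrievalHit(str(ids[j]), str(labels[j]), float(row[j])) for j in order]
        )
    return results


def plate_mixing_score(
    z: np.ndarray, plate_ids: Sequence[str], k: int = 10
) -> float:
    """Mean fraction of k cosine-nearest neighbours on the sample's own plate.

    Approaches 1/n_plates for perfectly mixed balanced plates and 1.0 when
    embeddings cluster by plate — a scalar readout of residual batch effect
    in the embedding space. Neighbour ties are broken by sample index.
    """
    z = _unit_rows(z)
    plates = np.asarray(plate_ids)
    n = z.shape[0]
    if len(np.unique(plates)) < 2:
        raise ValueError("plate_mixing_score needs samples from >= 2 plates")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples {n}")
    sims = z @ z.T
    np.fill_diagonal(sims, -2.0)  # exclude self (below the cosine range)
    idx = np.arange(n)
    fractions = np.empty(n)
    for i in range(n):
        order = np.lexsort((idx, -sims[i]))[:k]
        fractions[i] = float(np.mean(plates[order] == plates[i]))
    return float(fractions.mean())
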