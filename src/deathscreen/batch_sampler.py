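"""Batch-aware sampling across plates and classes.

Every training batch of size bs = n_plates * n_samples * n_classes is
composed from exactly n_plates distinct plates with n_samples items per
(plate, class) cell. This guarantees that each anchor can find positives
(same class, different plate) and negatives (different class, same plate)
inside the batch — the sampling contract that lets the contrastive loss
pull class signal together across plates instead of letting embeddings
cluster by acquisition batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .core_data import CLASS_LABELS, ExperimentManifest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    n_plates: int = 2
    n_samples: int = 5
    n_classes: int = 3
    seed: int = 0
    policy: str = "resample_with_replacement"  # or "skip"

    def __post_init__(self) -> None:
        for name in ("n_plates", "n_samples", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.policy not in ("resample_with_replacement", "skip"):
            raise ValueError(f"unknown policy {self.policy!r}")

    @property
    def batch_size(self) -> int:
        return self.n_plates * self.n_samples * self.n_classes


def _index_by_cell(
    manifest: ExperimentManifest, classes: Sequence[str]
) -> dict[tuple[str, str], list[int]]:
    cells: dict[tuple[str, str], list[int]] = {}
    for idx, rec in enumerate(manifest.images):
        if rec.class_label in classes:
            cells.setdefault((rec.plate_id, rec.class_label), []).append(idx)
    return cells


def make_batches(
    manifest: ExperimentManifest,
    cfg: SamplerConfig,
    n_batches: int | None = None,
    rng: np.random.Generator | None = None,
) -> Iterator[list[int]]:
    """Yield seeded batches of manifest indices.

    Plates are drawn uniformly without replacement per batch; within each
    selected plate, n_samples items are drawn per class (without replacement
    when the cell is large enough, else per the configured policy). One
    epoch defaults to enough batches to visit each item about once in
    expectation.
    """
    classes = CLASS_LABELS[: cfg.n_classes]
    plates = manifest.plates()
    if len(plates) < cfg.n_plates:
        raise ValueError(
            f"manifest has {len(plates)} plate(s); sampler needs {cfg.n_plates}"
        )
    present = {r.class_label for r in manifest.images}
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"class(es) entirely absent from manifest: {missing}")

    cells = _index_by_cell(manifest, classes)
    rng = rng or np.random.default_rng(cfg.seed)
    if n_batches is None:
        n_items = sum(len(v) for v in cells.values())
        n_batches = max(1, round(n_items / cfg.batch_size))

    for _ in range(n_batches):
        chosen_plates = list(rng.choice(plates, size=cfg.n_plates, replace=False))
        batch: list[int] = []
        feasible = True
        for plate in chosen_plates:
            for cls in classes:
                cell = cells.get((plate, cls), [])
                if len(cell) >= cfg.n_samples:
                    picks = rng.choice(cell, size=cfg.n_samples, replace=False)
                elif cell and cfg.policy == "resample_with_replacement":
                    picks = rng.choice(cell, size=cfg.n_samples, replace=True)
                elif cfg.policy == "resample_with_replacement":
                    # borrow from the same class on the other selected plates
                    pool = [
                        i for p in chosen_plates for i in cells.get((p, cls), [])
                    ]
                    if not pool:
                        pool = [
                            i for p in plates for i in cells.get((p, cls), [])
                        ]
                        logger.warning(
                            "class %s absent from selected plates %s; borrowing "
                            "from the full manifest", cls, chosen_plates,
                        )
                    picks = rng.choice(pool, size=cfg.n_samples, replace=True)
                else:  # skip policy
                    feasible = False
                    break
                batch.extend(int(i) for i in picks)
            if not feasible:
                break
        if feasible:
            yield batch


def triplet_roles(
    batch_indices: Sequence[int], manifest: ExperimentManifest
) -> list[tuple[list[int], list[int]]]:
    """Per-anchor positive/negative role sets, as batch positions.

    For anchor position i: positives are batch members with the same class
    label on a *different* plate; negatives share the anchor's plate but
    carry a different label. Empty sets are reported, not raised — they
    flag a batch on which the anti-batch-effect contract is degenerate.
    """
    recs = [manifest.images[i] for i in batch_indices]
    roles: list[tuple[list[int], list[int]]] = []
    for i, anchor in enumerate(recs):
        positives = [
            j
            for j, other in enumerate(recs)
            if j != i
            and other.class_label == anchor.class_label
            and other.plate_id != anchor.plate_id
        ]
        negatives = [
            j
            for j, other in enumerate(recs)
            if j != i
            and other.class_label != anchor.class_label
            and other.plate_id == anchor.plate_id
        ]
        roles.append((positives, negatives))
    return roles


def batch_diagnostics(
    batch_indices: Sequence[int], manifest: ExperimentManifest
) -> dict:
    """Counts used by tests and the CSV diagnostics dump."""
    recs = [manifest.images[i] for i in batch_indices]
    plates = sorted({r.plate_id for r in recs})
    per_plate = {p: sum(r.plate_id == p for r in recs) for p in plates}
    per_class = {c: sum(r.class_label == c for r in recs) for c in CLASS_LABELS}
    return {"size": len(recs), "plates": plates, "per_plate": per_plate, "per_class": per_class}
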