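"""Experiment data model for cell-painting screens.

A screen is a set of multi-well plates. Each well was treated with one
compound at one concentration (or with DMSO solvent only) and imaged at
several field positions in four fluorescence channels (ER, Actin/Golgi,
Mitochondria, Nuclei). A CellTiter-Glo ATP readout per well, normalised to
the plate's DMSO controls, measures residual viability and drives the
training-inclusion filter: treated wells are kept only when their normalised
viability falls in a window (default [0.3, 0.8]) where the treatment has
taken visible effect without killing the population outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

#: Canonical channel order for all field images.
CHANNEL_ORDER: tuple[str, str, str, str] = ("ER", "ActinGolgi", "Mitochondria", "Nuclei")

#: Canonical class labels, in fixed tie-break order.
CLASS_LABELS: tuple[str, str, str] = ("healthy", "apoptosis", "ferroptosis")

#: Compound name reserved for solvent-control wells.
DMSO = "DMSO"

MANIFEST_COLUMNS = [
    "image_id",
    "plate_id",
    "well_id",
    "field_index",
    "compound",
    "concentration_um",
    "class_label",
    "path",
]

ATP_COLUMNS = ["plate_id", "well_id", "raw_atp"]


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


class JoinError(ValueError):
    """Image and ATP tables do not join one-to-one on (plate_id, well_id)."""


class ImageFormatError(ValueError):
    """A field image on disk does not have the expected 4-channel layout."""


@dataclass(frozen=True)
class ImageRecord:
    """One 4-channel field image plus its experimental metadata."""

    image_id: str
    plate_id: str
    well_id: str
    field_index: int
    compound: str
    concentration_um: float
    class_label: str
    path: str
    channel_order: tuple[str, ...] = CHANNEL_ORDER

    def __post_init__(self) -> None:
        if self.field_index < 0:
            raise SchemaError(f"field_index must be >= 0, got {self.field_index}")
        if self.concentration_um < 0:
            raise SchemaError(f"concentration_um must be >= 0, got {self.concentration_um}")
        if self.class_label not in CLASS_LABELS:
            raise SchemaError(
                f"class_label {self.class_label!r} not one of {CLASS_LABELS}"
            )
        if tuple(self.channel_order) != CHANNEL_ORDER:
            raise SchemaError(
                f"channel_order must be {CHANNEL_ORDER}, got {self.channel_order}"
            )
        if self.compound == DMSO and self.class_label != "healthy":
            raise SchemaError(
                f"DMSO well {self.plate_id}/{self.well_id} must be labelled healthy"
            )

    @property
    def well_key(self) -> tuple[str, str]:
        return (self.plate_id, self.well_id)


@dataclass
class AtpRecord:
    """Raw and DMSO-normalised ATP viability for one well."""

    plate_id: str
    well_id: str
    raw_atp: float
    normalized_viability: float | None = None

    def __post_init__(self) -> None:
        if not self.raw_atp > 0:
            raise SchemaError(
                f"raw_atp must be positive, got {self.raw_atp} "
                f"({self.plate_id}/{self.well_id})"
            )

    @property
    def well_key(self) -> tuple[str, str]:
        return (self.plate_id, self.well_id)


@dataclass(frozen=True)
class ViabilityFilterConfig:
    """Closed-interval window on normalised viability for treated wells."""

    lower: float = 0.3
    upper: float = 0.8
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper):
            raise ValueError(f"need 0 <= lower < upper, got [{self.lower}, {self.upper}]")

    def contains(self, v: float) -> bool:
        if self.inclusive:
            return self.lower <= v <= self.upper
        return self.lower < v < self.upper


@dataclass
class ExperimentManifest:
    """Joined image + ATP tables; the central in-memory container.

    Invariants: every image's (plate_id, well_id) has exactly one ATP record
    and image_ids are unique.
    """

    images: list[ImageRecord]
    atp: list[AtpRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.images]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate image_id(s): {dupes[:5]}")
        atp_keys = [a.well_key for a in self.atp]
        if len(set(atp_keys)) != len(atp_keys):
            raise JoinError("duplicate (plate_id, well_id) in ATP table")
        self._atp_by_well = {a.well_key: a for a in self.atp}
        if self.atp:
            missing = sorted({r.well_key for r in self.images} - set(atp_keys))
            if missing:
                raise JoinError(
                    "wells present in image manifest but absent from ATP table: "
                    + ", ".join(f"{p}/{w}" for p, w in missing[:10])
                )

    # -- lookups ---------------------------------------------------------
    def atp_for(self, plate_id: str, well_id: str) -> AtpRecord:
        return self._atp_by_well[(plate_id, well_id)]

    def plates(self) -> list[str]:
        return sorted({r.plate_id for r in self.images})

    def wells(self) -> list[tuple[str, str]]:
        return sorted({r.well_key for r in self.images})

    def well_label(self, plate_id: str, well_id: str) -> str:
        labels = {r.class_label for r in self.images if r.well_key == (plate_id, well_id)}
        if len(labels) != 1:
            raise SchemaError(f"well {plate_id}/{well_id} has mixed labels {labels}")
        return labels.pop()

    def dmso_wells(self, plate_id: str) -> set[str]:
        return {
            r.well_id
            for r in self.images
            if r.plate_id == plate_id and r.compound == DMSO
        }

    def subset(self, keep_wells: Iterable[tuple[str, str]]) -> "ExperimentManifest":
        keep = set(keep_wells)
        images = [r for r in self.images if r.well_key in keep]
        atp = [a for a in self.atp if a.well_key in {r.well_key for r in images}]
        return ExperimentManifest(images=images, atp=atp)

    def subset_plates(self, plate_ids: Iterable[str]) -> "ExperimentManifest":
        plates = set(plate_ids)
        return self.subset(w for w in self.wells() if w[0] in plates)

    def __len__(self) -> int:
        return len(self.images)

    # -- dataframe views -------------------------------------------------
    def images_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": r.image_id,
                    "plate_id": r.plate_id,
                    "well_id": r.well_id,
                    "field_index": r.field_index,
                    "compound": r.compound,
                    "concentration_um": r.concentration_um,
                    "class_label": r.class_label,
                    "path": r.path,
                }
                for r in self.images
            ],
            columns=MANIFEST_COLUMNS,
        )

    def atp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plate_id": a.plate_id,
                    "well_id": a.well_id,
                    "raw_atp": a.raw_atp,
                    "normalized_viability": a.normalized_viability,
                }
                for a in self.atp
            ],
            columns=ATP_COLUMNS + ["normalized_viability"],
        )


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def read_manifest(manifest_path: str | Path, atp_path: str | Path) -> ExperimentManifest:
    """Read and join an image manifest CSV with a per-well ATP CSV.

    Raises :class:`SchemaError` for missing columns and :class:`JoinError`
    for image wells with no ATP row.
    """
    mdf = pd.read_csv(manifest_path)
    adf = pd.read_csv(atp_path)
    _require_columns(mdf, MANIFEST_COLUMNS, f"manifest {manifest_path}")
    _require_columns(adf, ATP_COLUMNS, f"ATP table {atp_path}")
    images = [
        ImageRecord(
            image_id=str(row.image_id),
            plate_id=str(row.plate_id),
            well_id=str(row.well_id),
            field_index=int(row.field_index),
            compound=str(row.compound),
            concentration_um=float(row.concentration_um),
            class_label=str(row.class_label),
            path=str(row.path),
        )
        for row in mdf.itertuples()
    ]
    atp = [
        AtpRecord(
            plate_id=str(row.plate_id),
            well_id=str(row.well_id),
            raw_atp=float(row.raw_atp),
            normalized_viability=(
                float(row.normalized_viability)
                if "normalized_viability" in adf.columns
                and not pd.isna(row.normalized_viability)
                else None
            ),
        )
        for row in adf.itertuples()
    ]
    return ExperimentManifest(images=images, atp=atp)


def normalize_atp(
    records: Sequence[AtpRecord], dmso_well_ids: Iterable[str]
) -> list[AtpRecord]:
    """Normalise raw ATP of one plate to the median of its DMSO wells.

    The median DMSO well maps to exactly 1.0; wells near 0 are dead.
    """
    records = list(records)
    plates = {r.plate_id for r in records}
    if len(plates) != 1:
        raise ValueError(f"normalize_atp expects records from one plate, got {plates}")
    dmso = set(dmso_well_ids)
    ref_values = [r.raw_atp for r in records if r.well_id in dmso]
    if not ref_values:
        raise ValueError(f"plate {plates.pop()} has no DMSO wells to normalise against")
    ref = float(np.median(ref_values))
    if not ref > 0:
        raise ValueError(f"non-positive DMSO reference {ref}")
    return [
        AtpRecord(
            plate_id=r.plate_id,
            well_id=r.well_id,
            raw_atp=r.raw_atp,
            normalized_viability=r.raw_atp / ref,
        )
        for r in records
    ]


def normalize_manifest_atp(manifest: ExperimentManifest) -> ExperimentManifest:
    """Apply :func:`normalize_atp` plate by plate across a whole manifest."""
    out: list[AtpRecord] = []
    for plate in manifest.plates():
        plate_atp = [a for a in manifest.atp if a.plate_id == plate]
        out.extend(normalize_atp(plate_atp, manifest.dmso_wells(plate)))
    return ExperimentManifest(images=list(manifest.images), atp=out)


def filter_by_viability(
    manifest: ExperimentManifest,
    cfg: ViabilityFilterConfig | None = None,
) -> ExperimentManifest:
    """Keep treated wells whose normalised viability lies in the window.

    Healthy/DMSO control wells bypass the filter and are always retained:
    their viability sits near 1.0, outside the window by construction, yet
    they anchor the healthy class during training.
    """
    cfg = cfg or ViabilityFilterConfig()
    keep: list[tuple[str, str]] = []
    for plate_id, well_id in manifest.wells():
        if manifest.well_label(plate_id, well_id) == "healthy":
            keep.append((plate_id, well_id))
            continue
        a = manifest.atp_for(plate_id, well_id)
        if a.normalized_viability is None:
            raise ValueError(
                f"well {plate_id}/{well_id} has no normalized_viability; "
                "run normalize_atp first"
            )
        if cfg.contains(a.normalized_viability):
            keep.append((plate_id, well_id))
    return manifest.subset(keep)


def concentration_series(ic50: float) -> np.ndarray:
    """Five-point two-fold titration anchored at the IC50.

    Returns [2·ic50, ic50, ic50/2, ic50/4, ic50/8] — one step above the
    IC50 and three below, strictly decreasing.
    """
    if not (math.isfinite(ic50) and ic50 > 0):
        raise ValueError(f"ic50 must be a positive finite concentration, got {ic50}")
    return ic50 * np.array([2.0, 1.0, 0.5, 0.25, 0.125])


def read_field_image(
    record: ImageRecord | str | Path, rescale: bool = True
) -> np.ndarray:
    """Load a field TIFF as a float (4, H, W) array in [0, 1].

    Accepts planar (4, H, W) or interleaved (H, W, 4) layouts. Integer data
    are divided by the dtype maximum. With ``rescale`` each channel is then
    stretched to its robust 1st–99th percentile range and clipped to [0, 1];
    with ``rescale=False`` the raw scaled values are returned (useful for
    round-trip checks).
    """
    path = record.path if isinstance(record, ImageRecord) else str(record)
    arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise ImageFormatError(f"{path}: expected a 3-d channel image, got shape {arr.shape}")
    if arr.shape[0] == 4:
        pass
    elif arr.shape[-1] == 4:
        arr = np.moveaxis(arr, -1, 0)
    else:
        raise ImageFormatError(
            f"{path}: expected 4 channels, got shape {arr.shape}"
        )
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float32)
    if not rescale:
        return arr
    out = np.empty_like(arr)
    for c in range(4):
        lo, hi = np.percentile(arr[c], [1.0, 99.0])
        if hi <= lo:
            out[c] = 0.0
        else:
            out[c] = np.clip((arr[c] - lo) / (hi - lo), 0.0, 1.0)
    return out


def write_field_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float (4, H, W) image in [0, 1] as a 16-bit planar TIFF."""
    if image.ndim != 3 or image.shape[0] != 4:
        raise ImageFormatError(f"expected (4, H, W) image, got shape {image.shape}")
    data = np.round(np.clip(image, 0.0, 1.0) * 65535.0).astype(np.uint16)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), data, photometric="minisblack")
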