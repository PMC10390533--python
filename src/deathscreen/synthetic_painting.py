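"""Seeded synthetic cell-painting experiments.

Generates desk-scale stand-ins for a high-content cell-death screen: plates
of wells imaged at several fields in the four canonical channels, together
with a matched per-well ATP table. Wells are treated with apoptosis or
ferroptosis inducers over a five-point two-fold titration around each
compound's IC50, or with DMSO solvent only. Viability follows a Hill
dose-response curve; the fraction of morphologically affected cells in a
well is coupled to it (effect_fraction = 1 - viability), so the standard
[0.3, 0.8] viability filter selects exactly the visibly affected wells.

Phenotypes are statistical, not photorealistic: apoptotic cells shrink and
fragment their nuclei into several bright blobs; ferroptotic cells round up
and show dim, finely granular mitochondria. Per-plate batch effects
(channel gain, offset, defocus blur) emulate plate-to-plate acquisition
drift and are the confounder the batch-aware training strategy must defeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core_data import (
    CLASS_LABELS,
    DMSO,
    AtpRecord,
    ExperimentManifest,
    ImageRecord,
    concentration_series,
    write_field_image,
)

# channel indices in CHANNEL_ORDER
CH_ER, CH_ACTIN, CH_MITO, CH_NUCLEI = 0, 1, 2, 3


@dataclass(frozen=True)
class CompoundSpec:
    """A synthetic cell-death inducer with its dose-response parameters."""

    name: str
    class_label: str  # "apoptosis" or "ferroptosis"
    ic50_um: float
    hill: float = 1.5

    def __post_init__(self) -> None:
        if self.class_label not in ("apoptosis", "ferroptosis"):
            raise ValueError(f"inducer class must be apoptosis/ferroptosis, got {self.class_label}")
        if self.ic50_um <= 0 or self.hill <= 0:
            raise ValueError("ic50_um and hill must be positive")


def default_compounds() -> list[CompoundSpec]:
    """Two inducers per death modality, IC50s spanning the nM–µM range."""
    return [
        CompoundSpec("apo-A", "apoptosis", ic50_um=0.024, hill=1.6),
        CompoundSpec("apo-B", "apoptosis", ic50_um=0.124, hill=1.4),
        CompoundSpec("fer-A", "ferroptosis", ic50_um=0.030, hill=1.6),
        CompoundSpec("fer-B", "ferroptosis", ic50_um=0.235, hill=1.4),
    ]


@dataclass(frozen=True)
class PhenotypeParams:
    """Rendering parameters for the three cell states.

    Radii are in pixels at the default 256 px field size; intensities are on
    the [0, 1] scale before plate effects.
    """

    # healthy morphology
    cell_count_mean: float = 25.0
    cell_radius: float = 11.0
    nucleus_radius_frac: float = 0.40
    base_intensity: tuple[float, float, float, float] = (0.40, 0.50, 0.60, 0.80)
    mito_granules: int = 7
    # apoptosis
    fragmentation_range: tuple[int, int] = (3, 6)
    shrink_factor: float = 0.60
    bleb_intensity: float = 0.75
    # ferroptosis
    mito_attenuation: float = 0.25
    granularity_scale: float = 0.60
    rounding_factor: float = 0.85

    def __post_init__(self) -> None:
        for name in ("shrink_factor", "mito_attenuation", "granularity_scale", "rounding_factor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.fragmentation_range[0] < 2:
            raise ValueError("nuclear fragmentation count must be >= 2")


@dataclass(frozen=True)
class PlateEffect:
    """Multiplicative gain, additive offset and defocus blur of one plate."""

    gain: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    offset: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    blur_sigma: float = 0.0

    def apply(self, image: np.ndarray) -> np.ndarray:
        out = image * np.asarray(self.gain, dtype=image.dtype)[:, None, None]
        out += np.asarray(self.offset, dtype=image.dtype)[:, None, None]
        if self.blur_sigma > 0:
            out = ndimage.gaussian_filter(out, sigma=(0, self.blur_sigma, self.blur_sigma))
        return np.clip(out, 0.0, 1.0)


IDENTITY_PLATE_EFFECT = PlateEffect()


@dataclass
class SyntheticConfig:
    """Design of a synthetic screen; the defaults are the study conditions."""

    n_plates: int = 3
    compounds: list[CompoundSpec] = field(default_factory=default_compounds)
    n_dmso_wells_per_plate: int = 4
    replicates_per_concentration: int = 1
    fields_per_well: int = 9
    image_size: tuple[int, int] = (256, 256)
    gain_log_sd: float = 0.15
    offset_sd: float = 0.01
    blur_sd: float = 0.4
    atp_noise_sd: float = 0.05
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_plates",
            "n_dmso_wells_per_plate",
            "replicates_per_concentration",
            "fields_per_well",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if min(self.image_size) < 64:
            raise ValueError(f"image_size must be at least 64x64, got {self.image_size}")
        if not self.compounds:
            raise ValueError("need at least one compound")


def viability_model(dose_um: float, ic50_um: float, hill: float) -> float:
    """Hill dose-response: viability = 1 / (1 + (dose/ic50)^hill).

    Returns 1.0 at zero dose and exactly 0.5 at the IC50; monotone
    non-increasing in dose.
    """
    if dose_um < 0 or ic50_um <= 0 or hill <= 0:
        raise ValueError(
            f"need dose >= 0, ic50 > 0, hill > 0; got {dose_um}, {ic50_um}, {hill}"
        )
    if dose_um == 0:
        return 1.0
    return float(1.0 / (1.0 + (dose_um / ic50_um) ** hill))


def _add_blob(
    channel: np.ndarray,
    cy: float,
    cx: float,
    sy: float,
    sx: float,
    theta: float,
    amp: float,
) -> None:
    """Accumulate a rotated anisotropic Gaussian blob in place."""
    h, w = channel.shape
    extent = 3.0 * max(sy, sx)
    y0, y1 = max(0, int(cy - extent)), min(h, int(cy + extent) + 1)
    x0, x1 = max(0, int(cx - extent)), min(w, int(cx + extent) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    channel[y0:y1, x0:x1] += amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def render_field(
    class_label: str,
    effect_fraction: float,
    phenotype: PhenotypeParams,
    plate_effect: PlateEffect,
    rng: np.random.Generator,
    image_size: tuple[int, int] = (256, 256),
) -> np.ndarray:
    """Render one 4-channel field as a float (4, H, W) array in [0, 1].

    A Poisson number of elliptical cells is scattered over the field; a
    Bernoulli(effect_fraction) subset of them expresses the class phenotype.
    The plate's gain/offset/blur effect is applied last.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class_label {class_label!r}")
    if not 0.0 <= effect_fraction <= 1.0:
        raise ValueError(f"effect_fraction must be in [0, 1], got {effect_fraction}")
    h, w = image_size
    scale = min(h, w) / 256.0  # radii are calibrated at 256 px
    img = np.zeros((4, h, w), dtype=np.float32)
    p = phenotype
    base = p.base_intensity
    n_cells = int(rng.poisson(p.cell_count_mean))
    margin = 2.0 * p.cell_radius * scale
    for _ in range(n_cells):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        r = float(np.clip(rng.normal(p.cell_radius, 1.5), 7.0, 16.0)) * scale
        q = rng.uniform(0.55, 0.95)  # minor/major axis ratio
        theta = rng.uniform(0, np.pi)
        # always draw, so the rng stream is identical across class labels
        # at effect_fraction 0 (no-effect degeneracy)
        u = rng.random()
        affected = class_label != "healthy" and u < effect_fraction
        shrink = p.shrink_factor if (affected and class_label == "apoptosis") else 1.0
        if affected and class_label == "ferroptosis":
            q = q + p.rounding_factor * (1.0 - q)  # round up
        a, b = r * shrink, r * q * shrink

        # ER: soft cytoplasm
        _add_blob(img[CH_ER], cy, cx, b, a, theta, base[CH_ER] * rng.uniform(0.8, 1.2))
        # Actin/Golgi: cortical ring = footprint minus interior
        amp_act = base[CH_ACTIN] * rng.uniform(0.8, 1.2)
        _add_blob(img[CH_ACTIN], cy, cx, b, a, theta, amp_act)
        _add_blob(img[CH_ACTIN], cy, cx, 0.65 * b, 0.65 * a, theta, -0.70 * amp_act)
        # Mitochondria: granules scattered in the cytoplasm
        n_gran = p.mito_granules
        g_amp = base[CH_MITO] * rng.uniform(0.85, 1.15)
        g_sig = 0.18 * r
        if affected and class_label == "ferroptosis":
            g_amp *= p.mito_attenuation
            g_sig *= p.granularity_scale
            n_gran = int(round(n_gran * 1.5))
        elif affected and class_label == "apoptosis":
            g_amp *= 0.8
        for _ in range(n_gran):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.25, 0.75)
            gy = cy + rad * b * np.sin(ang)
            gx = cx + rad * a * np.cos(ang)
            _add_blob(img[CH_MITO], gy, gx, g_sig, g_sig, 0.0, g_amp)
        # Nuclei: single blob, or bright fragments for apoptosis
        if affected and class_label == "apoptosis":
            # apoptotic bodies scatter over the cell's original footprint,
            # well beyond the shrunken remnant, so they resolve as separate
            # bright puncta
            lo, hi = p.fragmentation_range
            n_frag = int(rng.integers(lo, hi + 1))
            a0, b0 = r, r * q
            for _ in range(n_frag):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0.35, 1.0)
                fy = cy + rad * 0.9 * b0 * np.sin(ang)
                fx = cx + rad * 0.9 * a0 * np.cos(ang)
                _add_blob(
                    img[CH_NUCLEI], fy, fx, 0.11 * r, 0.11 * r, 0.0,
                    base[CH_NUCLEI] * rng.uniform(1.0, 1.2),
                )
            # membrane blebs on the actin channel
            for _ in range(3):
                ang = rng.uniform(0, 2 * np.pi)
                by = cy + 1.1 * b * np.sin(ang)
                bx = cx + 1.1 * a * np.cos(ang)
                _add_blob(img[CH_ACTIN], by, bx, 0.12 * r, 0.12 * r, 0.0, p.bleb_intensity)
        else:
            nr = p.nucleus_radius_frac * r
            _add_blob(
                img[CH_NUCLEI], cy, cx, nr * q, nr, theta,
                base[CH_NUCLEI] * rng.uniform(0.85, 1.1),
            )

    img += 0.03  # camera baseline
    img += rng.normal(0.0, 0.01, size=img.shape).astype(np.float32)
    img = np.clip(img, 0.0, 1.0)
    return plate_effect.apply(img)


def sample_plate_effect(cfg: SyntheticConfig, rng: np.random.Generator) -> PlateEffect:
    gain = tuple(np.exp(rng.normal(0.0, cfg.gain_log_sd, size=4)))
    offset = tuple(rng.normal(0.0, cfg.offset_sd, size=4))
    blur = float(abs(rng.normal(0.0, cfg.blur_sd)))
    return PlateEffect(gain=gain, offset=offset, blur_sigma=blur)


def _well_name(index: int) -> str:
    row, col = divmod(index, 24)
    if row >= 16:
        raise ValueError("plate layout exceeds 384 wells")
    return f"{chr(ord('A') + row)}{col + 1:02d}"


@dataclass(frozen=True)
class _WellPlan:
    well_id: str
    compound: str
    class_label: str
    dose_um: float
    viability: float  # noise-free


def _plan_plate(cfg: SyntheticConfig) -> list[_WellPlan]:
    plan: list[_WellPlan] = []
    idx = 0
    for _ in range(cfg.n_dmso_wells_per_plate):
        plan.append(_WellPlan(_well_name(idx), DMSO, "healthy", 0.0, 1.0))
        idx += 1
    for comp in cfg.compounds:
        for dose in concentration_series(comp.ic50_um):
            for _ in range(cfg.replicates_per_concentration):
                v = viability_model(float(dose), comp.ic50_um, comp.hill)
                plan.append(
                    _WellPlan(_well_name(idx), comp.name, comp.class_label, float(dose), v)
                )
                idx += 1
    return plan


def generate_experiment(cfg: SyntheticConfig, out_dir: str | Path) -> ExperimentManifest:
    """Write a full synthetic experiment (TIFF fields + manifest/ATP CSVs).

    Layout: ``out_dir/images/<plate>/<well>_f<k>.tiff`` plus
    ``manifest.csv`` and ``atp.csv`` in the experiment's CSV dialect.
    Byte-identical output for equal config (including seed).
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(cfg.seed)
    plate_seeds = root_ss.spawn(cfg.n_plates)
    plan = _plan_plate(cfg)

    images: list[ImageRecord] = []
    atp: list[AtpRecord] = []
    for p in range(cfg.n_plates):
        plate_id = f"plate{p + 1:02d}"
        rng = np.random.default_rng(plate_seeds[p])
        effect = sample_plate_effect(cfg, rng)
        dmso_level = rng.uniform(40000.0, 60000.0)
        for wp in plan:
            noise = rng.normal(0.0, cfg.atp_noise_sd)
            noise = max(noise, -0.9)  # keep raw ATP positive
            raw = dmso_level * wp.viability * (1.0 + noise)
            atp.append(AtpRecord(plate_id=plate_id, well_id=wp.well_id, raw_atp=raw))
            effect_fraction = 1.0 - wp.viability
            for f in range(cfg.fields_per_well):
                img = render_field(
                    wp.class_label,
                    effect_fraction,
                    cfg.phenotype,
                    effect,
                    rng,
                    cfg.image_size,
                )
                rel = Path("images") / plate_id / f"{wp.well_id}_f{f}.tiff"
                write_field_image(out_dir / rel, img)
                images.append(
                    ImageRecord(
                        image_id=f"{plate_id}_{wp.well_id}_f{f}",
                        plate_id=plate_id,
                        well_id=wp.well_id,
                        field_index=f,
                        compound=wp.compound,
                        concentration_um=wp.dose_um,
                        class_label=wp.class_label,
                        path=str(out_dir / rel),
                    )
                )

    manifest = ExperimentManifest(images=images, atp=atp)
    manifest.images_frame().to_csv(out_dir / "manifest.csv", index=False)
    manifest.atp_frame().drop(columns=["normalized_viability"]).to_csv(
        out_dir / "atp.csv", index=False
    )
    return manifest
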