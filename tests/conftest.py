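import numpy as np
import pytest

from deathscreen.core_data import AtpRecord, ExperimentManifest, ImageRecord
from deathscreen.synthetic_painting import CompoundSpec, SyntheticConfig, generate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_manifest(
    n_plates=2,
    wells_per_class=2,
    fields_per_well=3,
    classes=("healthy", "apoptosis", "ferroptosis"),
    with_atp=True,
):
    """In-memory manifest with placeholder image paths (no pixels on disk)."""
    images, atp = [], []
    for p in range(n_plates):
        plate = f"plate{p + 1:02d}"
        w = 0
        for cls in classes:
            for _ in range(wells_per_class):
                well = f"A{w + 1:02d}"
                w += 1
                compound = "DMSO" if cls == "healthy" else f"drug-{cls[:3]}"
                if with_atp:
                    atp.append(AtpRecord(plate, well, raw_atp=1000.0))
                for f in range(fields_per_well):
                    images.append(
                        ImageRecord(
                            image_id=f"{plate}_{well}_f{f}",
                            plate_id=plate,
                            well_id=well,
                            field_index=f,
                            compound=compound,
                            concentration_um=0.0 if cls == "healthy" else 1.0,
                            class_label=cls,
                            path=f"/nonexistent/{plate}/{well}_f{f}.tiff",
                        )
                    )
    return ExperimentManifest(images=images, atp=atp)


@pytest.fixture
def balanced_manifest():
    return make_manifest(n_plates=2, wells_per_class=3, fields_per_well=4)


def tiny_synth_config(seed=0, n_plates=2):
    """Small, fast synthetic screen: 64 px fields, 3 fields/well, 1 compound/class."""
    return SyntheticConfig(
        n_plates=n_plates,
        compounds=[
            CompoundSpec("apo-A", "apoptosis", ic50_um=0.1, hill=1.6),
            CompoundSpec("fer-A", "ferroptosis", ic50_um=0.1, hill=1.6),
        ],
        n_dmso_wells_per_plate=2,
        fields_per_well=3,
        image_size=(64, 64),
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_experiment(tmp_path_factory):
    """A small on-disk synthetic experiment shared across I/O tests."""
    out = tmp_path_factory.mktemp("tiny_exp")
    manifest = generate_experiment(tiny_synth_config(seed=7), out)
    return out, manifest
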