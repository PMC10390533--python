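"""Desk-scale reference experiments run end to end on synthetic screens.

Two canned protocols, used by the test suite, the acceptance script and the
documentation examples:

* hold-out-plate recovery: simulate a 3-plate screen, ATP-filter, train on
  two plates with the contrastive objective and batch-aware sampling, and
  score well-level majority-vote accuracy on the held-out plate;
* batch-effect ablation: simulate a 2-plate screen with strong per-plate
  channel gain, train once with and once without the contrastive term, and
  compare the plate-mixing score of the training embeddings.

The training settings here (Adam lr 1e-3, 120/15 epochs, 128 px crops of
256 px fields) are the package's desk-scale protocol for the from-scratch
tiny-cnn backbone; fine-tuning a pretrained backbone would instead use the
much smaller TrainConfig default learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .augmentation import AugmentConfig
from .batch_sampler import SamplerConfig
from .core_data import filter_by_viability, normalize_manifest_atp
from .network import BackboneSpec, HeadSpec, PhenotypeModel
from .objectives import LossConfig
from .synthetic_painting import SyntheticConfig, generate_experiment
from .train_eval import (
    EvalResult,
    ImageCache,
    TrainConfig,
    compute_field_embeddings,
    evaluate,
    plate_mixing_score,
    predict_fields,
    train,
    well_vote,
)

CROP_SIZE = 128
DESK_LR = 1e-3


def _seed_int(seed: int, stream: int) -> int:
    return int(
        np.random.SeedSequence(seed, spawn_key=(stream,)).generate_state(1)[0] % (2**31)
    )


@dataclass
class HeldOutPlateResult:
    well_result: EvalResult
    field_accuracy: float
    healthy_vote_fraction_on_viable_wells: float
    n_test_wells: int
    model: PhenotypeModel
    test_manifest: object


def run_heldout_plate_experiment(
    seed: int, work_dir: str | Path, epochs: int = 120
) -> HeldOutPlateResult:
    """Simulate, filter, train on 2 plates, evaluate wells on the third.

    Also predicts the held-out plate's *unfiltered* high-viability treated
    wells (normalised viability >= 0.9) to measure how often a trained model
    votes them healthy — the expected behaviour when a compound fails to
    induce death.
    """
    work_dir = Path(work_dir)
    synth = SyntheticConfig(n_plates=3, seed=_seed_int(seed, 0))
    raw = generate_experiment(synth, work_dir)
    manifest = normalize_manifest_atp(raw)
    filtered = filter_by_viability(manifest)
    plates = filtered.plates()
    train_manifest = filtered.subset_plates(plates[:2])
    test_manifest = filtered.subset_plates(plates[2:])

    model = PhenotypeModel(BackboneSpec(), HeadSpec(), seed=_seed_int(seed, 1))
    cache = ImageCache()
    train(
        train_manifest,
        model,
        LossConfig(),
        SamplerConfig(seed=_seed_int(seed, 2)),
        TrainConfig(learning_rate=DESK_LR, epochs=epochs, seed=_seed_int(seed, 3)),
        AugmentConfig(crop_size=CROP_SIZE),
        cache=cache,
    )

    preds = predict_fields(model, test_manifest, CROP_SIZE, cache)
    wells = well_vote(preds, test_manifest)
    y_true = [test_manifest.well_label(w.plate_id, w.well_id) for w in wells]
    y_pred = [w.label for w in wells]
    true_by_id = {r.image_id: r.class_label for r in test_manifest.images}
    field_acc = float(np.mean([p.label == true_by_id[p.image_id] for p in preds]))

    # dead-plate behaviour: treated wells the filter rejected for being viable
    viable_wells = [
        (a.plate_id, a.well_id)
        for a in manifest.atp
        if a.plate_id == plates[2]
        and a.normalized_viability is not None
        and a.normalized_viability >= 0.9
        and manifest.well_label(a.plate_id, a.well_id) != "healthy"
    ]
    healthy_frac = float("nan")
    if viable_wells:
        viable_manifest = manifest.subset(viable_wells)
        vp = predict_fields(model, viable_manifest, CROP_SIZE, cache)
        vw = well_vote(vp, viable_manifest)
        healthy_frac = float(np.mean([w.label == "healthy" for w in vw]))

    return HeldOutPlateResult(
        well_result=evaluate(y_true, y_pred),
        field_accuracy=field_acc,
        healthy_vote_fraction_on_viable_wells=healthy_frac,
        n_test_wells=len(wells),
        model=model,
        test_manifest=test_manifest,
    )


@dataclass
class AblationResult:
    mixing_with_supcon: float
    mixing_without_supcon: float


def run_batch_effect_ablation(
    seed: int, work_dir: str | Path, epochs: int = 15
) -> AblationResult:
    """Strong plate gain; train with lambda1=0.5 vs 0; compare plate mixing."""
    work_dir = Path(work_dir)
    synth = SyntheticConfig(
        n_plates=2, gain_log_sd=0.6, blur_sd=0.6, seed=_seed_int(seed, 0)
    )
    manifest = filter_by_viability(
        normalize_manifest_atp(generate_experiment(synth, work_dir))
    )
    cache = ImageCache()
    plate_by_id = {r.image_id: r.plate_id for r in manifest.images}
    scores: dict[float, float] = {}
    for lambda1 in (0.5, 0.0):
        model = PhenotypeModel(BackboneSpec(), HeadSpec(), seed=_seed_int(seed, 1))
        train(
            manifest,
            model,
            LossConfig(lambda1=lambda1),
            SamplerConfig(seed=_seed_int(seed, 2)),
            TrainConfig(learning_rate=DESK_LR, epochs=epochs, seed=_seed_int(seed, 3)),
            AugmentConfig(crop_size=CROP_SIZE),
            cache=cache,
        )
        ids, z = compute_field_embeddings(model, manifest, CROP_SIZE, cache)
        scores[lambda1] = plate_mixing_score(z, [plate_by_id[i] for i in ids], k=10)
    return AblationResult(
        mixing_with_supcon=scores[0.5], mixing_without_supcon=scores[0.0]
    )
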