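"""Splitting, training mechanics, voting, metrics, retrieval, mixing score."""

import numpy as np
import pytest

from deathscreen import nn
from deathscreen.augmentation import AugmentConfig
from deathscreen.batch_sampler import SamplerConfig
from deathscreen.core_data import filter_by_viability, normalize_manifest_atp
from deathscreen.network import BackboneSpec, HeadSpec, PhenotypeModel
from deathscreen.objectives import LossConfig
from deathscreen.train_eval import (
    FieldPrediction,
    Gallery,
    ImageCache,
    RetrievalConfig,
    TrainConfig,
    evaluate,
    plate_mixing_score,
    predict_fields,
    retrieve,
    split_dataset,
    train,
    well_vote,
)
from tests.conftest import make_manifest


class TestSplitDataset:
    def test_eighty_twenty_per_class(self):
        manifest = make_manifest(n_plates=1, wells_per_class=10, fields_per_well=2)
        tr, te = split_dataset(manifest, TrainConfig(seed=0))
        for cls in ("healthy", "apoptosis", "ferroptosis"):
            n_tr = sum(1 for w in tr.wells() if tr.well_label(*w) == cls)
            n_te = sum(1 for w in te.wells() if te.well_label(*w) == cls)
            assert (n_tr, n_te) == (8, 2)

    def test_no_leakage(self):
        manifest = make_manifest(n_plates=2, wells_per_class=5, fields_per_well=3)
        tr, te = split_dataset(manifest, TrainConfig(seed=1))
        tr_ids = {r.image_id for r in tr.images}
        te_ids = {r.image_id for r in te.images}
        assert not tr_ids & te_ids
        assert tr_ids | te_ids == {r.image_id for r in manifest.images}
        assert not set(tr.wells()) & set(te.wells())

    def test_deterministic_per_seed(self):
        manifest = make_manifest(n_plates=2, wells_per_class=5)
        a = split_dataset(manifest, TrainConfig(seed=7))
        b = split_dataset(manifest, TrainConfig(seed=7))
        assert a[0].wells() == b[0].wells() and a[1].wells() == b[1].wells()

    def test_single_well_class_raises(self):
        manifest = make_manifest(n_plates=1, wells_per_class=1)
        with pytest.raises(ValueError, match="healthy|apoptosis|ferroptosis"):
            split_dataset(manifest, TrainConfig(seed=0))

    def test_small_classes_still_split_both_sides(self):
        manifest = make_manifest(n_plates=1, wells_per_class=2)
        tr, te = split_dataset(manifest, TrainConfig(seed=3))
        for cls in ("healthy", "apoptosis", "ferroptosis"):
            assert any(tr.well_label(*w) == cls for w in tr.wells())
            assert any(te.well_label(*w) == cls for w in te.wells())


@pytest.fixture(scope="module")
def filtered_tiny(tiny_experiment):
    _, manifest = tiny_experiment
    return filter_by_viability(normalize_manifest_atp(manifest))


def _desk_configs(epochs=5, lambda1=0.5):
    return dict(
        loss_cfg=LossConfig(lambda1=lambda1),
        sampler_cfg=SamplerConfig(n_plates=2, n_samples=2, n_classes=3, seed=1),
        train_cfg=TrainConfig(learning_rate=1e-3, epochs=epochs, seed=1),
        augment_cfg=AugmentConfig(crop_size=32),
    )


class TestTraining:
    def test_loss_decreases(self, filtered_tiny):
        model = PhenotypeModel(BackboneSpec(), HeadSpec(), seed=0)
        result = train(filtered_tiny, model, **_desk_configs(epochs=6))
        assert result.history[-1]["total"] < result.history[0]["total"]

    def test_ablation_changes_trajectory(self, filtered_tiny):
        params = []
        for lambda1 in (0.5, 0.0):
            model = PhenotypeModel(BackboneSpec(), HeadSpec(), seed=0)
            train(filtered_tiny, model, **_desk_configs(epochs=1, lambda1=lambda1))
            params.append(np.concatenate([p.value.ravel() for p in model.params()]))
        assert not np.array_equal(params[0], params[1])

    def test_frozen_batchnorm_stats_unchanged(self, filtered_tiny):
        model = PhenotypeModel(BackboneSpec(), HeadSpec(), seed=0)
        stats_before = [
            (layer.running_mean.copy(), layer.running_var.copy())
            for layer in model.backbone.layers
            if isinstance(layer, nn.BatchNorm2d)
        ]
        train(filtered_tiny, model, **_desk_configs(epochs=1))
        stats_after = [
            (layer.running_mean, layer.running_var)
            for layer in model.backbone.layers
            if isinstance(layer, nn.BatchNorm2d)
        ]
        for (m0, v0), (m1, v1) in zip(stats_before, stats_after):
            assert np.array_equal(m0, m1) and np.array_equal(v0, v1)


class TestPredictFields:
    def test_probabilities_and_determinism(self, filtered_tiny):
        model = PhenotypeModel(BackboneSpec(), HeadSpec(), seed=2)
        sub = filtered_tiny.subset(filtered_tiny.wells()[:2])
        cache = ImageCache()
        a = predict_fields(model, sub, crop_size=32, cache=cache)
        b = predict_fields(model, sub, crop_size=32, cache=cache)
        for pa, pb in zip(a, b):
            assert pa.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.array_equal(pa.probabilities, pb.probabilities)


def _toy_predictions(labels_with_probs, manifest):
    preds = []
    for rec, (label, probs) in zip(manifest.images, labels_with_probs):
        preds.append(FieldPrediction(rec.image_id, np.asarray(probs), label))
    return preds


class TestWellVote:
    def _manifest(self, n_fields):
        return make_manifest(
            n_plates=1, wells_per_class=1, fields_per_well=n_fields,
            classes=("ferroptosis",), with_atp=False,
        )

    def test_unanimous(self):
        m = self._manifest(9)
        p_fer = [0.05, 0.05, 0.9]
        preds = _toy_predictions([("ferroptosis", p_fer)] * 9, m)
        (w,) = well_vote(preds, m)
        assert w.label == "ferroptosis" and not w.tie_broken
        assert w.votes == {"healthy": 0, "apoptosis": 0, "ferroptosis": 9}

    def test_tie_broken_by_summed_probability(self):
        """4-4-1 apoptosis/ferroptosis tie resolves to the class with the
        larger summed probability."""
        m = self._manifest(9)
        rows = (
            [("apoptosis", [0.1, 0.5, 0.4])] * 4
            + [("ferroptosis", [0.05, 0.15, 0.8])] * 4
            + [("healthy", [0.5, 0.25, 0.25])]
        )
        (w,) = well_vote(_toy_predictions(rows, m), m)
        assert w.votes == {"healthy": 1, "apoptosis": 4, "ferroptosis": 4}
        assert w.label == "ferroptosis" and w.tie_broken

    def test_strict_majority_ignores_probabilities(self):
        m = self._manifest(9)
        rows = (
            [("healthy", [0.4, 0.3, 0.3])] * 5
            + [("apoptosis", [0.0, 1.0, 0.0])] * 3
            + [("ferroptosis", [0.0, 0.0, 1.0])]
        )
        (w,) = well_vote(_toy_predictions(rows, m), m)
        assert w.label == "healthy" and not w.tie_broken

    def test_vote_counts_sum_to_fields(self):
        m = self._manifest(7)
        rows = [("apoptosis", [0.2, 0.6, 0.2])] * 7
        (w,) = well_vote(_toy_predictions(rows, m), m)
        assert sum(w.votes.values()) == 7


class TestEvaluate:
    def test_perfect_predictions(self):
        y = ["healthy", "apoptosis", "ferroptosis"] * 3
        r = evaluate(y, y)
        assert r.accuracy == 1.0 and r.macro_f1 == 1.0
        assert np.array_equal(np.diag(r.confusion), [3, 3, 3])

    def test_hand_computed_confusion(self):
        """Confusion [[2,1,0],[0,3,0],[1,0,2]]: accuracy 7/9 and macro-F1
        from the per-class harmonic means."""
        y_true = ["healthy"] * 3 + ["apoptosis"] * 3 + ["ferroptosis"] * 3
        y_pred = (
            ["healthy", "healthy", "apoptosis"]
            + ["apoptosis"] * 3
            + ["healthy", "ferroptosis", "ferroptosis"]
        )
        r = evaluate(y_true, y_pred)
        assert r.accuracy == pytest.approx(7 / 9)
        f1_h = 2 * (2 / 3) * (2 / 3) / ((2 / 3) + (2 / 3))
        f1_a = 2 * (3 / 4) * 1.0 / ((3 / 4) + 1.0)
        f1_f = 2 * 1.0 * (2 / 3) / (1.0 + (2 / 3))
        assert r.macro_f1 == pytest.approx((f1_h + f1_a + f1_f) / 3)
        assert np.array_equal(r.confusion, [[2, 1, 0], [0, 3, 0], [1, 0, 2]])

    def test_order_invariance(self, rng):
        y_true = ["healthy"] * 4 + ["apoptosis"] * 3 + ["ferroptosis"] * 5
        y_pred = ["healthy"] * 3 + ["apoptosis"] * 5 + ["ferroptosis"] * 4
        r1 = evaluate(y_true, y_pred)
        perm = rng.permutation(len(y_true))
        r2 = evaluate([y_true[i] for i in perm], [y_pred[i] for i in perm])
        assert r1.accuracy == r2.accuracy and r1.macro_f1 == r2.macro_f1

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            evaluate(["healthy"], ["healthy", "apoptosis"])


class TestRetrieve:
    def test_exact_match_is_rank_one(self, rng):
        g = rng.normal(size=(10, 4))
        gallery = Gallery(g, [f"g{i}" for i in range(10)], ["healthy"] * 10)
        hits = retrieve(g[3], gallery, RetrievalConfig(k=1))
        assert hits[0][0].gallery_id == "g3"
        assert hits[0][0].similarity == pytest.approx(1.0)

    def test_k10_ordered(self, rng):
        g = rng.normal(size=(30, 8))
        gallery = Gallery(g, [f"g{i:02d}" for i in range(30)], ["apoptosis"] * 30)
        hits = retrieve(rng.normal(size=8), gallery, RetrievalConfig(k=10))[0]
        assert len(hits) == 10
        sims = [h.similarity for h in hits]
        assert sims == sorted(sims, reverse=True)

    def test_matches_bruteforce_scan(self, rng):
        """Agrees with an O(N*M) loop on random 50x20 instances."""
        g = rng.normal(size=(20, 6))
        q = rng.normal(size=(50, 6))
        gallery = Gallery(g, [f"g{i:02d}" for i in range(20)], ["healthy"] * 20)
        hits = retrieve(q, gallery, RetrievalConfig(k=3))
        gn = g / np.linalg.norm(g, axis=1, keepdims=True)
        qn = q / np.linalg.norm(q, axis=1, keepdims=True)
        for qi in range(50):
            sims = [(float(qn[qi] @ gn[j]), f"g{j:02d}") for j in range(20)]
            expected = sorted(sims, key=lambda t: (-t[0], t[1]))[:3]
            got = [(h.similarity, h.gallery_id) for h in hits[qi]]
            for (es, eid), (gs, gid) in zip(expected, got):
                assert eid == gid and gs == pytest.approx(es)

    def test_k_exceeding_gallery_raises(self, rng):
        gallery = Gallery(rng.normal(size=(3, 2)), ["a", "b", "c"], ["healthy"] * 3)
        with pytest.raises(ValueError, match="exceeds gallery"):
            retrieve(rng.normal(size=2), gallery, RetrievalConfig(k=4))


class TestPlateMixingScore:
    def test_identical_embeddings_enumeration_oracle(self):
        """All-identical embeddings: ties resolve by sample index, so the
        k nearest of sample i are the first k indices != i."""
        plates = np.array(["A", "B", "A", "B", "A", "B"])
        z = np.ones((6, 3))
        k = 2
        expected = np.mean(
            [
                np.mean([plates[j] == plates[i] for j in range(6) if j != i][:k])
                for i in range(6)
            ]
        )
        assert plate_mixing_score(z, plates, k=k) == pytest.approx(expected)

    def test_separated_plates_score_one(self):
        z = np.vstack([np.tile([1.0, 0.0], (5, 1)), np.tile([0.0, 1.0], (5, 1))])
        plates = ["A"] * 5 + ["B"] * 5
        assert plate_mixing_score(z, plates, k=3) == 1.0

    def test_random_balanced_embeddings_near_half(self, rng):
        z = rng.normal(size=(200, 16))
        plates = ["A", "B"] * 100
        score = plate_mixing_score(z, plates, k=10)
        assert abs(score - 0.5) < 0.1

    def test_errors(self, rng):
        z = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="2 plates"):
            plate_mixing_score(z, ["A"] * 5, k=2)
        with pytest.raises(ValueError, match="smaller"):
            plate_mixing_score(z, ["A", "B", "A", "B", "A"], k=5)
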