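"""Manifest I/O, ATP normalisation, viability filtering, titration design."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

from deathscreen.core_data import (
    AtpRecord,
    ExperimentManifest,
    ImageFormatError,
    ImageRecord,
    JoinError,
    SchemaError,
    ViabilityFilterConfig,
    concentration_series,
    filter_by_viability,
    normalize_atp,
    normalize_manifest_atp,
    read_field_image,
    read_manifest,
    write_field_image,
)
from tests.conftest import make_manifest

# Printed five-point titrations of the 14 screened inducers:
# (name, [+], IC50, [-], [--], [---]) in µM.
TITRATION_TABLE = [
    ("staurosporine", 0.04748, 0.02374, 0.01187, 0.0059, 0.003),
    ("vinblastine", 0.00222, 0.00111, 0.000555, 0.0003, 0.0001),
    ("paclitaxel", 110.24, 55.12, 27.56, 13.78, 6.89),
    ("etoposide", 67.48, 33.74, 16.87, 8.435, 4.2175),
    ("actinomycin-d", 0.00151, 0.0007552, 0.0003776, 0.0002, 9.0e-05),
    ("doxorubicin", 0.2472, 0.1236, 0.0618, 0.0309, 0.0155),
    ("niclosamide", 6.78, 3.39, 1.695, 0.8475, 0.4238),
    ("rsl3", 0.06028, 0.03014, 0.01507, 0.0075, 0.0038),
    ("ml162", 0.09572, 0.04786, 0.02393, 0.012, 0.006),
    ("ml210", 0.4704, 0.2352, 0.1176, 0.0588, 0.0294),
    ("erastin", 5.132, 2.566, 1.283, 0.6415, 0.3208),
    ("ike", 1.396, 0.698, 0.349, 0.1745, 0.0873),
    ("fino2", 4.284, 2.142, 1.071, 0.5355, 0.2678),
    ("fin56", 0.3106, 0.1553, 0.07765, 0.0388, 0.0194),
]
# Lower rows printed with one significant figure; exempt from the 2% check.
ROUNDED_LOW_ROWS = {"vinblastine", "actinomycin-d"}


class TestManifestIO:
    def test_round_trip(self, tmp_path):
        m = make_manifest(n_plates=1, wells_per_class=1, fields_per_well=2)
        m.images_frame().to_csv(tmp_path / "manifest.csv", index=False)
        m.atp_frame().drop(columns=["normalized_viability"]).to_csv(
            tmp_path / "atp.csv", index=False
        )
        back = read_manifest(tmp_path / "manifest.csv", tmp_path / "atp.csv")
        assert back.images == m.images
        assert [(a.plate_id, a.well_id, a.raw_atp) for a in back.atp] == [
            (a.plate_id, a.well_id, a.raw_atp) for a in m.atp
        ]

    def test_synthetic_experiment_round_trip(self, tiny_experiment):
        out, manifest = tiny_experiment
        back = read_manifest(out / "manifest.csv", out / "atp.csv")
        assert back.images == manifest.images

    def test_missing_atp_well_is_join_error(self, tmp_path):
        m = make_manifest(n_plates=1, wells_per_class=1)
        mdf = m.images_frame()
        mdf.loc[0, "well_id"] = "C05"
        mdf.to_csv(tmp_path / "manifest.csv", index=False)
        m.atp_frame().to_csv(tmp_path / "atp.csv", index=False)
        with pytest.raises(JoinError, match="C05"):
            read_manifest(tmp_path / "manifest.csv", tmp_path / "atp.csv")

    def test_missing_column_is_schema_error(self, tmp_path):
        m = make_manifest(n_plates=1, wells_per_class=1)
        m.images_frame().drop(columns=["compound"]).to_csv(
            tmp_path / "manifest.csv", index=False
        )
        m.atp_frame().to_csv(tmp_path / "atp.csv", index=False)
        with pytest.raises(SchemaError, match="compound"):
            read_manifest(tmp_path / "manifest.csv", tmp_path / "atp.csv")

    def test_duplicate_image_id_rejected(self):
        m = make_manifest(n_plates=1, wells_per_class=1)
        with pytest.raises(SchemaError, match="duplicate"):
            ExperimentManifest(images=m.images + [m.images[0]], atp=m.atp)

    def test_dmso_well_must_be_healthy(self):
        with pytest.raises(SchemaError, match="healthy"):
            ImageRecord(
                image_id="x", plate_id="p", well_id="A01", field_index=0,
                compound="DMSO", concentration_um=0.0,
                class_label="apoptosis", path="/x.tiff",
            )


class TestNormalizeAtp:
    def _records(self, values, plate="p1"):
        return [
            AtpRecord(plate, f"A{i + 1:02d}", raw_atp=v) for i, v in enumerate(values)
        ]

    def test_dmso_median_maps_to_one(self):
        recs = self._records([900.0, 1000.0, 1100.0, 500.0])
        out = normalize_atp(recs, {"A01", "A02", "A03"})
        assert out[1].normalized_viability == pytest.approx(1.0)
        assert out[3].normalized_viability == pytest.approx(0.5)

    def test_no_dmso_wells_raises(self):
        with pytest.raises(ValueError, match="no DMSO"):
            normalize_atp(self._records([1000.0]), set())

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        values=st.lists(
            st.floats(min_value=1.0, max_value=1e5), min_size=3, max_size=8
        ),
    )
    def test_scale_invariance(self, scale, values):
        recs = self._records(values)
        base = normalize_atp(recs, {"A01", "A02"})
        scaled = normalize_atp(
            self._records([v * scale for v in values]), {"A01", "A02"}
        )
        for a, b in zip(base, scaled):
            assert b.normalized_viability == pytest.approx(
                a.normalized_viability, rel=1e-9
            )


class TestViabilityFilter:
    def _manifest_with_viabilities(self, viabilities):
        m = make_manifest(
            n_plates=1, wells_per_class=len(viabilities), classes=("apoptosis",),
            with_atp=False,
        )
        atp = [
            AtpRecord("plate01", f"A{i + 1:02d}", raw_atp=1.0, normalized_viability=v)
            for i, v in enumerate(viabilities)
        ]
        return ExperimentManifest(images=m.images, atp=atp)

    def test_brute_force_interval(self):
        vs = [0.1, 0.3, 0.5, 0.8, 0.9]
        m = self._manifest_with_viabilities(vs)
        kept = filter_by_viability(m)
        cfg = ViabilityFilterConfig()
        expected = {  # independent brute-force interval check
            m.atp[i].well_id for i, v in enumerate(vs) if cfg.lower <= v <= cfg.upper
        }
        assert {w for _, w in kept.wells()} == expected == {"A02", "A03", "A04"}

    def test_upper_boundary_inclusive(self):
        m = self._manifest_with_viabilities([0.8])
        assert len(filter_by_viability(m).wells()) == 1

    def test_healthy_wells_exempt(self):
        base = make_manifest(n_plates=1, wells_per_class=2, with_atp=False)
        atp = [
            AtpRecord(p, w, raw_atp=1.0, normalized_viability=1.0)
            for p, w in {r.well_key for r in base.images}
        ]
        m = ExperimentManifest(images=base.images, atp=atp)
        kept = filter_by_viability(m)
        labels = {m.well_label(p, w) for p, w in kept.wells()}
        assert labels == {"healthy"}  # treated wells at v=1.0 all dropped

    def test_idempotent(self):
        m = self._manifest_with_viabilities([0.2, 0.5, 0.7, 1.0])
        once = filter_by_viability(m)
        twice = filter_by_viability(once)
        assert twice.wells() == once.wells()


class TestConcentrationSeries:
    def test_unit_case(self):
        assert concentration_series(1.0).tolist() == [2.0, 1.0, 0.5, 0.25, 0.125]

    def test_two_fold_ratios_exact(self):
        s = concentration_series(0.02374)
        assert all(s[i] / s[i + 1] == 2.0 for i in range(4))

    def test_non_positive_ic50_raises(self):
        for bad in (0.0, -1.0, float("nan")):
            with pytest.raises(ValueError):
                concentration_series(bad)

    @pytest.mark.parametrize(
        "name,plus,ic50", [(r[0], r[1], r[2]) for r in TITRATION_TABLE]
    )
    def test_plus_step_matches_printed_values(self, name, plus, ic50):
        assert concentration_series(ic50)[0] == pytest.approx(plus, rel=1e-3)

    @pytest.mark.parametrize("row", TITRATION_TABLE, ids=[r[0] for r in TITRATION_TABLE])
    def test_lower_steps_match_printed_values(self, row):
        name, _, ic50, minus, minus2, minus3 = row
        series = concentration_series(ic50)
        assert series[2] == pytest.approx(minus, rel=0.02)
        if name not in ROUNDED_LOW_ROWS:
            assert series[3] == pytest.approx(minus2, rel=0.02)
            assert series[4] == pytest.approx(minus3, rel=0.02)


class TestFieldImageIO:
    def test_constant_zero_image(self, tmp_path):
        path = tmp_path / "zero.tiff"
        tifffile.imwrite(path, np.zeros((4, 64, 64), dtype=np.uint16), photometric="minisblack")
        img = read_field_image(path)
        assert img.shape == (4, 64, 64)
        assert np.all(img == 0)

    def test_write_read_round_trip(self, tmp_path, rng):
        img = rng.random((4, 32, 32)).astype(np.float32)
        path = tmp_path / "f.tiff"
        write_field_image(path, img)
        back = read_field_image(path, rescale=False)
        assert np.abs(back - img).max() <= 1.0 / 65535 + 1e-7

    def test_interleaved_layout_accepted(self, tmp_path, rng):
        data = (rng.random((16, 16, 4)) * 65535).astype(np.uint16)
        path = tmp_path / "hw4.tiff"
        tifffile.imwrite(path, data)
        img = read_field_image(path, rescale=False)
        assert img.shape == (4, 16, 16)

    def test_three_channel_rejected(self, tmp_path):
        path = tmp_path / "rgb.tiff"
        tifffile.imwrite(path, np.zeros((3, 16, 16), dtype=np.uint16), photometric="minisblack")
        with pytest.raises(ImageFormatError, match="4 channels"):
            read_field_image(path)

    def test_rescale_stretches_to_unit_range(self, tmp_path, rng):
        img = 0.2 + 0.1 * rng.random((4, 64, 64)).astype(np.float32)
        path = tmp_path / "lo.tiff"
        write_field_image(path, img)
        out = read_field_image(path, rescale=True)
        assert out.min() == 0.0 and out.max() == 1.0


def test_normalize_manifest_atp_per_plate(tiny_experiment):
    _, manifest = tiny_experiment
    normed = normalize_manifest_atp(manifest)
    for plate in normed.plates():
        dmso = normed.dmso_wells(plate)
        vals = [
            a.normalized_viability for a in normed.atp
            if a.plate_id == plate and a.well_id in dmso
        ]
        assert np.median(vals) == pytest.approx(1.0)
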