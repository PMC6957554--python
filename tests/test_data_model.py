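import numpy as np
import pandas as pd
import pytest

from mpus.data_model import (
    LABEL_BENIGN,
    LABEL_MALIGNANT,
    ZONE_PZ,
    ZONE_TZ,
    DcePlane,
    FeatureTable,
    PlaneBundle,
    RunConfig,
    bundle_paths,
    disk_offsets,
    feature_catalog,
    linearize_intensity,
    load_plane_bundle,
    log_compress_intensity,
    radius_mm_to_px,
    read_feature_table,
    ring_offsets,
    save_plane_bundle,
    write_feature_table,
)


def _tiny_bundle(n_frames=8, shape=(12, 16)):
    rng = np.random.default_rng(0)
    frames = rng.random((n_frames, *shape)).astype(np.float32)
    dce = DcePlane(frames=frames, timestamps=np.arange(n_frames, dtype=float) * 12.0,
                   pixel_spacing=(0.167, 0.167), patient_id="P00", plane_id="mid")
    prostate = np.zeros(shape, bool)
    prostate[3:9, 4:12] = True
    zone = np.zeros(shape, np.uint8)
    zone[prostate] = ZONE_PZ
    zone[5:7, 6:10] = ZONE_TZ
    roi = np.zeros(shape, np.uint8)
    roi[4, 5] = LABEL_BENIGN
    roi[7, 10] = LABEL_MALIGNANT
    return PlaneBundle(dce=dce, bmode=rng.random(shape) * 200,
                       swe=rng.random(shape) * 80 + 10,
                       prostate_mask=prostate, zone_mask=zone, roi_labels=roi)


class TestDcePlane:
    def test_timestamps_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            DcePlane(np.zeros((3, 4, 4)), [0.0, 2.0, 1.0], (0.167, 0.167))

    def test_negative_frames_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            DcePlane(-np.ones((2, 4, 4)), [0.0, 1.0], (0.167, 0.167))

    def test_constructed_loop_has_expected_timestamps(self):
        # 601 frames at 5 Hz span exactly 120 s
        t = np.arange(601) / 5.0
        plane = DcePlane(np.zeros((601, 4, 4)), t, (0.167, 0.167))
        assert plane.n_frames == 601
        assert np.all(np.diff(plane.timestamps) > 0)
        assert plane.timestamps[-1] == pytest.approx(120.0)


class TestPlaneBundle:
    def test_zone_label_outside_prostate_rejected(self):
        b = _tiny_bundle()
        zone = b.zone_mask.copy()
        zone[0, 0] = ZONE_PZ  # outside the prostate mask
        with pytest.raises(ValueError, match="outside"):
            PlaneBundle(dce=b.dce, bmode=b.bmode, swe=b.swe,
                        prostate_mask=b.prostate_mask, zone_mask=zone)

    def test_unzoned_prostate_pixel_rejected(self):
        b = _tiny_bundle()
        zone = b.zone_mask.copy()
        zone[4, 5] = 0
        with pytest.raises(ValueError, match="PZ or TZ"):
            PlaneBundle(dce=b.dce, bmode=b.bmode, swe=b.swe,
                        prostate_mask=b.prostate_mask, zone_mask=zone)

    def test_roi_outside_prostate_rejected(self):
        b = _tiny_bundle()
        roi = b.roi_labels.copy()
        roi[0, 0] = LABEL_MALIGNANT
        with pytest.raises(ValueError, match="inside the prostate"):
            PlaneBundle(dce=b.dce, bmode=b.bmode, swe=b.swe,
                        prostate_mask=b.prostate_mask, zone_mask=b.zone_mask,
                        roi_labels=roi)

    def test_shape_mismatch_rejected(self):
        b = _tiny_bundle()
        with pytest.raises(ValueError, match="shape"):
            PlaneBundle(dce=b.dce, bmode=np.zeros((5, 5)), swe=b.swe,
                        prostate_mask=b.prostate_mask, zone_mask=b.zone_mask)


class TestBundleIO:
    def test_round_trip_bit_identical(self, tmp_path):
        b = _tiny_bundle()
        paths = save_plane_bundle(b, tmp_path / "plane")
        loaded = load_plane_bundle(paths)
        assert np.array_equal(loaded.dce.frames, b.dce.frames)
        assert np.array_equal(loaded.dce.timestamps, b.dce.timestamps)
        assert np.array_equal(loaded.zone_mask, b.zone_mask)
        assert np.array_equal(loaded.roi_labels, b.roi_labels)
        assert loaded.patient_id == "P00" and loaded.plane_id == "mid"

    def test_missing_role_named_in_error(self, tmp_path):
        b = _tiny_bundle()
        paths = save_plane_bundle(b, tmp_path / "plane")
        del paths["swe"]
        with pytest.raises(FileNotFoundError, match="swe"):
            load_plane_bundle(paths)

    def test_missing_file_named_in_error(self, tmp_path):
        b = _tiny_bundle()
        paths = save_plane_bundle(b, tmp_path / "plane")
        paths["bmode"].unlink()
        with pytest.raises(FileNotFoundError, match="bmode"):
            load_plane_bundle(paths)

    def test_grid_mismatch_rejected_not_resampled(self, tmp_path):
        import tifffile

        b = _tiny_bundle()
        paths = save_plane_bundle(b, tmp_path / "plane")
        tifffile.imwrite(paths["swe"], np.zeros((5, 7), np.float32))
        with pytest.raises(ValueError, match="grid"):
            load_plane_bundle(paths)

    def test_bundle_paths_roundtrip(self, tmp_path):
        b = _tiny_bundle()
        save_plane_bundle(b, tmp_path / "plane")
        loaded = load_plane_bundle(bundle_paths(tmp_path / "plane"))
        assert np.array_equal(loaded.prostate_mask, b.prostate_mask)


class TestLinearization:
    def test_zero_maps_to_one(self):
        assert linearize_intensity(np.array(0.0)) == pytest.approx(1.0)

    def test_full_scale_40db(self):
        assert linearize_intensity(np.array(255.0), 40.0) == pytest.approx(1e4)

    def test_round_trip_all_gray_levels(self):
        x = np.arange(256, dtype=float)
        back = log_compress_intensity(linearize_intensity(x, 40.0), 40.0)
        assert np.allclose(back, x, atol=1e-10)

    def test_nonpositive_dynamic_range_rejected(self):
        with pytest.raises(ValueError):
            linearize_intensity(np.zeros(3), 0.0)


class TestFeatureTableIO:
    def _table(self, n=100):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "patient_id": rng.choice(["Pa", "Pb"], n), "plane_id": "mid",
            "row": rng.integers(0, 9, n), "col": rng.integers(0, 9, n),
            "zone": rng.choice([ZONE_PZ, ZONE_TZ], n),
            "label": rng.choice([0, LABEL_BENIGN, LABEL_MALIGNANT], n),
            "calcified": rng.random(n) < 0.1,
            "a": rng.normal(size=n), "b": rng.normal(size=n),
        })
        return FeatureTable(df, ["a", "b"])

    def test_round_trip(self, tmp_path):
        t = self._table()
        write_feature_table(t, tmp_path / "t.csv")
        back = read_feature_table(tmp_path / "t.csv")
        assert back.feature_columns == t.feature_columns
        pd.testing.assert_frame_equal(back.df, t.df, check_dtype=False)

    def test_manifest_mismatch_rejected(self, tmp_path):
        t = self._table()
        write_feature_table(t, tmp_path / "t.csv")
        text = (tmp_path / "t.csv").read_text()
        (tmp_path / "t.csv").write_text(
            text.replace("#manifest: a,b", "#manifest: b,a"))
        with pytest.raises(ValueError, match="manifest"):
            read_feature_table(tmp_path / "t.csv")

    def test_empty_table_round_trip(self, tmp_path):
        t = self._table()
        empty = t.subset(np.zeros(len(t), bool))
        write_feature_table(empty, tmp_path / "e.csv")
        back = read_feature_table(tmp_path / "e.csv")
        assert len(back) == 0
        assert back.feature_columns == ["a", "b"]

    def test_outside_zone_rows_rejected(self):
        t = self._table()
        df = t.df.copy()
        df.loc[0, "zone"] = 0
        with pytest.raises(ValueError, match="outside"):
            FeatureTable(df, t.feature_columns)


class TestConfigAndGeometry:
    def test_config_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=99, entropy_bins=16)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = RunConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_unknown_config_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("not_a_field: 3\n")
        with pytest.raises(ValueError, match="unknown"):
            RunConfig.from_yaml(tmp_path / "c.yaml")

    def test_invalid_config_values_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(subsample_fraction=0.0)
        with pytest.raises(ValueError):
            RunConfig(ring_inner_mm=2.0, ring_outer_mm=1.0)

    def test_radius_conversion(self):
        assert radius_mm_to_px(1.0, 0.167) == 6
        assert radius_mm_to_px(2.0, 0.167) == 12
        assert radius_mm_to_px(0.01, 0.167) == 1  # never below one pixel

    def test_disk_offsets_symmetric(self):
        offs = disk_offsets(3)
        assert {(int(-r), int(-c)) for r, c in offs} == {(int(r), int(c))
                                                         for r, c in offs}

    def test_ring_offsets_default_has_enough_members(self):
        offs, d = ring_offsets(0.5, 2.0, 0.167, max_members=16)
        assert len(offs) == 16
        assert np.all(d >= 0.5) and np.all(d <= 2.0)
        full, _ = ring_offsets(0.5, 2.0, 0.167, max_members=None)
        assert len(full) >= 8

    def test_feature_catalog_census(self):
        cat = feature_catalog()
        assert len(cat) == 84
        assert cat[:6] == ["Pe", "Pe.rel", "Pe.ent1", "Pe.ent2", "Pe.ent3",
                           "Pe.var2"]
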