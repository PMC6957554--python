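import collections

import numpy as np
import pytest

from mpus.data_model import BASE_FEATURES, ParamMap, RunConfig, disk_offsets
from mpus.map_radiomics import (
    bin_assignments,
    detect_calcifications,
    entropy_bin_edges,
    local_entropy,
    local_variance,
    radiomic_expand,
    relative_to_median,
)

SP = 0.167


def _random_map(rng, shape=(40, 44), invalid_frac=0.15, name="mu"):
    vals = rng.normal(size=shape)
    valid = rng.random(shape) > invalid_frac
    return ParamMap(name, vals, valid, "s")


class TestRelativeToMedian:
    def test_constant_map_zeroed(self):
        pm = ParamMap("mu", np.full((5, 5), 3.0), np.ones((5, 5), bool), "s")
        rel = relative_to_median(pm, np.ones((5, 5), bool))
        assert np.allclose(rel.values[rel.valid], 0.0)

    def test_three_value_example(self):
        vals = np.array([[1.0, 2.0, 3.0]])
        pm = ParamMap("mu", vals, np.ones_like(vals, bool), "s")
        rel = relative_to_median(pm, np.ones_like(vals, bool))
        assert np.allclose(rel.values, [[-1.0, 0.0, 1.0]])

    def test_output_median_is_zero(self, rng):
        for _ in range(5):
            pm = _random_map(rng)
            mask = rng.random(pm.values.shape) > 0.3
            rel = relative_to_median(pm, mask)
            inmask = rel.valid
            if inmask.any():
                assert np.median(rel.values[inmask]) == pytest.approx(0.0, abs=1e-12)

    def test_no_valid_pixels_gives_empty_map(self):
        pm = ParamMap("mu", np.full((4, 4), np.nan), np.zeros((4, 4), bool), "s")
        rel = relative_to_median(pm, np.ones((4, 4), bool))
        assert not rel.valid.any()

    def test_ratio_mode_on_positive_map(self, rng):
        pm = ParamMap("E", rng.uniform(10, 90, (8, 8)), np.ones((8, 8), bool), "kPa")
        cfg = RunConfig(relative_mode="ratio")
        rel = relative_to_median(pm, np.ones((8, 8), bool), cfg)
        assert np.median(rel.values[rel.valid]) == pytest.approx(1.0, abs=1e-12)


class TestLocalEntropy:
    def test_constant_map_zero_bits(self):
        pm = ParamMap("mu", np.full((20, 20), 2.0), np.ones((20, 20), bool), "s")
        ent = local_entropy(pm, 1.0, SP)
        assert np.all(ent.values[ent.valid] == 0.0)

    def test_two_equal_frequency_values_one_bit(self):
        # exactly ten valid kernel members of each of two values
        vals = np.zeros((30, 30))
        valid = np.zeros((30, 30), bool)
        offs = [o for o in disk_offsets(max(1, round(1.0 / SP))).tolist()
                if o != [0, 0]][:19]
        for i, (dr, dc) in enumerate(offs):
            valid[15 + dr, 15 + dc] = True
            vals[15 + dr, 15 + dc] = 0.0 if i < 9 else 1.0
        valid[15, 15] = True  # center is the tenth zero-valued member
        pm = ParamMap("mu", vals, valid, "s")
        ent = local_entropy(pm, 1.0, SP)
        assert ent.values[15, 15] == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_histogram_entropy(self, rng):
        cfg = RunConfig()
        pm = _random_map(rng, shape=(30, 32))
        ent = local_entropy(pm, 1.0, SP, cfg)
        r_px = max(1, round(1.0 / SP))
        offs = disk_offsets(r_px)
        edges = entropy_bin_edges(pm.values, pm.valid, cfg.entropy_bins)
        H, W = pm.values.shape
        for r in range(3, H - 3, 5):
            for c in range(3, W - 3, 5):
                members = [pm.values[r + dr, c + dc] for dr, dc in offs
                           if 0 <= r + dr < H and 0 <= c + dc < W
                           and pm.valid[r + dr, c + dc]]
                if not pm.valid[r, c] or len(members) < 10:
                    assert not ent.valid[r, c]
                    continue
                bi = bin_assignments(np.asarray(members), edges)
                n = len(members)
                brute = -sum((cnt / n) * np.log2(cnt / n)
                             for cnt in collections.Counter(bi.tolist()).values())
                assert ent.values[r, c] == pytest.approx(brute, abs=1e-12)

    def test_invalid_center_propagates(self, rng):
        pm = _random_map(rng)
        ent = local_entropy(pm, 2.0, SP)
        assert not ent.valid[~pm.valid].any()


class TestLocalVariance:
    def test_constant_map_zero(self):
        pm = ParamMap("mu", np.full((20, 20), 5.0), np.ones((20, 20), bool), "s")
        var = local_variance(pm, SP)
        assert np.allclose(var.values[var.valid], 0.0)

    def test_two_member_closed_form(self):
        # only two valid values {0, 2} inside the kernel: unbiased variance 2
        vals = np.zeros((30, 30))
        valid = np.zeros((30, 30), bool)
        vals[15, 15], vals[15, 16] = 0.0, 2.0
        valid[15, 15] = valid[15, 16] = True
        pm = ParamMap("mu", vals, valid, "s")
        var = local_variance(pm, SP)
        assert var.values[15, 15] == pytest.approx(2.0, abs=1e-12)

    def test_matches_bruteforce_variance(self, rng):
        cfg = RunConfig()
        pm = _random_map(rng, shape=(28, 30))
        var = local_variance(pm, SP, cfg)
        r_px = max(1, round(cfg.variance_radius_mm / SP))
        offs = disk_offsets(r_px)
        H, W = pm.values.shape
        for r in range(2, H - 2, 4):
            for c in range(2, W - 2, 4):
                members = [pm.values[r + dr, c + dc] for dr, dc in offs
                           if 0 <= r + dr < H and 0 <= c + dc < W
                           and pm.valid[r + dr, c + dc]]
                if not pm.valid[r, c] or len(members) < 2:
                    assert not var.valid[r, c]
                    continue
                assert var.values[r, c] == pytest.approx(
                    np.var(members, ddof=1), abs=1e-12)


class TestCalcificationDetection:
    def _speckle(self, rng, shape=(90, 110), mean=100.0):
        return mean * rng.gamma(6.0, 1 / 6.0, shape)

    def test_uniform_image_empty_mask(self):
        mask = np.ones((40, 40), bool)
        det = detect_calcifications(np.full((40, 40), 80.0), mask, SP)
        assert not det.any()

    def test_bright_disks_detected_dark_ignored(self, rng):
        shape = (90, 110)
        img = self._speckle(rng, shape)
        mask = np.ones(shape, bool)
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        truth = np.zeros(shape, bool)
        # bright spots of ~1.2 mm and ~3.6 mm diameter (radius 4 / 11 px)
        for (r0, c0, rad) in [(25, 30, 4), (60, 70, 11), (30, 85, 4), (65, 25, 11)]:
            disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2
            img[disk] = 5.0 * 100.0
            truth |= disk
        dark = (rr - 75) ** 2 + (cc - 95) ** 2 <= 11 ** 2
        img[dark] = 10.0
        det = detect_calcifications(img, mask, SP)
        sens = (det & truth).sum() / truth.sum()
        fp = (det & ~truth).sum() / mask.sum()
        assert sens >= 0.90
        assert fp <= 0.01
        assert not det[dark].any()


class TestRadiomicExpand:
    def _base_maps(self, rng, shape=(24, 26)):
        return {name: ParamMap(name, rng.normal(size=shape),
                               np.ones(shape, bool), "u")
                for name in BASE_FEATURES}

    def test_fourteen_maps_expand_to_84(self, rng):
        shape = (24, 26)
        maps = self._base_maps(rng, shape)
        out = radiomic_expand(maps, np.ones(shape, bool), SP)
        assert len(out) == 84
        assert list(out)[:6] == ["Pe", "Pe.rel", "Pe.ent1", "Pe.ent2",
                                 "Pe.ent3", "Pe.var2"]

    def test_fully_invalid_base_flags_all_derivatives(self, rng):
        shape = (24, 26)
        maps = self._base_maps(rng, shape)
        maps["D"] = ParamMap("D", np.full(shape, np.nan),
                             np.zeros(shape, bool), "u")
        out = radiomic_expand(maps, np.ones(shape, bool), SP)
        for suffix in ("", ".rel", ".ent1", ".ent2", ".ent3", ".var2"):
            assert not out["D" + suffix].valid.any()

    def test_input_order_irrelevant(self, rng):
        shape = (24, 26)
        maps = self._base_maps(rng, shape)
        shuffled = dict(reversed(list(maps.items())))
        out1 = radiomic_expand(maps, np.ones(shape, bool), SP)
        out2 = radiomic_expand(shuffled, np.ones(shape, bool), SP)
        assert list(out1) == list(out2)
        for k in out1:
            assert np.array_equal(out1[k].values, out2[k].values, equal_nan=True)

    def test_grid_mismatch_rejected(self, rng):
        maps = self._base_maps(rng)
        maps["G"] = ParamMap("G", np.zeros((5, 5)), np.ones((5, 5), bool), "u")
        with pytest.raises(ValueError, match="grid"):
            radiomic_expand(maps, np.ones((24, 26), bool), SP)
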