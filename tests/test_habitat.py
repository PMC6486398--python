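import numpy as np
import pytest

from habitatseg.habitat import (
    HabitatModel,
    QuartileThresholds,
    highest_quartile_mask,
    intersect_compartments,
    lowest_quartile_mask,
    mask_volume,
    pooled_quartiles,
    proportional_volume,
)
from habitatseg.volume_io import NormalizedMap, dice

from conftest import make_mask


def line_volume(values):
    """A 1-voxel-thick map holding the given values, with a matching full ROI."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    vol = NormalizedMap(arr, (1.0, 1.0, 1.0))
    roi = make_mask(np.ones(arr.shape, bool), label="CE")
    return vol, roi


class TestPooledQuartiles:
    def test_linear_interpolation_octet(self):
        # values 1..8: linear-interpolation quartiles are 2.75 and 6.25
        vol, roi = line_volume(range(1, 9))
        thr = pooled_quartiles(vol, roi)
        assert thr.q1 == pytest.approx(2.75)
        assert thr.q3 == pytest.approx(6.25)

    def test_constant_roi_collapses(self):
        vol, roi = line_volume([7.0] * 10)
        thr = pooled_quartiles(vol, roi)
        assert thr.q1 == thr.q3 == 7.0

    def test_single_voxel(self):
        vol, roi = line_volume([3.5])
        thr = pooled_quartiles(vol, roi)
        assert thr.q1 == thr.q3 == 3.5

    def test_empty_roi_rejected(self):
        vol, _ = line_volume(range(8))
        with pytest.raises(ValueError, match="empty"):
            pooled_quartiles(vol, make_mask(np.zeros(vol.shape, bool)))

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            QuartileThresholds(q1=2.0, q3=1.0, source="ADC")


class TestQuartileMasks:
    def test_lowest_selects_bottom_quarter(self):
        vol, roi = line_volume(range(1, 9))
        thr = pooled_quartiles(vol, roi)
        mask = lowest_quartile_mask(vol, roi, thr)
        np.testing.assert_array_equal(
            mask.data.ravel(), [True, True] + [False] * 6
        )

    def test_highest_selects_top_quarter(self):
        vol, roi = line_volume(range(1, 9))
        thr = pooled_quartiles(vol, roi)
        mask = highest_quartile_mask(vol, roi, thr)
        np.testing.assert_array_equal(
            mask.data.ravel(), [False] * 6 + [True, True]
        )

    def test_low_high_disjoint_for_nonconstant(self):
        vol, roi = line_volume(range(1, 9))
        thr = pooled_quartiles(vol, roi)
        low = lowest_quartile_mask(vol, roi, thr)
        high = highest_quartile_mask(vol, roi, thr)
        assert not (low.data & high.data).any()

    def test_constant_map_selects_entire_roi(self):
        vol, roi = line_volume([2.0] * 12)
        thr = pooled_quartiles(vol, roi)
        with pytest.warns(UserWarning, match="tie"):
            low = lowest_quartile_mask(vol, roi, thr)
        with pytest.warns(UserWarning, match="tie"):
            high = highest_quartile_mask(vol, roi, thr)
        assert low.count() == high.count() == roi.count()

    @pytest.mark.parametrize("n", [16, 40, 100, 257])
    def test_distinct_values_select_about_a_quarter(self, rng, n):
        vol, roi = line_volume(rng.permutation(np.linspace(0, 1, n)))
        thr = pooled_quartiles(vol, roi)
        low = lowest_quartile_mask(vol, roi, thr)
        assert abs(low.count() - n / 4) <= 1

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=50)
        vol, roi = line_volume(vals)
        thr = pooled_quartiles(vol, roi)
        ref_low = lowest_quartile_mask(vol, roi, thr).data
        ref_high = highest_quartile_mask(vol, roi, thr).data
        for f in (np.exp, lambda x: x**3 + 2 * x, lambda x: np.arctan(x)):
            tvol, _ = line_volume(f(vals))
            tthr = pooled_quartiles(tvol, roi)
            np.testing.assert_array_equal(lowest_quartile_mask(tvol, roi, tthr).data, ref_low)
            np.testing.assert_array_equal(highest_quartile_mask(tvol, roi, tthr).data, ref_high)


class TestIntersectCompartments:
    def _random_masks(self, rng, shape=(20, 20, 20)):
        ce = rng.random(shape) > 0.4
        inside = lambda: ce & (rng.random(shape) > 0.5)
        return (
            make_mask(inside(), label="rCBV_L"),
            make_mask(inside(), label="ADC_L"),
            make_mask(inside(), label="ADC_H"),
            make_mask(ce, label="CE"),
        )

    def test_matches_brute_force_set_operations(self, rng):
        for _ in range(5):
            rcbv_l, adc_l, adc_h, ce = self._random_masks(rng)
            out = intersect_compartments(rcbv_l, adc_l, adc_h, ce)
            # voxel-by-voxel oracle
            low = np.zeros(ce.shape, bool)
            high = np.zeros(ce.shape, bool)
            cec = np.zeros(ce.shape, bool)
            for idx in np.ndindex(*ce.shape):
                in_low = adc_l.data[idx] and rcbv_l.data[idx]
                in_high = adc_h.data[idx] and rcbv_l.data[idx]
                low[idx], high[idx] = in_low, in_high
                cec[idx] = ce.data[idx] and not (in_low or in_high)
            np.testing.assert_array_equal(out["ADC_L-rCBV_L"].data, low)
            np.testing.assert_array_equal(out["ADC_H-rCBV_L"].data, high)
            np.testing.assert_array_equal(out["CEC"].data, cec)

    def test_partition_of_ce(self, rng):
        rcbv_l, adc_l, adc_h, ce = self._random_masks(rng)
        out = intersect_compartments(rcbv_l, adc_l, adc_h, ce)
        union = out["ADC_L-rCBV_L"].data | out["ADC_H-rCBV_L"].data | out["CEC"].data
        np.testing.assert_array_equal(union, ce.data)

    def test_empty_intersection_leaves_everything_in_cec(self):
        ce = make_mask(np.ones((4, 4, 4), bool), label="CE")
        empty = make_mask(np.zeros((4, 4, 4), bool), label="rCBV_L")
        out = intersect_compartments(empty, empty, empty, ce)
        assert out["ADC_L-rCBV_L"].is_empty()
        assert out["CEC"].count() == ce.count()

    def test_mask_outside_ce_rejected(self):
        ce = np.zeros((4, 4, 4), bool)
        ce[1:3] = True
        stray = np.zeros((4, 4, 4), bool)
        stray[0, 0, 0] = True
        with pytest.raises(ValueError, match="outside CE"):
            intersect_compartments(
                make_mask(stray, label="rCBV_L"),
                make_mask(np.zeros_like(ce), label="ADC_L"),
                make_mask(np.zeros_like(ce), label="ADC_H"),
                make_mask(ce, label="CE"),
            )


class TestVolumes:
    def test_thousand_unit_voxels_is_one_cm3(self):
        arr = np.zeros((10, 10, 10), bool)
        arr[:] = True
        assert mask_volume(make_mask(arr)) == pytest.approx(1.0)

    def test_empty_mask_zero(self):
        assert mask_volume(make_mask(np.zeros((5, 5, 5), bool))) == 0.0

    def test_submillimetre_voxels(self):
        arr = np.zeros((2, 2, 2), bool)
        arr[:] = True  # 8 voxels at 0.5 mm isotropic = 0.001 cm^3
        assert mask_volume(make_mask(arr, voxel_dims=(0.5, 0.5, 0.5))) == pytest.approx(0.001)

    def test_proportional_volume_hand_example(self):
        ce = np.zeros((10, 10, 2), bool)
        ce.ravel()[:200] = True
        comp = np.zeros_like(ce)
        comp.ravel()[:25] = True
        assert proportional_volume(make_mask(comp), make_mask(ce, label="CE")) == pytest.approx(12.5)

    def test_proportional_extremes(self):
        ce = make_mask(np.ones((3, 3, 3), bool), label="CE")
        assert proportional_volume(ce, ce) == 100.0
        assert proportional_volume(make_mask(np.zeros((3, 3, 3), bool)), ce) == 0.0

    def test_empty_ce_rejected(self):
        empty = make_mask(np.zeros((3, 3, 3), bool))
        with pytest.raises(ValueError, match="empty"):
            proportional_volume(empty, empty)


class TestHabitatModel:
    def test_partition_invariant_on_phantom(self, default_phantom, fitted_habitat):
        res = fitted_habitat
        n = (
            res.masks["ADC_L-rCBV_L"].count()
            + res.masks["ADC_H-rCBV_L"].count()
            + res.masks["CEC"].count()
        )
        assert n == default_phantom.ce.count()
        assert not (res.masks["ADC_L-rCBV_L"].data & res.masks["ADC_H-rCBV_L"].data).any()

    def test_planted_core_recovery(self, default_phantom, fitted_habitat):
        truth = default_phantom.truth["masks"]
        assert dice(fitted_habitat.masks["rCBV_L"], truth["rCBV_L"]) >= 0.99
        assert dice(fitted_habitat.masks["ADC_L-rCBV_L"], truth["ADC_L-rCBV_L"]) >= 0.99
        assert dice(fitted_habitat.masks["ADC_H-rCBV_L"], truth["ADC_H-rCBV_L"]) >= 0.99

    def test_proportional_volumes_sum_to_hundred(self, fitted_habitat):
        total = sum(fitted_habitat.prop_volumes.values())
        assert total == pytest.approx(100.0)

    def test_small_ce_flagged_but_computed(self, default_phantom):
        b = default_phantom
        small = np.zeros(b.ce.shape, bool)
        idx = np.argwhere(b.ce.data)[:30]
        small[tuple(idx.T)] = True
        model = HabitatModel.from_raw(b.adc, b.rcbv, make_mask(small, label="CE"), b.nawm)
        res = model.fit()
        assert any("unreliable" in f for f in res.flags)
        assert res.abs_volumes["CE"] > 0

    def test_summary_mentions_thresholds(self, fitted_habitat):
        text = fitted_habitat.summary()
        assert "q1=" in text and "ADC_L-rCBV_L" in text
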