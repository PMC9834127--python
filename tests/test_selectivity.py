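"""Overall selectivity, digit selectivity, the OS2 variant and sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from digitsel.constants import DIGITS, DIGIT_PAIRS
from digitsel.roi import RoiMask, ZStatMapSet, activation_mask, winner_takes_all
from digitsel.selectivity import (
    DEFAULT_SWEEP_THRESHOLDS,
    analyze_selectivity,
    digit_selectivity_cluster,
    digit_selectivity_voxel,
    os2_absolute_variant,
    overall_selectivity_map,
    overall_selectivity_roi,
    overall_selectivity_voxel,
    threshold_sweep,
)
from digitsel.synthetic import make_neural_fields, simulate_zmaps

positive_z = st.floats(0.01, 50.0, allow_nan=False)


def _zset(d1, d2, d5):
    return ZStatMapSet(
        maps={"D1": np.asarray(d1, float), "D2": np.asarray(d2, float),
              "D5": np.asarray(d5, float)},
        contrast="test",
    )


class TestOverallSelectivityVoxel:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((6.0, 3.0, 3.0), 0.5),
            ((4.0, 4.0, 4.0), 1 / 3),
        ],
    )
    def test_worked_examples(self, triple, expected):
        value, flagged = overall_selectivity_voxel(*triple)
        assert not flagged
        assert value == pytest.approx(expected)

    def test_negative_crosstalk_cancels_denominator(self):
        """(5, -2, -3) sums to zero: flagged, no value returned."""
        value, flagged = overall_selectivity_voxel(5.0, -2.0, -3.0)
        assert flagged and np.isnan(value)

    def test_any_nonpositive_input_flagged(self):
        assert overall_selectivity_voxel(5.0, 1.0, -0.1)[1]
        assert overall_selectivity_voxel(5.0, 0.0, 1.0)[1]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            overall_selectivity_voxel(np.inf, 1.0, 1.0)

    @settings(derandomize=True, max_examples=300)
    @given(z1=positive_z, z2=positive_z, z5=positive_z)
    def test_bounds_for_positive_triples(self, z1, z2, z5):
        """OS lies in [1/3, 1] whenever all three responses are positive."""
        value, flagged = overall_selectivity_voxel(z1, z2, z5)
        assert not flagged
        assert 1 / 3 - 1e-12 <= value <= 1.0 + 1e-12


class TestOverallSelectivityRoi:
    def test_mean_of_unflagged(self):
        z = _zset([[6.0, 7.0]], [[3.0, 1.0]], [[3.0, 2.0]])
        act = np.array([[True, True]])
        mean, frac = overall_selectivity_roi(z, act)
        assert mean == pytest.approx(0.5 * (0.5 + 0.7))
        assert frac == 0.0

    def test_flagged_voxel_excluded_and_counted(self):
        z = _zset([[6.0, 5.0]], [[3.0, -2.0]], [[3.0, -3.0]])
        act = np.array([[True, True]])
        mean, frac = overall_selectivity_roi(z, act)
        assert mean == pytest.approx(0.5)
        assert frac == 0.5

    def test_empty_mask_rejected(self):
        z = _zset([[6.0]], [[3.0]], [[3.0]])
        with pytest.raises(ValueError, match="empty"):
            overall_selectivity_roi(z, np.array([[False]]))

    def test_policy_raw_keeps_degenerate_values(self):
        z = _zset([[5.0]], [[-2.0]], [[-2.5]])
        os_vol, flags = overall_selectivity_map(
            z, np.array([[True]]), policy="raw"
        )
        assert os_vol[0, 0] == pytest.approx(5.0 / 0.5)  # exceeds 1: the failure mode
        assert not flags[0, 0]

    def test_policy_clamp_bounds_values(self):
        z = _zset([[5.0]], [[-2.0]], [[-2.5]])
        os_vol, _ = overall_selectivity_map(z, np.array([[True]]), policy="clamp")
        assert 1 / 3 <= os_vol[0, 0] <= 1.0

    def test_unknown_policy_rejected(self):
        z = _zset([[5.0]], [[1.0]], [[1.0]])
        with pytest.raises(ValueError, match="policy"):
            overall_selectivity_map(z, np.array([[True]]), policy="drop")

    def test_vaso_like_more_selective_than_bold_like(self, small_config):
        """Narrow-PSF, low-amplitude contrast scores higher OS, same seed."""
        roi = RoiMask(make_neural_fields(small_config).ribbon, "ribbon")
        scores = {}
        for contrast in ("VASO-CBV", "BOLD"):
            z = simulate_zmaps(small_config, contrast)
            act = activation_mask(z, roi, 2.5)
            scores[contrast], _ = overall_selectivity_roi(z, act)
        assert scores["VASO-CBV"] > scores["BOLD"]


class TestDigitSelectivity:
    def test_group_mean_crosstalk_worked_example(self):
        """DS evaluated on dominant 3.48 vs non-dominant 1.20 and 1.13."""
        assert digit_selectivity_voxel(3.48, 1.20, 1.13) == pytest.approx(
            0.6652, abs=5e-4
        )

    def test_perfectly_selective_voxel(self):
        assert digit_selectivity_voxel(7.3, 0.0, 0.0) == 1.0

    def test_unselective_voxel(self):
        assert digit_selectivity_voxel(2.0, 2.0, 2.0) == 0.0

    def test_nonpositive_dominant_rejected(self):
        with pytest.raises(ValueError):
            digit_selectivity_voxel(0.0, 1.0, 1.0)

    @settings(derandomize=True, max_examples=300)
    @given(
        dom=positive_z,
        a=st.floats(-10, 50, allow_nan=False),
        b=st.floats(-10, 50, allow_nan=False),
    )
    def test_algebraic_identity(self, dom, a, b):
        """Mean-difference form equals 1 - (a+b)/(2 dom) to 1e-12."""
        lhs = digit_selectivity_voxel(dom, a, b)
        rhs = 1.0 - (a + b) / (2.0 * dom)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(dom=positive_z, a=st.floats(0, 50), b=st.floats(0, 50), c=positive_z)
    def test_extra_crosstalk_strictly_lowers_ds(self, dom, a, b, c):
        base = digit_selectivity_voxel(dom, a, b)
        bumped = digit_selectivity_voxel(dom, a + c, b + c)
        assert bumped < base

    def test_single_voxel_cluster(self):
        z = _zset([[4.0]], [[1.0]], [[1.0]])
        labels = winner_takes_all(z, np.array([[True]]))
        ds = digit_selectivity_cluster(z, labels)
        assert ds["D1"] == pytest.approx(0.75)
        assert np.isnan(ds["D2"]) and np.isnan(ds["D5"])

    def test_noiseless_zero_psf_near_perfect(self, separated_noiseless_config):
        z = simulate_zmaps(separated_noiseless_config, "ideal")
        roi = RoiMask(make_neural_fields(separated_noiseless_config).ribbon, "r")
        act = activation_mask(z, roi, 2.5)
        labels = winner_takes_all(z, act)
        ds = digit_selectivity_cluster(z, labels)
        assert all(v > 0.95 for v in ds.values())

    def test_vaso_like_exceeds_bold_like_per_digit(self, small_config):
        roi = RoiMask(make_neural_fields(small_config).ribbon, "ribbon")
        scores = {}
        for contrast in ("VASO-CBV", "BOLD"):
            z = simulate_zmaps(small_config, contrast)
            act = activation_mask(z, roi, 2.5)
            labels = winner_takes_all(z, act)
            scores[contrast] = digit_selectivity_cluster(z, labels)
        for d in DIGITS:
            assert scores["VASO-CBV"][d] > scores["BOLD"][d]

    def test_means_of_means_aggregation(self):
        z = _zset([[4.0, 6.0]], [[1.0, 3.0]], [[1.0, 1.0]])
        labels = winner_takes_all(z, np.array([[True, True]]))
        ds = digit_selectivity_cluster(z, labels, aggregation="means-of-means")
        # cluster means: dom 5, nd (2, 1)
        assert ds["D1"] == pytest.approx(1 - 3 / 10)


class TestOs2Variant:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((6.0, 3.0, 3.0), 0.5),  # agrees with OS when all positive
            ((5.0, -2.0, -3.0), 0.5),  # finite where OS diverges
            ((-1.0, -1.0, -1.0), -1 / 3),  # sign preserved in numerator
        ],
    )
    def test_worked_examples(self, triple, expected):
        value, flagged = os2_absolute_variant(*triple)
        assert not flagged
        assert value == pytest.approx(expected)

    def test_all_zero_flagged(self):
        value, flagged = os2_absolute_variant(0.0, 0.0, 0.0)
        assert flagged and np.isnan(value)

    @settings(derandomize=True, max_examples=200)
    @given(z1=positive_z, z2=positive_z, z5=positive_z)
    def test_equals_os_for_positive_inputs(self, z1, z2, z5):
        os_val, _ = overall_selectivity_voxel(z1, z2, z5)
        os2_val, _ = os2_absolute_variant(z1, z2, z5)
        assert os2_val == pytest.approx(os_val, abs=1e-12)


class TestCrosstalkMixing:
    def test_mixing_lowers_ds_and_raises_dice(self, small_config):
        """Blending each digit map with the others' maps emulates added
        vascular overlap: DS falls, pairwise Dice rises, monotonically."""
        from digitsel.overlap import pairwise_overlap
        from digitsel.roi import digit_cluster_masks

        z0 = simulate_zmaps(small_config, "BOLD")
        roi = RoiMask(make_neural_fields(small_config).ribbon, "ribbon")
        ds_means, dice_means = [], []
        for lam in (0.0, 0.2, 0.4):
            mixed = {}
            for d in DIGITS:
                others = [z0.maps[m] for m in DIGITS if m != d]
                mixed[d] = (1 - lam) * z0.maps[d] + lam * 0.5 * (
                    others[0] + others[1]
                )
            z = ZStatMapSet(maps=mixed, contrast="mixed")
            act = activation_mask(z, roi, 2.5)
            labels = winner_takes_all(z, act)
            ds = digit_selectivity_cluster(z, labels)
            ds_means.append(np.nanmean(list(ds.values())))
            ov = pairwise_overlap(digit_cluster_masks(z, roi, 2.5))
            dice_means.append(np.mean([p.dice for p in ov.pairs.values()]))
        assert ds_means[0] > ds_means[1] > ds_means[2]
        assert dice_means[0] < dice_means[1] < dice_means[2]


class TestThresholdSweep:
    def test_counts_non_increasing_and_rows_complete(self, small_config):
        z = simulate_zmaps(small_config, "BOLD")
        roi = RoiMask(make_neural_fields(small_config).ribbon, "ribbon")
        sw = threshold_sweep(z, roi, DEFAULT_SWEEP_THRESHOLDS)
        counts = sw.frame["n_active"].to_numpy()
        assert np.all(np.diff(counts) <= 0)
        assert {"os", "ds_D1", "dice_D1-D2"} <= set(sw.frame.columns)

    def test_empty_grid_rejected(self, small_config):
        z = simulate_zmaps(small_config, "BOLD")
        roi = RoiMask(make_neural_fields(small_config).ribbon, "ribbon")
        with pytest.raises(ValueError, match="empty"):
            threshold_sweep(z, roi, [])

    def test_unsorted_grid_rejected(self, small_config):
        z = simulate_zmaps(small_config, "BOLD")
        roi = RoiMask(make_neural_fields(small_config).ribbon, "ribbon")
        with pytest.raises(ValueError, match="ascending"):
            threshold_sweep(z, roi, [3.0, 2.0])

    def test_threshold_above_max_flags_empty(self, small_config):
        z = simulate_zmaps(small_config, "BOLD")
        roi = RoiMask(make_neural_fields(small_config).ribbon, "ribbon")
        top = float(max(z.maps[d].max() for d in DIGITS)) + 1.0
        sw = threshold_sweep(z, roi, [top])
        row = sw.frame.iloc[0]
        assert row["empty"] and row["n_active"] == 0
        assert np.isnan(row["os"])

    def test_duplicate_thresholds_identical_rows(self, small_config):
        z = simulate_zmaps(small_config, "VASO-CBV")
        roi = RoiMask(make_neural_fields(small_config).ribbon, "ribbon")
        sw = threshold_sweep(z, roi, [2.5, 2.5])
        a, b = sw.frame.iloc[0], sw.frame.iloc[1]
        assert a.equals(b)


class TestAnalyzeSelectivity:
    def test_bundle_fields_consistent(self, small_config):
        z = simulate_zmaps(small_config, "VASO-CBV")
        roi = RoiMask(make_neural_fields(small_config).ribbon, "ribbon")
        res = analyze_selectivity(z, roi, 2.5)
        assert res.n_active > 0
        assert 0.0 <= res.outlier_fraction <= 1.0
        assert np.isfinite(res.os_roi)
        finite_os = res.os_map[np.isfinite(res.os_map)]
        assert res.os_roi == pytest.approx(finite_os.mean())
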