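"""Marker operators: roughness indices, filtering, detection, group stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eclopy import markers
from eclopy.markers import MarkerTrace


def _trace(values, channel="roughness_sd", dt=0.2):
    values = np.asarray(values, dtype=float)
    return MarkerTrace("a", channel, dt * np.arange(len(values)), values)


# -- roughness: standard-deviation algorithm ----------------------------------


def _roughness_sd_oracle(img: np.ndarray) -> float:
    # direct double-loop over interior pixels; population SD of the 9
    # neighborhood intensities
    total = 0.0
    for r in range(1, img.shape[0] - 1):
        for c in range(1, img.shape[1] - 1):
            total += np.std(img[r - 1 : r + 2, c - 1 : c + 2])
    return total


class TestRoughnessSD:
    def test_uniform_is_zero(self):
        assert markers.roughness_sd(np.full((7, 7), 42.0)) == 0.0

    def test_single_bright_center(self):
        img = np.zeros((3, 3))
        img[1, 1] = 9.0
        assert markers.roughness_sd(img) == pytest.approx(np.sqrt(8.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (10, 10)).astype(float)
        assert markers.roughness_sd(img) == pytest.approx(
            _roughness_sd_oracle(img), abs=1e-9
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-100, 100),
           st.floats(0.1, 5.0))
    def test_offset_and_scale_behavior(self, seed, offset, scale):
        img = np.random.default_rng(seed).integers(0, 200, (8, 8)).astype(float)
        base = markers.roughness_sd(img)
        assert markers.roughness_sd(img + offset) == pytest.approx(base, rel=1e-9,
                                                                   abs=1e-9)
        assert markers.roughness_sd(img * scale) == pytest.approx(scale * base,
                                                                  rel=1e-9)

    def test_differences_mode(self):
        img = np.zeros((3, 3))
        img[1, 1] = 9.0
        # eight signed differences (neighbor - center) are all -9: SD 0
        assert markers.roughness_sd(img, mode="differences") == 0.0

    def test_too_small_roi_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            markers.roughness_sd(np.zeros((2, 5)))


# -- roughness: borders algorithm ---------------------------------------------


class TestPatches:
    def test_isolated_pixel(self):
        img = np.zeros((5, 5))
        img[2, 2] = 10
        patches = markers.segment_patches(img, None, threshold=5)
        assert len(patches) == 1
        assert patches[0].area == 1 and patches[0].perimeter == 4

    def test_solid_block(self):
        img = np.zeros((5, 5))
        img[1:4, 1:4] = 10
        patches = markers.segment_patches(img, None, threshold=5)
        assert len(patches) == 1
        assert patches[0].perimeter == 12

    def test_diagonal_pixels_share_patch(self):
        img = np.zeros((5, 5))
        img[1, 1] = img[2, 2] = 10
        patches = markers.segment_patches(img, None, threshold=5)
        assert len(patches) == 1  # 8-connectivity
        assert patches[0].perimeter == 8

    def test_no_pixels_above_threshold(self):
        assert markers.roughness_borders(np.zeros((5, 5)), None, 1.0) == 0.0

    def test_splitting_increases_index(self):
        together = np.zeros((6, 10))
        together[2:4, 2:8] = 10  # one 2x6 block
        apart = np.zeros((6, 10))
        apart[2:4, 1:4] = 10     # two separated 2x3 blocks, same total area
        apart[2:4, 6:9] = 10
        assert (markers.roughness_borders(apart, None, 5)
                > markers.roughness_borders(together, None, 5))

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        blob = rng.integers(0, 2, (4, 4)) * 10
        a = np.zeros((12, 12)); a[2:6, 2:6] = blob
        b = np.zeros((12, 12)); b[5:9, 6:10] = blob
        assert (markers.roughness_borders(a, None, 5)
                == markers.roughness_borders(b, None, 5))

    def test_perimeter_additive_under_split(self):
        # crack-edge perimeters of the two halves sum to more than the
        # whole by exactly twice the cut length
        img = np.zeros((6, 6))
        img[2:4, 1:5] = 10
        whole = markers.roughness_borders(img, None, 5)
        left = np.zeros((6, 6)); left[2:4, 1:3] = 10
        right = np.zeros((6, 6)); right[2:4, 3:5] = 10
        split_sum = (markers.roughness_borders(left, None, 5)
                     + markers.roughness_borders(right, None, 5))
        assert split_sum == whole + 2 * 2


# -- filtering and detection ---------------------------------------------------


class TestHighpass:
    def test_constant_trace_zeroed(self):
        hp = markers.highpass(_trace(np.full(60, 7.0)))
        np.testing.assert_allclose(hp.values, 0.0, atol=1e-12)

    def test_linear_ramp_zero_interior(self):
        hp = markers.highpass(_trace(np.arange(80.0)), window_h=2.0)
        w = 11  # samples spanning 2 h at 0.2-h cadence, rounded odd
        np.testing.assert_allclose(hp.values[w // 2 : -(w // 2)], 0.0, atol=1e-9)

    def test_step_gives_extremum_at_step(self):
        v = np.zeros(100)
        v[50:] = 10.0
        hp = markers.highpass(_trace(v), window_h=2.0)
        assert np.argmax(hp.values) == 50

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            markers.highpass(_trace([1.0, 2.0]))


class TestDetectEmergence:
    def test_wing_jump_detected_at_step(self):
        v = np.full(100, 100.0)
        v[50:] = 200.0
        t = markers.detect_emergence(_trace(v, channel="wing_intensity"))
        assert t == pytest.approx(50 * 0.2)

    def test_roughness_collapse_detected(self):
        v = np.linspace(100, 400, 100)
        v[80:] = 20.0
        assert markers.detect_emergence(_trace(v)) == pytest.approx(80 * 0.2)

    def test_monotone_ramp_gives_none(self):
        assert markers.detect_emergence(
            _trace(np.linspace(200, 100, 50), channel="wing_intensity")) is None

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            markers.detect_emergence(_trace([1.0, 2.0], channel="wing_intensity"))


class TestDetectOnset:
    def test_flat_noisy_trace_none(self):
        rng = np.random.default_rng(0)
        v = 100 + rng.normal(0, 1, 300)
        assert markers.detect_onset(_trace(v)) is None

    def test_known_change_point_recovered(self):
        # flat 30 h then a clear rise: onset within +-0.6 h of the kink
        rng = np.random.default_rng(1)
        t = 0.2 * np.arange(300)
        v = 100 + rng.normal(0, 1, 300)
        rise = t > 30.0
        v[rise] += 120.0 * np.sqrt(t[rise] - 30.0)
        onset = markers.detect_onset(_trace(v))
        assert onset == pytest.approx(30.0, abs=0.6)

    def test_short_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            markers.detect_onset(_trace(np.zeros(10)))


class TestSummarizeOnsets:
    def test_arithmetic(self):
        t = 0.2 * np.arange(300)
        rng = np.random.default_rng(2)
        v = 100 + rng.normal(0, 1, 300)
        v[t >= 30.0] += 150 + 40 * np.sqrt(np.maximum(t[t >= 30.0] - 30, 0))
        v[t >= 43.0] = 10.0  # collapse = emergence
        summaries, excluded, table = markers.summarize_onsets([_trace(v)])
        assert not excluded
        s = summaries[0]
        assert s.time_to_onset_h == pytest.approx(30.0, abs=0.6)
        assert s.duration_h == pytest.approx(13.0, abs=0.8)
        assert len(table) == 1

    def test_empty_input(self):
        summaries, excluded, table = markers.summarize_onsets([])
        assert summaries == [] and excluded == [] and table.empty

    def test_undetectable_animal_excluded_with_reason(self):
        rng = np.random.default_rng(3)
        flat = 100 + rng.normal(0, 1, 300)
        summaries, excluded, _ = markers.summarize_onsets([_trace(flat)])
        assert summaries == []
        assert excluded[0][1].startswith("no roughening onset")


# -- group statistics ----------------------------------------------------------


class TestGroupCompare:
    def test_hand_anova_oracle(self):
        out = markers.group_compare({"a": [1, 2, 3], "b": [2, 3, 4]})
        assert out["F"] == pytest.approx(1.5)
        assert out["df"] == (1, 4)

    def test_identical_groups_f_zero(self):
        out = markers.group_compare({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert out["F"] == pytest.approx(0.0)
        assert set(out["letters"]["a"]) & set(out["letters"]["b"])

    def test_far_group_gets_distinct_letter(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": 10 + rng.normal(0, 1, 8),
            "b": 10.5 + rng.normal(0, 1, 8),
            "c": 30 + rng.normal(0, 1, 8),
        }
        out = markers.group_compare(groups)
        assert not set(out["letters"]["c"]) & set(out["letters"]["a"])
        assert not set(out["letters"]["c"]) & set(out["letters"]["b"])
        assert set(out["letters"]["a"]) & set(out["letters"]["b"])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            markers.group_compare({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            markers.group_compare({"a": [5, 5], "b": [5, 5]})
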