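"""The counts chain: stage-by-stage contracts and whole-pipeline properties."""

import numpy as np
import pytest

from actikit import (
    ACTIGRAPH_BANDPASS,
    ContractError,
    CountsConfig,
    compute_counts,
)
from actikit.counts import (
    decimate_to_output_rate,
    downsample_to_filter_rate,
    epoch_sum,
    scale_rectify_threshold,
)

from oracles import counts_reference

CFG = CountsConfig()
SPEC = ACTIGRAPH_BANDPASS


class TestDownsample:
    def test_decimation_by_two(self):
        out = downsample_to_filter_rate(np.array([1.0, 2.0, 3.0, 4.0]), 60, 30)
        np.testing.assert_array_equal(out, [1.0, 3.0])

    def test_identity_when_rates_equal(self):
        x = np.arange(5.0)
        np.testing.assert_array_equal(downsample_to_filter_rate(x, 30, 30), x)

    def test_length_arithmetic(self):
        assert len(downsample_to_filter_rate(np.zeros(600), 60, 30)) == 300

    def test_upsampling_rejected(self):
        with pytest.raises(ContractError):
            downsample_to_filter_rate(np.zeros(10), 30, 60)

    def test_noninteger_ratio_uses_polyphase(self, sinusoid):
        # 50 Hz -> 30 Hz: anti-aliased path; a slow sinusoid survives intact
        x = sinusoid(1.0, 1.0, 30.0, fs=50.0)
        out = downsample_to_filter_rate(x, 50, 30)
        assert len(out) == int(len(x) * 30 / 50)
        t30 = np.arange(len(out)) / 30.0
        mid = slice(60, -60)  # polyphase edge effects excluded
        np.testing.assert_allclose(out[mid], np.sin(2 * np.pi * t30)[mid], atol=0.01)

    def test_explicit_decimate_rejects_noninteger_ratio(self):
        with pytest.raises(ContractError, match="integer"):
            downsample_to_filter_rate(np.zeros(100), 50, 30, method="decimate")


class TestScaleRectifyThreshold:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, 0.0),
            (10.0, 128.0),           # 171.27... clips to the ceiling
            (-10.0, 128.0),          # rectified first
            (0.2, 0.0),              # 3.4255 < 4 falls in the dead-band
            (0.5, 0.5 * 17.127404),  # 8.5637 passes both thresholds
        ],
    )
    def test_pointwise_rule(self, value, expected):
        out = scale_rectify_threshold(np.array([value]), CFG)
        assert out[0] == pytest.approx(expected)

    def test_boundary_values_exact(self):
        # exactly 4 passes (dead-band is strict), exactly 128 is not clipped
        at_deadband = 4.0 / CFG.scale_factor
        at_ceiling = 128.0 / CFG.scale_factor
        out = scale_rectify_threshold(np.array([at_deadband, at_ceiling]), CFG)
        np.testing.assert_allclose(out, [4.0, 128.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ContractError):
            scale_rectify_threshold(np.array([np.inf]), CFG)


class TestDecimateAndSum:
    def test_decimate_by_three(self):
        out = decimate_to_output_rate(np.array([1.0, 2, 3, 4, 5, 6]), CFG)
        np.testing.assert_array_equal(out, [1.0, 4.0])

    def test_one_minute_lengths(self):
        assert len(decimate_to_output_rate(np.zeros(1800), CFG)) == 600

    def test_sum_of_ones(self):
        np.testing.assert_array_equal(epoch_sum(np.ones(600), CFG), [600])

    def test_floor_before_sum(self):
        np.testing.assert_array_equal(epoch_sum(np.full(600, 0.9), CFG), [0])

    def test_trailing_partial_epoch_dropped(self):
        np.testing.assert_array_equal(epoch_sum(np.ones(900), CFG), [600])

    def test_negative_input_rejected(self):
        with pytest.raises(ContractError):
            epoch_sum(np.array([-1.0]), CFG)


class TestComputeCounts:
    def test_zero_recording_gives_zero_counts(self, make_recording):
        rec = make_recording(np.zeros(60 * 60 * 5))
        ep = compute_counts(rec, CFG, SPEC)
        for arr in (ep.counts_x, ep.counts_y, ep.counts_z):
            assert len(arr) == 5 and np.all(arr == 0)

    def test_still_device_gravity_rejected(self, make_recording):
        # constant (0, 1, 0) g: DC is filtered out and the steady-start
        # initialisation leaves no switch-on transient either
        rec = make_recording(np.ones(60 * 60 * 5))
        ep = compute_counts(rec, CFG, SPEC)
        assert np.all(ep.counts_y == 0)
        assert np.all(ep.counts_x == 0) and np.all(ep.counts_z == 0)

    def test_matches_per_sample_reference_on_sinusoid(self, make_recording, sinusoid):
        rec = make_recording(sinusoid(1.0, 1.0, 180.0))
        ep = compute_counts(rec, CFG, SPEC)
        expected = counts_reference(rec.y.tolist(), 60.0, SPEC.b, SPEC.a)
        assert ep.counts_y.tolist() == expected

    def test_matches_per_sample_reference_on_random_recordings(self, rng, make_recording):
        # oracle equivalence, exact, across randomized short recordings
        for _ in range(100):
            n = int(rng.integers(3600, 3600 * 3))
            y = rng.normal(0, rng.uniform(0.05, 2.0), n)
            rec = make_recording(y)
            ep = compute_counts(rec, CFG, SPEC)
            assert ep.counts_y.tolist() == counts_reference(y.tolist(), 60.0, SPEC.b, SPEC.a)

    def test_count_ceiling_on_random_inputs(self, rng, make_recording):
        # 128 * 10 Hz * 60 s bounds every epoch for any finite input
        for _ in range(60):
            n = int(rng.integers(3600, 7200))
            y = rng.normal(0, 50.0, n)  # absurdly violent input
            ep = compute_counts(make_recording(y), CFG, SPEC)
            assert np.all(ep.counts_y <= 76_800)

    def test_deadband_recordings_give_zero(self, make_recording, sinusoid):
        # post-filter amplitude * 17.127404 < 4 -> all counts zero
        freq = 1.0
        gain = SPEC.gain_at(freq)[0]
        amp = 0.5 * (4.0 / CFG.scale_factor) / gain  # half the dead-band limit
        ep = compute_counts(make_recording(sinusoid(freq, amp, 300.0)), CFG, SPEC)
        assert np.all(ep.counts_y == 0)

    def test_saturation_monotone_in_amplitude(self, make_recording, sinusoid):
        amps = [0.05, 0.2, 0.5, 1.0, 3.0, 10.0, 40.0]
        totals = []
        for amp in amps:
            ep = compute_counts(make_recording(sinusoid(1.0, amp, 300.0)), CFG, SPEC)
            totals.append(int(ep.counts_y[1:].sum()))
        assert totals == sorted(totals)
        assert totals[-1] >= 0.99 * 76_800 * 4  # 4 settled minutes near the cap

    def test_axis_independence_under_permutation(self, rng, make_recording):
        y = rng.normal(0, 0.6, 3600 * 2)
        x = rng.normal(0, 0.3, 3600 * 2)
        z = rng.normal(0, 0.9, 3600 * 2)
        a = compute_counts(make_recording(y, x=x, z=z), CFG, SPEC)
        b = compute_counts(make_recording(x, x=z, z=y), CFG, SPEC)
        np.testing.assert_array_equal(a.counts_x, b.counts_y)
        np.testing.assert_array_equal(a.counts_y, b.counts_z)
        np.testing.assert_array_equal(a.counts_z, b.counts_x)

    def test_short_recording_yields_empty(self, make_recording):
        ep = compute_counts(make_recording(np.zeros(600)), CFG, SPEC)  # 10 s
        assert len(ep) == 0

    def test_warmup_discard(self, make_recording):
        cfg = CountsConfig(discard_warmup_epochs=1)
        rec = make_recording(np.ones(3600 * 3))
        ep = compute_counts(rec, cfg, SPEC)
        assert len(ep) == 2 and np.all(ep.counts_y == 0)


class TestCountsConfig:
    def test_rate_ratio_must_be_integer(self):
        with pytest.raises(ContractError):
            CountsConfig(fs_filter=30.0, fs_decimated=7.0)

    def test_ceiling_above_deadband(self):
        with pytest.raises(ContractError):
            CountsConfig(clip_ceiling=3.0, deadband=4.0)

    def test_max_count_per_epoch(self):
        assert CountsConfig().max_count_per_epoch == 76_800
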