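"""PTSD spike detection: noise estimation, thresholding, cutouts."""

import numpy as np
import pytest

from adspipe import (
    PTSDParams,
    detect_spikes_ptsd,
    estimate_noise_sd,
    extract_cutouts,
    make_biphasic_template,
    match_to_ground_truth,
)

FS = 30_000.0


def _trace_with_spikes(times, amp=100.0, duration=1.0, noise_sd=0.0, seed=0):
    """Noise + biphasic templates inserted at given times (single channel)."""
    rng = np.random.default_rng(seed)
    n = int(duration * FS)
    x = rng.normal(0.0, noise_sd, n) if noise_sd else np.zeros(n)
    tpl = make_biphasic_template(amp, channel_footprint={0: 1.0})
    for t in times:
        s0 = int(round(t * FS)) - tpl.align_index
        lo, hi = max(s0, 0), min(s0 + tpl.samples.size, x.size)
        x[lo:hi] += tpl.samples[lo - s0 : hi - s0]
    return x


class TestNoiseSD:
    def test_gaussian_noise_recovered(self):
        """Median(|x|)/0.6745 recovers a known Gaussian SD within 2%."""
        x = np.random.default_rng(0).normal(0.0, 10.0, int(10 * FS))
        assert abs(estimate_noise_sd(x, "robust_median") - 10.0) < 0.2

    def test_constant_zero_signal(self):
        assert estimate_noise_sd(np.zeros(1000), "robust_median") == 0.0

    def test_robust_estimator_ignores_spikes_plain_sd_does_not(self):
        """Sparse 150 uV spikes: robust estimate stays near 10, plain SD inflates."""
        x = _trace_with_spikes(np.arange(0.1, 9.9, 0.5), amp=150.0, duration=10.0,
                               noise_sd=10.0, seed=1)
        robust = estimate_noise_sd(x, "robust_median")
        plain = estimate_noise_sd(x, "plain_sd")
        assert abs(robust - 10.0) < 0.5
        assert plain > robust

    def test_empty_signal_raises(self):
        with pytest.raises(ValueError):
            estimate_noise_sd(np.array([]))


class TestDetect:
    def test_single_noiseless_spike(self):
        """One 100 uV biphasic spike, 50 uV threshold -> 1 event at the peak."""
        x = _trace_with_spikes([0.5], amp=100.0)
        ev = detect_spikes_ptsd(x, PTSDParams(threshold_factor=1.0), FS, noise_sd=50.0)
        assert ev.n_events == 1
        assert abs(ev.times[0] - 0.5) <= 1.0 / FS

    def test_subthreshold_spike_ignored(self):
        x = _trace_with_spikes([0.5], amp=100.0)
        ev = detect_spikes_ptsd(x, PTSDParams(threshold_factor=1.0), FS, noise_sd=150.0)
        assert ev.n_events == 0

    def test_event_count_monotone_in_threshold(self, single_channel_trace):
        """Raising the threshold factor can only remove events."""
        sig, fs, _ = single_channel_trace
        nsd = estimate_noise_sd(sig)
        counts = [
            detect_spikes_ptsd(
                sig, PTSDParams(threshold_factor=f), fs, noise_sd=nsd
            ).n_events
            for f in (4, 6, 8, 10, 14, 20, 40)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_dead_time_enforced(self, single_channel_trace):
        sig, fs, _ = single_channel_trace
        ev = detect_spikes_ptsd(sig, PTSDParams(), fs)
        if ev.n_events > 1:
            assert np.diff(ev.times).min() >= PTSDParams().dead_time - 1e-12

    def test_translation_equivariance(self):
        """Prepending k baseline samples shifts all event times by k samples."""
        x = _trace_with_spikes([0.3, 0.6], amp=120.0, noise_sd=5.0, seed=2)
        k = 450
        shifted = np.concatenate([np.zeros(k), x])
        p = PTSDParams(threshold_factor=8.0)
        ev0 = detect_spikes_ptsd(x, p, FS, noise_sd=5.0)
        ev1 = detect_spikes_ptsd(shifted, p, FS, noise_sd=5.0)
        np.testing.assert_allclose(ev1.times, ev0.times + k / FS, atol=1e-12)

    def test_recall_precision_on_benchmark(self, detection_benchmark):
        """>= 0.95 recall and precision at 8x-SD threshold, +-1 ms matching."""
        rec, trains = detection_benchmark
        recalls, precisions = [], []
        for ch in range(rec.n_channels):
            sig = rec.samples[ch]
            ev = detect_spikes_ptsd(sig, PTSDParams(), rec.sample_rate, channel=ch)
            gt = np.sort(
                np.concatenate([t.timestamps for t in trains if t.channel == ch])
            )
            r, p, _ = match_to_ground_truth(ev.times, gt, tolerance=0.001)
            recalls.append(r)
            precisions.append(p)
        assert min(recalls) >= 0.95
        assert min(precisions) >= 0.95


class TestCutouts:
    def test_window_shape_and_alignment(self):
        """At 30 kHz the cutout is 37 samples with the extremum at index 12."""
        x = _trace_with_spikes([0.5], amp=100.0)
        ev = detect_spikes_ptsd(x, PTSDParams(threshold_factor=1.0), FS, noise_sd=40.0)
        ev = extract_cutouts(x, ev)
        assert ev.cutouts.shape == (1, 37)
        assert int(np.argmax(np.abs(ev.cutouts[0]))) == 12
        assert not ev.truncated[0]

    def test_boundary_event_zero_padded_and_flagged(self):
        x = _trace_with_spikes([0.0002], amp=100.0, duration=0.1)
        ev = detect_spikes_ptsd(x, PTSDParams(threshold_factor=1.0), FS, noise_sd=40.0)
        ev = extract_cutouts(x, ev)
        assert ev.n_events >= 1
        assert ev.truncated[0]
        assert ev.cutouts[0, 0] == 0.0

    def test_cutouts_are_local(self):
        """Two events 5 ms apart extract independently: slicing the trace
        around one event reproduces its cutout bit-for-bit."""
        x = _trace_with_spikes([0.5, 0.505], amp=100.0)
        ev = detect_spikes_ptsd(x, PTSDParams(threshold_factor=1.0), FS, noise_sd=40.0)
        ev = extract_cutouts(x, ev)
        assert ev.n_events == 2
        c0 = int(round(ev.times[0] * FS))
        window = x[c0 - 12 : c0 + 25]
        np.testing.assert_array_equal(ev.cutouts[0], window)
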