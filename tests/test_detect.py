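"""Causal RMS HFO detection: referencing, filtering, thresholding, windows."""

import warnings

import numpy as np
import pytest

from hforate.core import Channel, ChannelMap, EEGSegment, HFOEvent
from hforate.detect import (
    DetectorConfig,
    bandpass_filter,
    common_average_reference,
    compute_background,
    detect_epoch,
    pseudo_prospective_detect,
    redact_artifacts,
    _moving_rms,
)
from hforate.synthetic import SimConfig, make_channel_map, synthesize_ieeg

from _oracles import naive_detect_runs

FS = 2048.0


def _segment(data, fs=FS, ids=None, start=0.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    ids = ids or [f"CH{i}" for i in range(data.shape[0])]
    return EEGSegment(data, fs, ids, start)


def _burst(fs, freq=140.0, dur=0.05, amp=1.0):
    t = np.arange(int(round(dur * fs))) / fs
    return amp * np.hanning(t.size) * np.sin(2 * np.pi * freq * t)


def _noise_with_bursts(rng, fs, duration, burst_times, snr=10.0):
    """Gaussian noise with known bursts; returns (raw, true intervals)."""
    n = int(duration * fs)
    x = rng.standard_normal(n)
    ref = bandpass_filter(_segment(x, fs), (80.0, 500.0)).samples[0]
    amp = snr * np.sqrt((ref**2).mean())
    truth = []
    for t0 in burst_times:
        b = _burst(fs, amp=amp)
        i0 = int(t0 * fs)
        x[i0:i0 + b.size] += b
        truth.append((t0, t0 + b.size / fs))
    return x, truth


class TestCommonAverageReference:
    def test_identical_channels_become_zero(self):
        x = np.random.default_rng(0).standard_normal(100)
        cm = ChannelMap([Channel("a", "SOZ", "depth"),
                         Channel("b", "OUT", "depth")])
        out = common_average_reference(_segment([x, x], ids=["a", "b"]), cm)
        assert np.allclose(out.samples, 0.0)

    def test_zero_mean_pair_unchanged(self):
        x = np.random.default_rng(1).standard_normal(100)
        cm = ChannelMap([Channel("a", "SOZ", "grid"),
                         Channel("b", "OUT", "grid")])
        out = common_average_reference(_segment([x, -x], ids=["a", "b"]), cm)
        assert np.allclose(out.samples, [x, -x])

    def test_per_type_mean_removed_independently(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 64))
        ids = ["d0", "d1", "d2", "g0", "g1"]
        cm = ChannelMap(
            [Channel(i, "OUT", "depth") for i in ids[:3]]
            + [Channel(i, "OUT", "grid") for i in ids[3:]]
        )
        out = common_average_reference(_segment(data, ids=ids), cm)
        # direct per-sample arithmetic oracle
        expect = data.copy()
        expect[:3] -= data[:3].mean(axis=0)
        expect[3:] -= data[3:].mean(axis=0)
        assert np.allclose(out.samples, expect)
        assert np.allclose(out.samples[:3].mean(axis=0), 0.0)
        assert np.allclose(out.samples[3:].mean(axis=0), 0.0)

    def test_single_channel_type_passes_through(self, caplog):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((3, 64))
        ids = ["d0", "d1", "s0"]
        cm = ChannelMap([Channel("d0", "OUT", "depth"),
                         Channel("d1", "OUT", "depth"),
                         Channel("s0", "OUT", "strip")])
        with caplog.at_level("WARNING"):
            out = common_average_reference(_segment(data, ids=ids), cm)
        assert np.allclose(out.samples[2], data[2])
        assert "single channel" in caplog.text


class TestBandpassFilter:
    def test_inband_sinusoid_preserved(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 140.0 * t)
        y = bandpass_filter(_segment(x)).samples[0]
        mid = slice(int(FS), int(3 * FS))
        assert abs(np.abs(y[mid]).max() - 1.0) < 0.1

    def test_out_of_band_attenuated_40db(self):
        t = np.arange(int(4 * FS)) / FS
        for f in (10.0, 40.0, 1000.0 if FS > 2100 else 10.0):
            x = np.sin(2 * np.pi * f * t)
            y = bandpass_filter(_segment(x)).samples[0]
            mid = slice(int(FS), int(3 * FS))
            assert np.abs(y[mid]).max() < 10 ** (-40 / 20)

    def test_zero_input_zero_output(self):
        y = bandpass_filter(_segment(np.zeros(8192))).samples[0]
        assert np.allclose(y, 0.0)

    def test_band_edge_beyond_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(_segment(np.zeros(8192)), (80.0, 1100.0))


class TestDetectEpoch:
    def _bg_and_filtered(self, rng, duration=20.0, burst_times=()):
        raw, truth = _noise_with_bursts(rng, FS, duration, burst_times)
        filt = bandpass_filter(_segment(raw))
        bg_seg = EEGSegment(filt.samples[:, : int(10 * FS)], FS,
                            filt.channel_ids)
        bg = compute_background(bg_seg)
        return filt, bg, truth

    def test_flat_signal_warns_and_empty(self):
        seg = _segment(np.zeros(4096))
        bg = compute_background(seg)
        with pytest.warns(UserWarning, match="flat background"):
            assert detect_epoch(seg, bg) == []

    def test_single_burst_detected_once(self):
        filt, bg, truth = self._bg_and_filtered(
            np.random.default_rng(4), burst_times=[15.0])
        events = detect_epoch(filt, bg)
        assert len(events) == 1
        (a, b), ev = truth[0], events[0]
        assert ev.start_s < b and a < ev.end_s
        assert ev.peak_rms > 0

    def test_merge_gap_rule(self):
        # the Hann-tapered pair leaves a ~26 ms sub-threshold gap: merged
        # into one event when merge_gap exceeds it, two events otherwise
        close = self._bg_and_filtered(np.random.default_rng(5),
                                      burst_times=[15.0, 15.055])
        filt, bg, _ = close
        assert len(detect_epoch(filt, bg, DetectorConfig(merge_gap_ms=40.0))) == 1
        assert len(detect_epoch(filt, bg, DetectorConfig(merge_gap_ms=10.0))) == 2
        # widely separated pair stays two events regardless
        filt, bg, _ = self._bg_and_filtered(
            np.random.default_rng(5), burst_times=[15.0, 15.3])
        assert len(detect_epoch(filt, bg, DetectorConfig(merge_gap_ms=40.0))) == 2

    def test_matches_bruteforce_run_oracle(self):
        cfg = DetectorConfig()
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            times = np.sort(rng.uniform(11.0, 19.0, 4))
            filt, bg, _ = self._bg_and_filtered(rng, burst_times=times)
            events = detect_epoch(filt, bg, cfg)
            x = filt.samples[0]
            rms = _moving_rms(x, FS, cfg.rms_window_ms)
            cid = filt.channel_ids[0]
            expected = naive_detect_runs(
                rms, np.abs(x), *bg.rms[cid], *bg.rect[cid], FS)
            assert [(round(e.start_s * FS), round(e.end_s * FS))
                    for e in events] == expected


class TestPseudoProspective:
    def _recording(self, seed, duration=700.0, n_bursts=6, n_channels=2):
        rng = np.random.default_rng(seed)
        data = []
        truth = {}
        for c in range(n_channels):
            times = np.sort(rng.uniform(601.0, duration - 2.0, n_bursts))
            x, tr = _noise_with_bursts(rng, FS, duration, times)
            data.append(x)
            truth[f"CH{c}"] = tr
        return _segment(np.array(data)), truth

    def test_short_recording_warns_empty(self):
        seg = _segment(np.random.default_rng(0).standard_normal(
            (1, int(540 * FS))))
        with pytest.warns(UserWarning, match="no events"):
            assert pseudo_prospective_detect(seg) == []

    def test_no_event_starts_before_600s(self):
        seg, _ = self._recording(6)
        # bursts before the warm-up boundary must not be reported
        b = _burst(FS, amp=50.0)
        seg.samples[0, int(100 * FS): int(100 * FS) + b.size] += b
        events = pseudo_prospective_detect(seg)
        assert events and min(e.start_s for e in events) >= 600.0

    def test_determinism(self):
        seg, _ = self._recording(7)
        assert (pseudo_prospective_detect(seg)
                == pseudo_prospective_detect(seg))

    def test_equals_bruteforce_per_window_detection(self):
        """Implementation vs independent window-by-window re-derivation."""
        cfg = DetectorConfig()
        for seed in range(5):
            seg, _ = self._recording(20 + seed, duration=700.0)
            events = pseudo_prospective_detect(seg, config=cfg)
            filt = bandpass_filter(seg, cfg.band)
            expected = []
            for ci, cid in enumerate(filt.channel_ids):
                x = filt.samples[ci]
                rms = _moving_rms(x, FS, cfg.rms_window_ms)
                ax = np.abs(x)
                for t in np.arange(600.0, 700.0 - 30.0 + 1e-9, 30.0):
                    j0, j1 = int(t * FS), int((t + 30) * FS)
                    b0 = int((t - 600.0) * FS)
                    s0, s1 = j0 - int(FS), min(x.size, j1 + int(FS))
                    runs = naive_detect_runs(
                        rms[s0:s1], ax[s0:s1],
                        rms[b0:j0].mean(), rms[b0:j0].std(),
                        ax[b0:j0].mean(), ax[b0:j0].std(), FS)
                    for i0, i1 in runs:
                        if j0 <= s0 + i0 < j1:
                            expected.append((cid, (s0 + i0) / FS,
                                             (s0 + i1) / FS))
            got = [(e.channel_id, e.start_s, e.end_s) for e in events]
            assert sorted(got) == sorted(expected)

    def test_causality_under_truncation(self):
        """Deleting future samples never changes already-emitted events."""
        seg, _ = self._recording(33, duration=720.0)
        full = pseudo_prospective_detect(seg)
        T = 690.0
        cut = _segment(seg.samples[:, : int(T * FS)])
        trunc = pseudo_prospective_detect(cut)
        keep = [e for e in full if e.end_s <= T - 30.0]
        keep_t = [e for e in trunc if e.end_s <= T - 30.0]
        assert keep == keep_t


class TestRedactArtifacts:
    def test_no_artifacts_identity(self):
        rng = np.random.default_rng(8)
        seg = _segment(rng.standard_normal(int(10 * FS)), ids=["c"])
        events = [HFOEvent("c", 2.0, 2.05), HFOEvent("c", 7.0, 7.05)]
        assert redact_artifacts(events, seg) == events

    def test_event_on_step_discontinuity_removed(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(int(10 * FS))
        x[int(5.0 * FS):] += 40.0  # sharp step at t=5
        seg = _segment(x, ids=["c"])
        events = [HFOEvent("c", 4.99, 5.04), HFOEvent("c", 8.0, 8.05)]
        kept = redact_artifacts(events, seg)
        assert kept == [events[1]]

    def test_saturation_run_removed(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(int(10 * FS))
        x[int(3.0 * FS): int(3.5 * FS)] = 123.0  # clipped flat stretch
        seg = _segment(x, ids=["c"])
        events = [HFOEvent("c", 3.1, 3.15), HFOEvent("c", 8.0, 8.05)]
        assert redact_artifacts(events, seg) == [events[1]]

    def test_empty_event_list(self):
        seg = _segment(np.random.default_rng(11).standard_normal(4096))
        assert redact_artifacts([], seg) == []


def test_detector_recall_on_embedded_bursts(small_map):
    """100 bursts at snr 10 embedded via the synthesis module: recall >= 0.9."""
    cfg = SimConfig(sampling_rate=FS, burst_snr=10.0, rng_seed=21,
                    n_soz=2, n_out=3)
    rng = np.random.default_rng(21)
    truth = []
    for ch in small_map.ids():
        for s in np.sort(rng.uniform(605.0, 795.0, 20)):
            truth.append(HFOEvent(ch, float(s), float(s) + 0.05))
    seg = synthesize_ieeg(truth, small_map, cfg, duration=810.0)
    detected = pseudo_prospective_detect(seg, small_map)
    hit = 0
    for t in truth:
        if any(d.channel_id == t.channel_id and d.start_s < t.end_s
               and t.start_s < d.end_s for d in detected):
            hit += 1
    assert hit / len(truth) >= 0.9
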