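"""Cycle segmentation: R detection, truncation, labels, curvature, extrema."""

import numpy as np
import pytest

from cardiovib import segment as sg
from cardiovib import simulate as sim

FS = 2000.0


class TestDetectRPeaks:
    def test_flat_trace_empty(self):
        peaks = sg.detect_r_peaks(np.zeros(int(10 * FS)), FS)
        assert len(peaks) == 0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="3 s"):
            sg.detect_r_peaks(np.zeros(100), FS)

    def test_full_recall_on_default_noise(self, default_recording):
        rec = default_recording
        peaks = sg.detect_r_peaks(rec.ecg, rec.sampling_rate)
        truth = rec.cycle_start_samples
        tol = int(0.010 * rec.sampling_rate)
        hits = sum(
            np.min(np.abs(np.asarray(peaks.indices) - t)) <= tol for t in truth
        )
        assert hits == len(truth)
        assert len(peaks) == len(truth)

    def test_mean_rr_jitter_free(self):
        cfg = sim.with_noise_free(sim.SimulationConfig(seed=1, n_cycles=20))
        rec = sim.synthesize_recording(cfg)
        peaks = sg.detect_r_peaks(rec.ecg, rec.sampling_rate)
        rr = np.diff(peaks.indices) / rec.sampling_rate
        assert abs(np.mean(rr) - 0.8) <= 1 / rec.sampling_rate

    def test_rr_bounds_validated(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            sg.RPeakList(np.array([10, 10]), FS).validate()
        with pytest.raises(ValueError, match="plausibility"):
            sg.RPeakList(np.array([0, 100]), FS).validate()  # 50 ms


class TestTruncateCycles:
    def _peaks(self, idx):
        return sg.RPeakList(np.asarray(idx), FS)

    def test_exact_length_cycle(self):
        x = np.arange(6000, dtype=float)
        segs = sg.truncate_cycles({"SCG": x}, self._peaks([0, 2048, 4096]))
        assert len(segs) == 2
        assert segs[0].pad_length == 0
        assert not segs[0].truncated
        assert np.array_equal(segs[0].traces["SCG"], x[:2048])

    def test_short_cycle_zero_padded(self):
        x = np.ones(6000)
        segs = sg.truncate_cycles({"SCG": x}, self._peaks([0, 1600, 3200]))
        assert segs[0].pad_length == 2048 - 1600
        assert np.all(segs[0].traces["SCG"][1600:] == 0.0)
        assert np.all(segs[0].traces["SCG"][:1600] == 1.0)

    def test_long_cycle_truncated_and_flagged(self):
        x = np.ones(8000)
        segs = sg.truncate_cycles({"SCG": x}, self._peaks([0, 3000, 6000]))
        assert segs[0].truncated
        assert segs[0].length == 2048

    def test_constant_length_regardless_of_rate(self, default_recording,
                                                default_bands):
        rec = default_recording
        peaks = sg.detect_r_peaks(rec.ecg, rec.sampling_rate)
        segs = sg.truncate_cycles(
            {k: v for k, v in default_bands.items() if k != "ECG"}, peaks
        )
        assert all(s.length == 2048 for s in segs)

    def test_final_incomplete_cycle_dropped(self):
        x = np.ones(5000)
        segs = sg.truncate_cycles({"SCG": x}, self._peaks([0, 1600, 3200]))
        assert len(segs) == 2  # nothing emitted past the last R

    def test_partition_property(self, default_recording, default_bands):
        rec = default_recording
        peaks = sg.detect_r_peaks(rec.ecg, rec.sampling_rate)
        scg = default_bands["SCG"]
        segs = sg.truncate_cycles({"SCG": scg}, peaks)
        cores = [
            s.traces["SCG"][: min(s.cycle_length, s.length)] for s in segs
        ]
        joined = np.concatenate(cores)
        first, last = peaks.indices[0], peaks.indices[-1]
        if all(s.cycle_length <= s.length for s in segs):
            assert np.array_equal(joined, scg[first:last])

    def test_needs_two_peaks(self):
        with pytest.raises(ValueError, match="2 R-peaks"):
            sg.truncate_cycles({"SCG": np.ones(3000)}, self._peaks([5]))


class TestAttachLabels:
    def _dataset(self, n_cycles=5, period=0.8, jitter=0.0):
        scheds = [
            sim.make_event_schedule(period, jitter=jitter, cycle_index=i,
                                    rng=np.random.default_rng(i))
            for i in range(n_cycles)
        ]
        clen = round(period * FS)
        idx = np.arange(n_cycles + 1) * clen
        x = np.zeros(idx[-1] + 10)
        segs = sg.truncate_cycles({"SCG": x, "PCG": x}, sg.RPeakList(idx, FS))
        return segs, scheds

    def test_event_at_r_is_label_zero(self):
        segs, scheds = self._dataset(2)
        scheds[0].event_times["MC"] = 1e-9  # effectively at the R sample
        ds = sg.attach_labels(segs, scheds, FS)
        assert ds.segments[0].labels["MC"] == 0

    def test_unit_conversion_100ms(self):
        segs, scheds = self._dataset(2)
        scheds[0].event_times["AO"] = 0.100
        ds = sg.attach_labels(segs, scheds, FS)
        assert ds.segments[0].labels["AO"] == 200

    def test_500_cycles_no_exclusions(self):
        segs, scheds = self._dataset(500, period=0.8, jitter=0.005)
        ds = sg.attach_labels(segs, scheds, FS)
        assert ds.n_excluded == 0
        assert len(ds) == 500

    def test_mismatch_rejected(self):
        segs, scheds = self._dataset(3)
        with pytest.raises(ValueError, match="one schedule per R-R"):
            sg.attach_labels(segs, scheds[:-1], FS)

    def test_label_out_of_window_excluded(self):
        segs, scheds = self._dataset(2)
        scheds[1].event_times["RF"] = 0.79999  # rounds to cycle length: out
        ds = sg.attach_labels(segs, scheds, FS)
        assert ds.n_excluded == 1
        assert len(ds) == 1

    def test_wt_as_never_targets(self):
        segs, scheds = self._dataset(2)
        ds = sg.attach_labels(segs, scheds, FS)
        assert "WT" not in ds.feature_names
        assert "AS" not in ds.feature_names
        assert set(ds.feature_names) == set(sim.EXTRACTION_TARGETS)


class TestLabelRoundTrip:
    def test_exact_recovery_noise_free(self):
        from cardiovib import bands as bd

        cfg = sim.with_noise_free(sim.SimulationConfig(seed=5, n_cycles=10))
        rec = sim.synthesize_recording(cfg)
        traces = bd.decompose_bands(rec.vibration, rec.ecg, rec.sampling_rate)
        ds = sg.segment_recording(
            rec, {k: v for k, v in traces.items() if k != "ECG"},
            use_true_onsets=True,
        )
        assert len(ds) == 10
        fs = rec.sampling_rate
        for seg, sched in zip(ds.segments, rec.schedules):
            for feat in ds.feature_names:
                assert seg.labels[feat] == round(sched.event_times[feat] * fs)


class TestCurvature:
    def test_line_zero_curvature(self):
        x = np.linspace(0.0, 5.0, 100)
        k = sg.curvature_trace(2.0 * x + 1.0, dx=x[1] - x[0])
        assert np.allclose(k[1:-1], 0.0, atol=1e-9)

    def test_circle_unit_curvature(self):
        xs = np.linspace(-0.7, 0.7, 5000)
        ys = np.sqrt(1.0 - xs**2)  # upper unit-circle arc sampled in x
        k = sg.curvature_trace(ys, dx=xs[1] - xs[0])
        interior = k[100:-100]
        assert np.allclose(interior, 1.0, atol=0.02)

    def test_parabola_apex(self):
        x = np.linspace(-1.0, 1.0, 20001)
        k = sg.curvature_trace(x**2, dx=x[1] - x[0])
        apex = k[len(x) // 2]
        assert abs(apex - 2.0) < 1e-3

    def test_min_length(self):
        with pytest.raises(ValueError, match="3 samples"):
            sg.curvature_trace(np.array([1.0, 2.0]))

    def test_same_length_output(self):
        x = np.sin(np.linspace(0, 10, 500))
        assert sg.curvature_trace(x).shape == x.shape


class TestUlfExtrema:
    def test_recovery_noise_free(self, noise_free_recording):
        from cardiovib import bands as bd

        rec = noise_free_recording
        fs = rec.sampling_rate
        ulf = bd.zero_phase_bandpass(
            rec.vibration, bd.CANONICAL_BANDS["ULF-SCG"], fs
        )
        onsets = rec.cycle_start_samples
        ends = np.concatenate(
            [onsets, [onsets[-1] + round(rec.schedules[-1].period_T * fs)]]
        )
        res = sg.ulf_extrema(ulf, sg.RPeakList(ends, fs))
        tol = int(0.020 * fs)
        for e in res:
            if e["cycle_index"] >= len(rec.schedules):
                continue
            assert not e["flagged"]
            sched = rec.schedules[e["cycle_index"]]
            start = onsets[e["cycle_index"]]
            assert abs(e["WC"] - start - sched.event_times["WC"] * fs) <= tol
            assert abs(e["WT"] - start - sched.event_times["WT"] * fs) <= tol

    def test_constant_trace_flagged(self):
        res = sg.ulf_extrema(
            np.zeros(4000), sg.RPeakList(np.array([0, 1600, 3200]), FS)
        )
        assert all(e["flagged"] for e in res)

    def test_wc_before_wt(self, default_recording, default_bands):
        rec = default_recording
        peaks = sg.detect_r_peaks(rec.ecg, rec.sampling_rate)
        res = sg.ulf_extrema(default_bands["ULF-SCG"], peaks)
        for e in res:
            if not e["flagged"]:
                assert e["WC"] < e["WT"]
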