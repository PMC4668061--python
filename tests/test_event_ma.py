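import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcgseg import (InsufficientEventsError, MethodVParams, PCGError,
                    SilentRecordError, detect_method_v, label_s1_s2,
                    match_events, metrics, moving_average)
from pcgseg.event_ma import (Region, blocks_of_interest, filter_blocks,
                             localize_peaks, odd_window_samples, square)
from pcgseg.records import HeartSoundRecord


class TestSquare:
    def test_values(self):
        assert np.allclose(square(np.array([-1.0, 0.5, 0.0])), [1.0, 0.25, 0.0])

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50))
    @settings(max_examples=25, deadline=None)
    def test_nonnegative_and_even(self, xs):
        x = np.asarray(xs)
        assert np.all(square(x) >= 0.0)
        assert np.array_equal(square(x), square(-x))


class TestMovingAverage:
    def test_constant_signal_unchanged(self):
        out = moving_average(np.full(100, 3.5), 0.005, 4000.0)
        assert np.allclose(out, 3.5)

    def test_impulse_becomes_plateau(self):
        y = np.zeros(51)
        y[25] = 1.0
        out = moving_average(y, 5 / 4000.0, 4000.0)  # 5-sample window
        assert np.allclose(out[23:28], 0.2)
        assert np.allclose(out[:21], 0.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(0, 1, 400)
        w = odd_window_samples(0.005, 4000.0)
        half = w // 2
        oracle = np.array([
            np.mean(y[max(0, i - half):min(len(y), i + half + 1)])
            for i in range(len(y))])
        out = moving_average(y, 0.005, 4000.0)
        assert np.allclose(out, oracle, rtol=1e-12, atol=1e-12)

    def test_window_rounded_to_odd(self):
        assert odd_window_samples(0.130, 4000.0) == 521
        assert odd_window_samples(0.270, 4000.0) == 1081
        assert odd_window_samples(519 / 4000.0, 4000.0) == 519


class TestBlocks:
    def test_no_excursion_gives_no_blocks(self):
        assert blocks_of_interest(np.zeros(50), np.ones(50)) == []

    def test_single_excursion(self):
        ma = np.zeros(1000)
        ma[100:400] = 1.0
        blocks = blocks_of_interest(ma, np.full(1000, 0.5))
        assert blocks == [Region(100, 400)]

    def test_one_subthreshold_sample_splits_blocks(self):
        ma = np.ones(100)
        ma[50] = 0.0
        blocks = blocks_of_interest(ma, np.full(100, 0.5))
        assert blocks == [Region(0, 50), Region(51, 100)]

    def test_width_filter_keeps_geq(self):
        blocks = [Region(0, 100), Region(200, 439), Region(500, 740),
                  Region(800, 1300)]
        kept = filter_blocks(blocks, 240)
        assert [b.width for b in kept] == [240, 500]

    def test_width_filter_trivia(self):
        assert filter_blocks([], 10) == []
        wide = [Region(0, 500), Region(600, 1200)]
        assert filter_blocks(wide, 100) == wide


class TestLocalizePeaks:
    def test_argmax_of_magnitude(self):
        x = np.zeros(30)
        x[14] = -2.0
        assert localize_peaks([Region(10, 20)], x).tolist() == [14]

    def test_tie_broken_to_earliest(self):
        x = np.zeros(30)
        x[12] = 1.0
        x[17] = -1.0
        assert localize_peaks([Region(10, 20)], x).tolist() == [12]


class TestLabeling:
    def test_short_systole_first(self):
        table = label_s1_s2(np.array([0.0, 0.3, 1.0, 1.3, 2.0]) * 4000, 4000.0)
        assert table.labels == ("S1", "S2", "S1", "S2", "S1")

    def test_long_interval_first(self):
        table = label_s1_s2(np.array([0.0, 0.7, 1.0, 1.7, 2.0]) * 4000, 4000.0)
        assert table.labels == ("S2", "S1", "S2", "S1", "S2")

    def test_too_few_events_rejected(self):
        with pytest.raises(InsufficientEventsError):
            label_s1_s2(np.array([0.0, 1.0]) * 4000, 4000.0)

    def test_matches_ground_truth_on_synthetic_records(self):
        """Interval labeling recovers truth for complete synthetic beats."""
        from pcgseg import SynthParams, generate_record
        for seed in range(5):
            sr = generate_record(SynthParams(hr_bpm=75.0 + 10 * seed,
                                             seed=seed, duration_s=10.0))
            table = label_s1_s2(sr.annotations.times_s * sr.record.fs,
                                sr.record.fs)
            assert table.labels == sr.annotations.labels


class TestDetectMethodV:
    def test_default_parameters(self):
        p = MethodVParams()
        assert (p.w1_s, p.w2_s, p.block_s, p.beta) == (0.130, 0.270, 0.060,
                                                       0.03)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(PCGError):
            MethodVParams(w1_s=0.3, w2_s=0.2)
        with pytest.raises(PCGError):
            MethodVParams(beta=0.5)

    def test_silent_record_rejected(self):
        rec = HeartSoundRecord(np.zeros(80_000), 4000.0)
        with pytest.raises(SilentRecordError):
            detect_method_v(rec)

    def test_clean_record_80bpm_fully_detected(self, clean_record_80bpm):
        """One S1 and one S2 per beat, each within 5 ms of annotation."""
        table = detect_method_v(clean_record_80bpm.record)
        assert len(table) == len(clean_record_80bpm.annotations)
        assert table.alternates()
        mets = metrics(match_events(table, clean_record_80bpm.annotations))
        assert mets.SE == 100.0
        assert mets.PPV == 100.0

    def test_amplitude_scale_invariance(self, clean_record_80bpm):
        rec = clean_record_80bpm.record
        scaled = HeartSoundRecord(0.2 * rec.samples, rec.fs)
        a = detect_method_v(rec)
        b = detect_method_v(scaled)
        assert np.array_equal(a.times_s, b.times_s)
        assert a.labels == b.labels

    def test_deterministic(self, clean_record_80bpm):
        a = detect_method_v(clean_record_80bpm.record)
        b = detect_method_v(clean_record_80bpm.record)
        assert np.array_equal(a.times_s, b.times_s) and a.labels == b.labels

    def test_events_lie_inside_disjoint_blocks(self, clean_record_80bpm):
        table, trace = detect_method_v(clean_record_80bpm.record,
                                       return_trace=True)
        blocks = trace.blocks
        for b1, b2 in zip(blocks, blocks[1:]):
            assert b1.offset_idx <= b2.onset_idx
        fs = clean_record_80bpm.record.fs
        for t in table.times_s:
            idx = int(round(t * fs))
            assert any(b.onset_idx <= idx < b.offset_idx for b in blocks)

    def test_trace_invariants(self, clean_record_80bpm):
        _, trace = detect_method_v(clean_record_80bpm.record,
                                   return_trace=True)
        assert np.all(trace.y >= 0.0)
        assert trace.alpha >= 0.0
        assert np.allclose(trace.thr1, trace.ma_wave + trace.alpha)
        assert all(b.width >= trace.thr2_samples for b in trace.blocks)
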