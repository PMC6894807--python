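"""AMPD peak detection, envelopes, reduced-excursion segmentation and
breath-onset assembly."""

import numpy as np
import pytest

from respibench.breaths import (
    BreathCycle, ReducedSegment, compute_excursion, detect_breath_onsets,
    detect_peaks_valleys, find_reduced_excursion_segments, OnsetSource,
    rescue_missed_cycles, select_reference_rip,
)
from respibench.errors import DataQualityError

FS = 20.0


def _sine(ttot_s: float, duration_s: float = 180.0, amp: float = 1.0):
    t = np.arange(0, duration_s, 1 / FS)
    return t, amp * np.sin(2 * np.pi * t / ttot_s)


class TestDetectPeaksValleys:
    @pytest.mark.parametrize("ttot,expected", [(4.0, 45), (2.5, 72)])
    def test_cycle_count_in_three_minute_window(self, ttot, expected):
        _, x = _sine(ttot)
        peaks, valleys = detect_peaks_valleys(x, FS)
        assert abs(len(peaks) - expected) <= 1
        assert abs(len(valleys) - expected) <= 1

    def test_peak_positions_match_analytic_maxima(self):
        t, x = _sine(4.0)
        peaks, _ = detect_peaks_valleys(x, FS)
        # oracle: argmax of each analytic period at t = 1 + 4k
        expected = 20 + 80 * np.arange(45)
        matched = sum(1 for p in peaks if np.min(np.abs(expected - p)) <= 1)
        assert matched >= len(peaks) - 1

    def test_alternation(self):
        _, x = _sine(3.0)
        peaks, valleys = detect_peaks_valleys(x, FS)
        marks = sorted([(p, 1) for p in peaks] + [(v, 0) for v in valleys])
        kinds = [k for _, k in marks]
        assert all(a != b for a, b in zip(kinds[:-1], kinds[1:]))

    def test_constant_signal_has_no_peaks(self):
        peaks, valleys = detect_peaks_valleys(np.full(3600, 2.0), FS)
        assert len(peaks) == 0 and len(valleys) == 0

    def test_empty_signal(self):
        peaks, valleys = detect_peaks_valleys(np.empty(0), FS)
        assert len(peaks) == 0 and len(valleys) == 0


class TestRescueMissedCycles:
    def test_deleted_peak_restored(self):
        t, x = _sine(4.0)
        peaks, valleys = detect_peaks_valleys(x, FS)
        victim = peaks[10]
        kept_p = np.delete(peaks, 10)
        # drop the neighbouring valley too so the gap is clean
        p2, v2 = rescue_missed_cycles(
            x, kept_p, valleys, FS, mean_amplitude=2.0, mean_ttot_s=4.0)
        assert np.min(np.abs(p2 - victim)) <= 2

    def test_flat_gap_inserts_nothing(self):
        x = np.concatenate([_sine(4.0, 40)[1], np.zeros(400), _sine(4.0, 40)[1]])
        peaks, valleys = detect_peaks_valleys(x, FS)
        n_before = len(peaks)
        p2, _ = rescue_missed_cycles(
            x, peaks, valleys, FS, mean_amplitude=2.0, mean_ttot_s=4.0)
        in_gap = [p for p in p2 if 800 <= p < 1200]
        assert len(in_gap) == 0

    def test_subthreshold_ripple_ignored(self):
        # oracle: ripple amplitude 0.05 < 0.2 * mean amplitude / 2
        t = np.arange(0, 40, 1 / FS)
        x = np.concatenate([np.sin(2 * np.pi * t / 4),
                            0.05 * np.sin(2 * np.pi * t / 4),
                            np.sin(2 * np.pi * t / 4)])
        peaks, valleys = detect_peaks_valleys(x, FS)
        big_p = np.array([p for p in peaks if x[p] > 0.5])
        big_v = np.array([v for v in valleys if x[v] < -0.5])
        p2, _ = rescue_missed_cycles(
            x, big_p, big_v, FS, mean_amplitude=2.0, mean_ttot_s=4.0)
        assert not any(800 <= p < 1600 and abs(x[p]) < 0.1 for p in p2)


class TestExcursion:
    def test_constant_sine_excursion_is_twice_amplitude(self):
        _, x = _sine(4.0, amp=0.7)
        peaks, valleys = detect_peaks_valleys(x, FS)
        exc = compute_excursion(x, peaks, valleys, FS)
        interior = exc.excursion[200:-200]
        assert np.all(np.abs(interior - 1.4) < 0.07)  # within 5%

    def test_amplitude_modulated_sine_tracked(self):
        t = np.arange(0, 300, 1 / FS)
        env = 1.0 + 0.5 * np.sin(2 * np.pi * t / 120)   # modulation >> Ttot
        x = env * np.sin(2 * np.pi * t / 4)
        peaks, valleys = detect_peaks_valleys(x, FS)
        exc = compute_excursion(x, peaks, valleys, FS)
        sl = slice(400, -400)
        assert np.all(np.abs(exc.excursion[sl] / (2 * env[sl]) - 1) < 0.10)

    def test_flat_flow_raises(self):
        with pytest.raises(DataQualityError):
            compute_excursion(np.zeros(100), np.empty(0, int), np.empty(0, int), FS)

    def test_excursion_nonnegative(self):
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * np.arange(0, 120, 1 / FS) / 4) + rng.normal(0, 0.1, 2400)
        peaks, valleys = detect_peaks_valleys(x, FS)
        exc = compute_excursion(x, peaks, valleys, FS)
        assert np.all(exc.excursion >= 0)


class TestReducedSegments:
    def _track(self, drop_frac, drop_dur_s, total_s=400.0):
        """Excursion = 1 with a scripted drop starting at 300 s."""
        n = int(total_s * FS)
        exc = np.ones(n)
        i0 = int(300 * FS)
        exc[i0:i0 + int(drop_dur_s * FS)] = drop_frac
        from respibench.breaths import ExcursionTrack
        return ExcursionTrack(exc, np.zeros(n), exc, np.empty(0, int),
                              np.empty(0, int), FS)

    def test_deep_drop_detected(self):
        segs = find_reduced_excursion_segments(self._track(0.30, 10.0))
        assert len(segs) == 1
        assert segs[0].start == pytest.approx(300 * FS, abs=2)
        assert segs[0].baseline == pytest.approx(1.0, rel=0.01)

    def test_short_drop_rejected_by_duration_rule(self):
        assert find_reduced_excursion_segments(self._track(0.30, 3.0)) == []

    def test_no_drop_no_segments(self):
        assert find_reduced_excursion_segments(self._track(1.0, 0.0)) == []


class TestReferenceRip:
    def _segment(self):
        return ReducedSegment(int(300 * FS), int(320 * FS), 1.0)

    def _rip(self, pre_amp, seg_amp, total_s=400.0):
        t = np.arange(0, total_s, 1 / FS)
        amp = np.full(len(t), pre_amp)
        amp[int(300 * FS):int(320 * FS)] = seg_amp
        return amp * np.sin(2 * np.pi * t / 4)

    def test_larger_relative_modulation_wins(self):
        th = self._rip(1.0, 0.5)
        ab = self._rip(1.0, 0.1)
        ref, ok = select_reference_rip(th, ab, self._segment(), FS)
        assert ref is OnsetSource.RIP_THORAX and ok

    def test_abdomen_wins_when_thorax_flat(self):
        th = self._rip(1.0, 0.05)
        ab = self._rip(1.0, 0.8)
        ref, ok = select_reference_rip(th, ab, self._segment(), FS)
        assert ref is OnsetSource.RIP_ABDOMEN and ok

    def test_tie_goes_to_thorax(self):
        th = self._rip(1.0, 0.5)
        ref, ok = select_reference_rip(th, th.copy(), self._segment(), FS)
        assert ref is OnsetSource.RIP_THORAX

    def test_both_flat_flags_central(self):
        th = self._rip(1.0, 0.01)
        _, ok = select_reference_rip(th, th.copy(), self._segment(), FS)
        assert not ok


class TestBreathOnsets:
    def test_sine_onsets_at_ascending_zero_crossings(self):
        _, x = _sine(4.0)
        peaks, valleys = detect_peaks_valleys(x, FS)
        exc = compute_excursion(x, peaks, valleys, FS)
        cycles = detect_breath_onsets(x, exc, np.zeros_like(x),
                                      np.zeros_like(x), [], FS)
        onsets = np.array([c.onset_s for c in cycles])
        # analytic ascending crossings at t = 4k
        frac = np.abs((onsets / 4.0) - np.round(onsets / 4.0))
        assert np.all(frac * 4.0 <= 0.051)
        ttots = np.array([c.ttot_s for c in cycles])
        assert np.all(np.abs(ttots - 4.0) <= 0.051)

    def test_cycle_amplitude_matches_bruteforce(self):
        _, x = _sine(4.0, amp=0.8)
        peaks, valleys = detect_peaks_valleys(x, FS)
        exc = compute_excursion(x, peaks, valleys, FS)
        cycles = detect_breath_onsets(x, exc, np.zeros_like(x),
                                      np.zeros_like(x), [], FS)
        for c in cycles[:10]:
            i, j = int(c.onset_s * FS), int(c.end_s * FS)
            assert c.amplitude == pytest.approx(x[i:j].max() - x[i:j].min())

    def test_empty_record(self):
        from respibench.breaths import ExcursionTrack
        exc = ExcursionTrack(np.empty(0), np.empty(0), np.empty(0),
                             np.empty(0, int), np.empty(0, int), FS)
        assert detect_breath_onsets(np.empty(0), exc, np.empty(0),
                                    np.empty(0), [], FS) == []

    def test_onsets_against_generator_ground_truth(self, short_record, config):
        from respibench.pipeline import _detect_cycles
        record, gt = short_record
        cycles, _, _ = _detect_cycles(
            record.vsource, config.fs, config,
            record.series["rip_thorax"], record.series["rip_abdomen"], 0.0)
        det = np.array([c.onset_s for c in cycles])
        truth = gt.cycle_onsets()
        truth = truth[(truth > 5) & (truth < record.duration_s - 10)]
        err = np.abs(det[None, :] - truth[:, None]).min(axis=1)
        assert np.mean(err <= 0.15) >= 0.95

    def test_rip_onsets_during_obstruction(self):
        """During a scripted obstructive apnea the reference RIP valleys
        stand in for the vanished airflow onsets (3 s attempt period)."""
        t = np.arange(0, 400, 1 / FS)
        x = np.sin(2 * np.pi * t / 4)
        seg0, seg1 = int(300 * FS), int(330 * FS)
        x[seg0:seg1] *= 0.02
        rip = -np.cos(2 * np.pi * t / 4)       # valleys at flow onsets
        rip[seg0:seg1] = -np.cos(2 * np.pi * (t[seg0:seg1] - t[seg0]) / 3.0)
        peaks, valleys = detect_peaks_valleys(x, FS)
        exc = compute_excursion(x, peaks, valleys, FS)
        reduced = find_reduced_excursion_segments(exc)
        assert len(reduced) >= 1
        cycles = detect_breath_onsets(x, exc, rip, 0.5 * rip, reduced, FS)
        inside = [c for c in cycles
                  if 302 < c.onset_s < 328 and c.onset_source is not OnsetSource.FLOW]
        assert len(inside) >= 6
        gaps = np.diff([c.onset_s for c in inside])
        assert np.all(np.abs(gaps - 3.0) < 0.5)
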