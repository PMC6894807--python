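"""Apnea/hypopnea detection, obstruction evidence, and the IFL classifier."""

import numpy as np
import pytest

from respibench.breaths import BreathCycle, CycleLabel, ExcursionTrack
from respibench.events import (
    SDBEvent, classify_apnea, classify_hypopnea, classify_ifl, detect_apneas,
    detect_hypopneas, detect_paradox, detect_snore, event_indices,
    extract_ifl_features, train_ifl_model,
)

FS = 20.0


def _exc_track(drop_frac, drop_dur_s, total_s=500.0, onset_s=300.0):
    n = int(total_s * FS)
    exc = np.ones(n)
    i0 = int(onset_s * FS)
    exc[i0:i0 + int(drop_dur_s * FS)] = drop_frac
    return ExcursionTrack(exc, np.zeros(n), exc, np.empty(0, int),
                          np.empty(0, int), FS)


def _confirm(drop, drop_dur_s, total_s=500.0, onset_s=300.0):
    n = int(total_s * FS)
    c = np.ones(n)
    i0 = int(onset_s * FS)
    c[i0:i0 + int(drop_dur_s * FS)] = 1.0 - drop
    return c


class TestDetectApneas:
    def test_deep_confirmed_drop_detected(self):
        events = detect_apneas(_exc_track(0.05, 15.0), _confirm(0.5, 15.0))
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(300.0, abs=1.0)
        assert 10.0 <= events[0].duration_s <= 20.0
        assert events[0].baseline_excursion == pytest.approx(1.0, rel=0.01)

    def test_below_minimum_duration_rejected(self):
        assert detect_apneas(_exc_track(0.05, 8.0), _confirm(0.5, 8.0)) == []

    def test_mouth_breathing_mimic_rejected(self):
        # deep nasal drop but the secondary flow channel barely moves
        assert detect_apneas(_exc_track(0.05, 15.0), _confirm(0.05, 15.0)) == []

    def test_over_three_minutes_rejected(self):
        ev = detect_apneas(_exc_track(0.05, 200.0, total_s=600.0),
                           _confirm(0.5, 200.0, total_s=600.0))
        assert ev == []

    def test_no_confirmation_channel_excluded_by_default(self):
        assert detect_apneas(_exc_track(0.05, 15.0), None) == []
        kept = detect_apneas(_exc_track(0.05, 15.0), None, allow_unconfirmed=True)
        assert len(kept) == 1 and not kept[0].confirmed


class TestClassifyApnea:
    def _rip(self, attempt_frac, total_s=500.0, onset_s=300.0, dur_s=15.0):
        t = np.arange(0, total_s, 1 / FS)
        rip = np.sin(2 * np.pi * t / 4)
        i0, i1 = int(onset_s * FS), int((onset_s + dur_s) * FS)
        rip[i0:i1] *= attempt_frac
        exc = 2.0 * np.ones(len(t))
        exc[i0:i1] = 2.0 * attempt_frac
        return rip, exc

    def _event(self):
        return SDBEvent(onset_s=300.0, duration_s=15.0, baseline_excursion=1.0)

    def test_significant_attempts_make_obstructive(self):
        rip, exc = self._rip(0.4)
        ev = classify_apnea(self._event(), rip, exc, FS)
        assert ev.kind is CycleLabel.OA
        assert all(sig for _, sig in ev.attempts)

    def test_flat_rip_is_central(self):
        rip, exc = self._rip(0.0)
        ev = classify_apnea(self._event(), rip, exc, FS)
        assert ev.kind is CycleLabel.CA
        assert not any(sig for _, sig in ev.attempts)

    def test_insignificant_attempts_are_central(self):
        rip, exc = self._rip(0.05)
        ev = classify_apnea(self._event(), rip, exc, FS)
        assert ev.kind is CycleLabel.CA


class TestDetectHypopneas:
    def test_moderate_confirmed_drop_detected(self):
        ev = detect_hypopneas(_exc_track(0.5, 20.0), _confirm(0.15, 20.0), [])
        assert len(ev) == 1

    def test_shallow_drop_rejected(self):
        assert detect_hypopneas(_exc_track(0.8, 20.0), _confirm(0.15, 20.0), []) == []

    def test_sensor_displacement_guard(self):
        assert detect_hypopneas(_exc_track(0.5, 200.0, total_s=600.0),
                                _confirm(0.15, 200.0, total_s=600.0), []) == []

    def test_apnea_interval_excluded_from_candidacy(self):
        apnea = SDBEvent(onset_s=300.0, duration_s=20.0)
        apnea.kind = CycleLabel.OA
        ev = detect_hypopneas(_exc_track(0.05, 20.0), _confirm(0.5, 20.0), [apnea])
        assert ev == []


class TestSnoreParadox:
    def _cycle(self):
        return BreathCycle(onset_s=0.0, end_s=4.0, insp_peak_s=1.0,
                           exp_valley_s=2.5, amplitude=1.0)

    def _flow(self):
        t = np.arange(0, 4, 1 / FS)
        return np.sin(2 * np.pi * t / 4)

    def test_inspiratory_burst_is_snoring(self):
        audio = np.full(80, 0.1)
        audio[:40] = 1.0              # 10x power during inspiration
        assert detect_snore(audio, self._flow(), self._cycle(), FS)

    def test_uniform_audio_is_not(self):
        assert not detect_snore(np.full(80, 0.5), self._flow(), self._cycle(), FS)

    def test_expiratory_noise_is_not(self):
        audio = np.full(80, 0.1)
        audio[40:] = 1.0
        assert not detect_snore(audio, self._flow(), self._cycle(), FS)

    def test_antiphase_bands_are_paradox(self):
        t = np.arange(0, 4, 1 / FS)
        th = np.sin(2 * np.pi * t / 4)
        assert detect_paradox(th, -th, self._cycle(), FS)

    def test_in_phase_bands_are_not(self):
        t = np.arange(0, 4, 1 / FS)
        th = np.sin(2 * np.pi * t / 4)
        assert not detect_paradox(th, th.copy(), self._cycle(), FS)

    def test_quarter_period_shift_follows_closeness_rule(self):
        # oracle: explicit extrema arithmetic on the sinusoids.  thorax peak
        # at t=1; abdomen = sin(2*pi*(t-1)/4) peaks at t=2, valley at t=0
        # within the cycle -> |1-0| = 1 < |1-2| = 1 is false (tie), so the
        # strict inequality reports no paradox
        t = np.arange(0, 4, 1 / FS)
        th = np.sin(2 * np.pi * t / 4)
        ab = np.sin(2 * np.pi * (t - 1.0) / 4)
        assert not detect_paradox(th, ab, self._cycle(), FS)

    def test_flat_band_is_not_paradox(self):
        t = np.arange(0, 4, 1 / FS)
        th = np.sin(2 * np.pi * t / 4)
        assert not detect_paradox(th, np.zeros_like(th), self._cycle(), FS)


class TestIFLFeatures:
    def _half_sine(self, n=32):
        return np.sin(np.pi * np.arange(n) / (n - 1))

    def test_half_sine_is_single_peaked_and_round(self):
        f = extract_ifl_features(self._half_sine(), baseline_amp=1.0)
        assert f.peak_count == 1
        assert f.deviation_index < 0.05     # essentially the fitted template
        assert f.norm_peak_amp == pytest.approx(1.0, abs=0.01)

    def test_plateau_is_flatter_and_more_scooped_than_half_sine(self):
        # oracle: hand evaluation of the local definitions on both shapes
        round_f = extract_ifl_features(self._half_sine(), 1.0)
        clipped = np.minimum(self._half_sine(), 0.7)
        flat_f = extract_ifl_features(clipped, 1.0)
        assert flat_f.flattening_index > round_f.flattening_index
        assert flat_f.deviation_index > round_f.deviation_index
        # fraction of the limb within 15% of the peak, computed analytically:
        # sin(theta) >= 0.85 * 1 on [0, pi] covers (pi - 2*asin(0.85)) / pi
        expected = 1 - 2 * np.arcsin(0.85) / np.pi
        assert round_f.flattening_index == pytest.approx(expected, abs=0.08)
        # every clipped sample sits at the plateau = the peak
        expected_flat = 1 - 2 * np.arcsin(0.7) / np.pi
        assert flat_f.flattening_index == pytest.approx(expected_flat, abs=0.08)

    def test_two_peaked_limb_counted(self):
        x = np.concatenate([self._half_sine(16), self._half_sine(16)])
        assert extract_ifl_features(x, 1.0).peak_count == 2

    def test_degenerate_limb_flagged(self):
        assert extract_ifl_features(np.zeros(20), 1.0).degenerate
        assert extract_ifl_features(np.ones(3), 1.0).degenerate


class TestIFLModel:
    def test_heldout_accuracy_on_synthetic_corpus(self):
        from sklearn.model_selection import train_test_split
        from respibench.synth import generate_ifl_corpus
        X, y = generate_ifl_corpus(seed=42)
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=0.25, random_state=0, stratify=y)
        model = train_ifl_model(Xtr, ytr, seed=42)
        acc = np.mean(model._clf.predict(Xte) == yte)
        assert acc >= 0.9

    def test_separable_clouds_learned_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (200, 7)), rng.normal(5, 0.1, (200, 7))])
        y = np.repeat([0, 1], 200)
        model = train_ifl_model(X, y, seed=1)
        assert np.mean(model._clf.predict(X) == y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_ifl_model(np.zeros((50, 7)), np.zeros(50))

    def test_gross_imbalance_rejected(self):
        X = np.zeros((120, 7))
        y = np.array([1] * 5 + [0] * 115)
        with pytest.raises(ValueError, match="imbalance"):
            train_ifl_model(X, y)

    def test_untrained_model_refuses(self):
        from respibench.events import IFLModel
        f = extract_ifl_features(np.sin(np.pi * np.arange(32) / 31), 1.0)
        with pytest.raises(RuntimeError, match="untrained"):
            classify_ifl(f, IFLModel())


class TestClassifyHypopnea:
    def _event(self):
        return SDBEvent(onset_s=0.0, duration_s=20.0)

    def test_paradox_alone_is_obstructive(self):
        ev = classify_hypopnea(self._event(), [{"paradox"}, set()])
        assert ev.kind is CycleLabel.OH and ev.evidence == {"paradox"}

    def test_no_evidence_is_central(self):
        ev = classify_hypopnea(self._event(), [set(), set()])
        assert ev.kind is CycleLabel.CH and ev.evidence == set()

    def test_evidence_union_recorded(self):
        ev = classify_hypopnea(self._event(), [{"snore"}, {"ifl"}])
        assert ev.kind is CycleLabel.OH and ev.evidence == {"snore", "ifl"}


class TestEventIndices:
    def test_counts_per_stable_hour(self):
        events = []
        for k, kind in enumerate([CycleLabel.OA, CycleLabel.CA, CycleLabel.OH]):
            e = SDBEvent(onset_s=100.0 * k, duration_s=15.0)
            e.kind = kind
            events.append(e)
        idx = event_indices(events, stable_hours=2.0)
        assert idx["ahi"] == pytest.approx(1.5)
        assert idx["ai"] == pytest.approx(1.0)
        assert idx["hi"] == pytest.approx(0.5)
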