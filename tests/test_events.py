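"""Detector fixtures with known injected events, biomarkers, classification."""

import numpy as np
import pytest

from cardiolyso.events import (DetectorConfig, amplitude, classify_pair,
                               classify_population, detect_dads,
                               detect_spontaneous_release, flag_ambiguous,
                               fold_change, normalized_change)


def paced_trace(n_beats=4, cl=1000.0, dt=1.0, amp=2e-4, dia=1e-4, tau=40.0):
    """Synthetic train of clean paced Ca transients (exponential decay)."""
    t = np.arange(0.0, n_beats * cl, dt)
    ci = np.full_like(t, dia)
    stim = np.arange(0.0, n_beats * cl, cl)
    for s in stim:
        m = t >= s + 5.0
        ci[m] += amp * np.exp(-(t[m] - s - 5.0) / tau)
    return t, ci, stim


def inject_bump(t, ci, at, width=30.0, height=1e-4):
    return ci + height * np.exp(-0.5 * ((t - at) / width) ** 2)


class TestSpontaneousRelease:
    def test_clean_trace_has_no_events(self):
        t, ci, stim = paced_trace()
        assert detect_spontaneous_release(t, ci, stim) == []

    def test_injected_diastolic_bump_detected_once(self):
        t, ci, stim = paced_trace()
        ci = inject_bump(t, ci, at=2600.0, height=1e-4)  # 0.5x paced amplitude
        events = detect_spontaneous_release(t, ci, stim)
        assert len(events) == 1
        assert events[0].time == pytest.approx(2600.0, abs=5.0)
        assert events[0].beat_index == 2
        assert events[0].diastolic

    @pytest.mark.parametrize("theta", [0.05, 0.10, 0.15])
    def test_detection_robust_to_threshold_choice(self, theta):
        t, ci, stim = paced_trace()
        ci = inject_bump(t, ci, at=1700.0, height=1e-4)
        cfg = DetectorConfig(theta=theta)
        assert len(detect_spontaneous_release(t, ci, stim, cfg)) == 1

    def test_translation_and_scale_invariance(self):
        t, ci, stim = paced_trace()
        ci = inject_bump(t, ci, at=2600.0, height=1e-4)
        base = detect_spontaneous_release(t, ci, stim)
        shifted = detect_spontaneous_release(t + 5000.0, ci, stim + 5000.0)
        assert len(shifted) == len(base) == 1
        assert shifted[0].time == pytest.approx(base[0].time + 5000.0, abs=1e-6)
        scaled = detect_spontaneous_release(t, ci * 3.7, stim)
        assert len(scaled) == 1

    def test_short_trace_raises(self):
        t, ci, stim = paced_trace(n_beats=1)
        with pytest.raises(ValueError):
            detect_spontaneous_release(t[:100], ci[:100], stim)


class TestAmbiguity:
    def test_clean_trace_not_ambiguous(self):
        t, ci, stim = paced_trace()
        assert flag_ambiguous(t, ci, stim) is False

    def test_small_relaxation_ripple_is_ambiguous(self):
        t, ci, stim = paced_trace()
        for s in (300.0, 1300.0, 2300.0):
            ci = inject_bump(t, ci, at=s, width=15.0, height=8e-6)  # 4% ripple
        assert flag_ambiguous(t, ci, stim) is True

    def test_full_event_is_not_ambiguous(self):
        t, ci, stim = paced_trace()
        ci = inject_bump(t, ci, at=2600.0, height=1.5e-4)
        assert flag_ambiguous(t, ci, stim) is False


class TestDads:
    def resting_v(self, n_beats=3, cl=1000.0):
        t = np.arange(0.0, n_beats * cl, 1.0)
        v = np.full_like(t, -82.0)
        stim = np.arange(0.0, n_beats * cl, cl)
        for s in stim:
            m = (t >= s) & (t < s + 60.0)
            v[m] = -82.0 + 110.0 * np.exp(-(t[m] - s) / 15.0)
        return t, v, stim

    def test_resting_trace_no_dads(self):
        t, v, stim = self.resting_v()
        assert detect_dads(t, v, stim) == []

    def test_injected_hump_detected_with_amplitude(self):
        t, v, stim = self.resting_v()
        v = v + 5.0 * np.exp(-0.5 * ((t - 1650.0) / 40.0) ** 2)
        dads = detect_dads(t, v, stim)
        assert len(dads) == 1
        assert dads[0].magnitude == pytest.approx(5.0, rel=0.1)
        assert dads[0].type == "DAD"


class TestStatistics:
    def test_amplitude_definition(self):
        assert amplitude([1.0, 3.5, 0.5]) == 3.0
        with pytest.raises(ValueError):
            amplitude([])

    def test_identical_populations_fold_one(self, rng):
        a = rng.uniform(0.1, 0.5, 40)
        assert fold_change(a, a) == pytest.approx(1.0)

    def test_fold_change_uses_medians(self):
        assert fold_change([1.0, 2.0, 30.0], [1.0, 1.0, 1.0]) == pytest.approx(2.0)

    def test_normalized_change(self):
        out = normalized_change([1.2, 1.4], [1.0, 1.0])
        assert out["mean"] == pytest.approx(0.3)
        assert out["per_model"] == pytest.approx([0.2, 0.4])
        with pytest.raises(ValueError):
            normalized_change([1.0], [0.0])


class TestClassification:
    def test_definitions(self):
        assert classify_pair(0, [1, 2], []).label == "TPC_specific"
        assert classify_pair(1, [1], [1]).label == "other_proarrhythmic"
        assert classify_pair(2, [], []).label == "nonproarrhythmic"
        assert classify_pair(3, [1], [], ambiguous=True).label == "excluded_ambiguous"
        assert classify_pair(4, [], [], failed=True).label == "failed"

    def test_labels_partition_population(self, rng):
        cls = []
        for i in range(60):
            wt = [1] * rng.integers(0, 3)
            ko = [1] * rng.integers(0, 2)
            cls.append(classify_pair(i, wt, ko,
                                     ambiguous=bool(rng.random() < 0.1)))
        summary = classify_population(cls)
        assert summary["n_analyzed"] + summary["n_excluded"] + summary["n_failed"] == 60
        # reclassification from the same event lists is exactly reproducible
        again = [classify_pair(c.model_id, [1] * c.n_events_wt, [1] * c.n_events_ko,
                               ambiguous=(c.label == "excluded_ambiguous"))
                 for c in cls]
        assert [c.label for c in again] == [c.label for c in cls]

    def test_incidences(self):
        cls = [classify_pair(0, [1], []), classify_pair(1, [1], [1]),
               classify_pair(2, [], []), classify_pair(3, [], [])]
        s = classify_population(cls)
        assert s["wt_incidence"] == pytest.approx(0.5)
        assert s["ko_incidence"] == pytest.approx(0.25)
        assert s["n_tpc_specific"] == 1
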