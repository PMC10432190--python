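"""Spontaneous-release and DAD detection, biomarkers, and model classification.

Detection conventions (all thresholds are configurable and expressed
relative to the paced transient, so the detectors are invariant to uniform
rescaling of a trace and to translation in time):

* a spontaneous calcium-release event is a diastolic upstroke of cytosolic
  Ca2+ beginning after the stimulated transient has decayed (more than the
  refractory window ``t_refract``, by default the time to 90% decay of the
  reference paced transient), with prominence at least ``theta`` (default
  10%) of the reference paced-transient amplitude;
* sub-threshold ripple during the relaxation phase (prominence between
  ``theta_low``, default 2%, and ``theta``) that cannot be counted as a
  clear event marks a trace as ambiguous, and ambiguous models are excluded
  from proarrhythmia statistics;
* a delayed afterdepolarization (DAD) is a diastolic depolarization with
  prominence of at least ``theta_v`` (default 1 mV) occurring after full
  repolarization and outside stimulus windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "EventRecord", "BiomarkerSet", "ModelClassification", "DetectorConfig",
    "detect_spontaneous_release", "flag_ambiguous", "detect_dads",
    "amplitude", "fold_change", "normalized_change", "biomarkers",
    "classify_pair", "classify_population", "reverted_fraction",
]


@dataclass(frozen=True)
class DetectorConfig:
    theta: float = 0.10        # event prominence, fraction of paced amplitude
    theta_low: float = 0.02    # ambiguity (ripple) floor
    theta_v: float = 1.0       # DAD prominence (mV)
    repol_level: float = -70.0 # membrane considered repolarized below this (mV)


@dataclass(frozen=True)
class EventRecord:
    time: float                # ms
    type: str                  # "spontaneous_Ca_release" | "DAD"
    magnitude: float           # prominence (mM or mV)
    beat_index: int
    diastolic: bool = True


@dataclass
class BiomarkerSet:
    """Last-beat biomarkers of one simulation."""

    amp_ci: float
    amp_cls: float
    amp_serca: float
    amp_ryr: float
    diastolic_ci: float
    systolic_ci: float
    t50_ms: float
    ryr_po_peak: float

    def __post_init__(self):
        if self.systolic_ci < self.diastolic_ci:
            raise ValueError("systolic Ca below diastolic Ca")


@dataclass
class ModelClassification:
    model_id: int
    label: str                 # TPC_specific | other_proarrhythmic |
                               # nonproarrhythmic | excluded_ambiguous | failed
    n_events_wt: int = 0
    n_events_ko: int = 0
    evidence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trace utilities
# ---------------------------------------------------------------------------

def _beat_windows(t: np.ndarray, stim_times: np.ndarray) -> list[tuple[int, float, float]]:
    """(beat index, window start, window end) for stimuli inside the trace."""
    stim = np.asarray(stim_times, dtype=float)
    stim = stim[(stim >= t[0] - 1e-9) & (stim <= t[-1])]
    if stim.size == 0:
        raise ValueError("no stimulus inside the recorded trace")
    out = []
    for b, s in enumerate(stim):
        end = stim[b + 1] if b + 1 < stim.size else t[-1]
        out.append((b, s, end))
    return out


def _paced_reference(t: np.ndarray, y: np.ndarray,
                     stim_times: np.ndarray) -> tuple[float, float, float]:
    """Amplitude, time of peak, and time to 90% decay of the last paced beat."""
    beats = _beat_windows(t, stim_times)
    b, s, e = beats[-1]
    m = (t >= s) & (t <= e)
    seg_t, seg = t[m], y[m]
    if seg.size < 3:
        b, s, e = beats[-2]
        m = (t >= s) & (t <= e)
        seg_t, seg = t[m], y[m]
    amp = seg.max() - seg.min()
    pk = int(np.argmax(seg))
    level90 = seg[pk] - 0.9 * amp
    below = np.where(seg[pk:] <= level90)[0]
    t_decay90 = (seg_t[pk + below[0]] - s) if below.size else (e - s)
    return amp, seg_t[pk] - s, t_decay90


def amplitude(trace: np.ndarray) -> float:
    """Amplitude biomarker: absolute difference of maximum and minimum."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    return float(trace.max() - trace.min())


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_spontaneous_release(t, ci, stim_times,
                               config: DetectorConfig = DetectorConfig()
                               ) -> list[EventRecord]:
    """Diastolic Ca2+ upstrokes beyond the refractory window of each beat."""
    t = np.asarray(t, dtype=float)
    ci = np.asarray(ci, dtype=float)
    beats = _beat_windows(t, stim_times)
    if len(beats) >= 2:
        beat_len = beats[1][1] - beats[0][1]
    else:
        beat_len = 250.0  # minimum plausible cycle for a lone stimulus
    if t[-1] - beats[0][1] < 0.9 * beat_len:
        raise ValueError("trace shorter than one beat")
    a_ref, _, t_refract = _paced_reference(t, ci, stim_times)
    if a_ref <= 0:
        return []
    events: list[EventRecord] = []
    for b, s, e in beats:
        m = (t >= s + t_refract) & (t < e)
        if m.sum() < 3:
            continue
        seg_t, seg = t[m], ci[m]
        peaks, props = find_peaks(seg, prominence=config.theta * a_ref)
        for p, prom in zip(peaks, props["prominences"]):
            events.append(EventRecord(time=float(seg_t[p]),
                                      type="spontaneous_Ca_release",
                                      magnitude=float(prom),
                                      beat_index=b, diastolic=True))
    return events


def flag_ambiguous(t, ci, stim_times,
                   config: DetectorConfig = DetectorConfig()) -> bool:
    """Relaxation-phase ripple that cannot be counted as a clear event.

    True when sub-threshold oscillations (prominence between ``theta_low``
    and ``theta`` of the paced amplitude) occur between 50% decay and the
    next stimulus, in a trace with no countable spontaneous-release events.
    A trace with a full-blown diastolic release is an event, not ambiguous.
    """
    t = np.asarray(t, dtype=float)
    ci = np.asarray(ci, dtype=float)
    if detect_spontaneous_release(t, ci, stim_times, config):
        return False
    a_ref, t_peak, _ = _paced_reference(t, ci, stim_times)
    if a_ref <= 0:
        return False
    for b, s, e in _beat_windows(t, stim_times):
        m = (t >= s) & (t < e)
        seg_t, seg = t[m], ci[m]
        if seg.size < 5:
            continue
        pk = int(np.argmax(seg))
        amp = seg.max() - seg.min()
        below = np.where(seg[pk:] <= seg[pk] - 0.5 * amp)[0]
        if below.size == 0:
            continue
        start = pk + below[0]
        relax = seg[start:]
        peaks, props = find_peaks(relax, prominence=config.theta_low * a_ref)
        if any(prom < config.theta * a_ref for prom in props["prominences"]):
            return True
    return False


def detect_dads(t, v, stim_times,
                config: DetectorConfig = DetectorConfig()) -> list[EventRecord]:
    """Diastolic depolarizations after full repolarization."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    events: list[EventRecord] = []
    for b, s, e in _beat_windows(t, stim_times):
        m = (t >= s) & (t < e)
        seg_t, seg = t[m], v[m]
        if seg.size < 5:
            continue
        repol = np.where(seg <= config.repol_level)[0]
        if repol.size == 0:
            continue
        dia = seg[repol[0]:]
        dia_t = seg_t[repol[0]:]
        peaks, props = find_peaks(dia, prominence=config.theta_v)
        for p, prom in zip(peaks, props["prominences"]):
            if dia[p] <= config.repol_level + 40.0:  # not a triggered AP
                events.append(EventRecord(time=float(dia_t[p]), type="DAD",
                                          magnitude=float(prom),
                                          beat_index=b, diastolic=True))
    return events


# ---------------------------------------------------------------------------
# biomarkers and population statistics
# ---------------------------------------------------------------------------

def biomarkers(result) -> BiomarkerSet:
    """Last-beat biomarker set of a simulation result."""
    t = result.t
    last = result.record_stim_times[-1]
    m = t >= last
    ci = result.trace("C_i")[m]
    amp_ci = amplitude(ci)
    pk = int(np.argmax(ci))
    below = np.where(ci[pk:] <= ci[pk] - 0.5 * amp_ci)[0]
    t50 = float(t[m][pk + below[0]] - t[m][pk]) if below.size else np.nan
    return BiomarkerSet(
        amp_ci=amp_ci,
        amp_cls=amplitude(result.trace("C_ls")[m]),
        amp_serca=amplitude(result.fluxes["J_SERCA"][m]),
        amp_ryr=amplitude(result.fluxes["J_RyR"][m]),
        diastolic_ci=float(ci.min()),
        systolic_ci=float(ci.max()),
        t50_ms=t50,
        ryr_po_peak=float(result.fluxes["ryr_po"][m].max()),
    )


def fold_change(pop_a, pop_b) -> float:
    """Ratio of the medians of two amplitude populations."""
    a, b = np.asarray(pop_a, float), np.asarray(pop_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty population")
    mb = np.median(b)
    if mb == 0:
        raise ValueError("zero reference median")
    return float(np.median(a) / mb)


def normalized_change(amp_protocol, amp_ctrl) -> dict:
    """Per-model relative change with population mean and standard error."""
    p = np.asarray(amp_protocol, float)
    c = np.asarray(amp_ctrl, float)
    if p.shape != c.shape or p.size == 0:
        raise ValueError("paired nonempty amplitude arrays required")
    if np.any(c == 0):
        raise ValueError("zero CTRL amplitude: normalized change undefined")
    change = (p - c) / c
    return {
        "per_model": change,
        "mean": float(change.mean()),
        "se": float(change.std(ddof=1) / np.sqrt(change.size)) if change.size > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pair(model_id: int, wt_events: list, ko_events: list,
                  ambiguous: bool = False, failed: bool = False) -> ModelClassification:
    """Label one model from its paired WT / TPC2-KO event lists."""
    if failed:
        label = "failed"
    elif ambiguous:
        label = "excluded_ambiguous"
    elif wt_events and not ko_events:
        label = "TPC_specific"
    elif wt_events and ko_events:
        label = "other_proarrhythmic"
    else:
        # events only in KO are counted as lysosome-independent arrhythmia
        label = "other_proarrhythmic" if ko_events else "nonproarrhythmic"
    return ModelClassification(model_id=model_id, label=label,
                               n_events_wt=len(wt_events),
                               n_events_ko=len(ko_events))


def classify_population(classifications: list[ModelClassification]) -> dict:
    """Incidence summary over a classified population."""
    analyzed = [c for c in classifications
                if c.label not in ("excluded_ambiguous", "failed")]
    n = len(analyzed)
    wt_events = sum(1 for c in analyzed if c.n_events_wt > 0)
    ko_events = sum(1 for c in analyzed if c.n_events_ko > 0)
    tpc = sum(1 for c in analyzed if c.label == "TPC_specific")
    return {
        "n_analyzed": n,
        "n_excluded": sum(1 for c in classifications if c.label == "excluded_ambiguous"),
        "n_failed": sum(1 for c in classifications if c.label == "failed"),
        "wt_incidence": wt_events / n if n else np.nan,
        "ko_incidence": ko_events / n if n else np.nan,
        "n_tpc_specific": tpc,
        "tpc_specific_fraction": tpc / wt_events if wt_events else np.nan,
    }


def reverted_fraction(result, n_beats: int = 1) -> float:
    """Fraction of the lysosomal Ca2+ throughput routed back to the junction.

    Computed over the last ``n_beats`` stimulated beats as the integral of
    the positive part of J_ls,up (times lysosomal volume) divided by the
    total outgoing lysosomal flux (CLC + TPC2 + outward diffusion).  Under
    release block this quantifies how much of the lysosomal load is reverted
    into the junctional space through the loading channels.
    """
    t = result.t
    stim = result.record_stim_times
    start = stim[-n_beats]
    m = t >= start
    ts = t[m]
    ls = result.params.lysosome
    up = result.fluxes["J_ls_up"][m]
    rel = result.fluxes["J_ls_rel"][m]
    cls = result.trace("C_ls")[m]
    cj = result.trace("C_j")[m]
    ci = result.trace("C_i")[m]
    dif_j_out = np.clip(ls.j_ls_j * (cls - cj), 0.0, None) / ls.v_ls
    dif_i_out = np.clip(ls.j_ls_i * (cls - ci), 0.0, None) / ls.v_ls
    out_j = np.trapezoid(np.clip(up, 0.0, None), ts) * ls.v_ls
    out_total = (out_j
                 + np.trapezoid(np.clip(rel, 0.0, None), ts) * ls.v_ls
                 + np.trapezoid(dif_j_out + dif_i_out, ts) * ls.v_ls)
    if out_total <= 0:
        return 0.0
    return float(out_j / out_total)
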