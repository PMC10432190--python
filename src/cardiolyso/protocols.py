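"""Declarative pacing/intervention protocols for the in-silico experiments.

Every experiment in the study is a combination of a pacing schedule, an
extracellular Ca2+ level, NAADP and isoprenaline concentrations, and
intervention flags (TPC2 knockout / lysosomal flux blocks / NCX
enhancement).  Protocols are plain data and construct deterministically, so
they serialize losslessly to configuration files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["PacingSegment", "ProtocolSpec", "PROTOCOL_NAMES", "make_protocol",
           "stimulus_onsets", "stimulus_current"]


@dataclass(frozen=True)
class PacingSegment:
    rate_hz: float
    n_beats: int

    @property
    def cycle_length_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def duration_ms(self) -> float:
        return self.n_beats * self.cycle_length_ms


@dataclass
class ProtocolSpec:
    name: str
    segments: list[PacingSegment]
    ca_o: float = 1.0            # extracellular Ca (mM)
    naadp: float = 1.0           # nM
    iso: float = 0.0             # nM (0 or 100)
    release_block: bool = False  # TPC2-KO / J_ls,rel = 0
    uptake_block: bool = False   # J_ls,up = 0
    ncx_multiplier: float = 1.0
    analysis_beats: int = 3      # trailing beats analysed for events/biomarkers

    def __post_init__(self):
        if not self.segments:
            raise ValueError("protocol needs at least one pacing segment")
        for seg in self.segments:
            if seg.rate_hz <= 0 or seg.n_beats < 1:
                raise ValueError("pacing segments need rate > 0 and n_beats >= 1")
        if self.ca_o <= 0:
            raise ValueError("extracellular Ca must be > 0")

    @property
    def duration_ms(self) -> float:
        return sum(seg.duration_ms for seg in self.segments)

    @property
    def tpc2_ko(self) -> bool:
        # genetic deletion and release block are the same intervention
        return self.release_block

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segments"] = [{"rate_hz": s.rate_hz, "n_beats": s.n_beats}
                         for s in self.segments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        d = dict(d)
        d["segments"] = [PacingSegment(**s) for s in d["segments"]]
        return cls(**d)


PROTOCOL_NAMES = ("CTRL", "NAADP_AM", "ISO", "HYPERCALCEMIA_ISO",
                  "FASTPACE_ISO", "FASTPACE25_ISO")


def make_protocol(name: str, ko: bool = False, uptake_block: bool = False,
                  release_block: bool = False, ncx3: bool = False,
                  n_beats: int | None = None) -> ProtocolSpec:
    """Build one of the named study protocols.

    CTRL: 150 beats at 1 Hz, 1.0 mM Ca_o, endogenous NAADP (1 nM), no ISO.
    NAADP_AM: CTRL with NAADP raised to 15 nM.
    ISO: CTRL with 100 nM isoprenaline (which also raises NAADP to 15 nM).
    HYPERCALCEMIA_ISO: ISO with extracellular Ca raised from 1.0 to 1.8 mM.
    FASTPACE_ISO: ISO paced at 10 Hz for 150 beats, then 1 Hz for 5 beats.
    FASTPACE25_ISO: same with the fast segment at 25 Hz.

    ``ko`` is an alias for ``release_block`` (TPC2 knockout); ``n_beats``
    overrides the length of the *first* pacing segment (reduced presets).
    """
    key = name.upper().replace("-", "_")
    base_beats = 150 if n_beats is None else int(n_beats)
    one_hz = [PacingSegment(1.0, base_beats)]
    if key == "CTRL":
        spec = ProtocolSpec("CTRL", one_hz, ca_o=1.0, naadp=1.0, iso=0.0)
    elif key == "NAADP_AM":
        spec = ProtocolSpec("NAADP_AM", one_hz, ca_o=1.0, naadp=15.0, iso=0.0)
    elif key == "ISO":
        spec = ProtocolSpec("ISO", one_hz, ca_o=1.0, naadp=15.0, iso=100.0)
    elif key == "HYPERCALCEMIA_ISO":
        spec = ProtocolSpec("HYPERCALCEMIA_ISO", one_hz, ca_o=1.8, naadp=15.0,
                            iso=100.0)
    elif key == "FASTPACE_ISO":
        spec = ProtocolSpec(
            "FASTPACE_ISO",
            [PacingSegment(10.0, base_beats), PacingSegment(1.0, 5)],
            ca_o=1.0, naadp=15.0, iso=100.0, analysis_beats=5)
    elif key == "FASTPACE25_ISO":
        spec = ProtocolSpec(
            "FASTPACE25_ISO",
            [PacingSegment(25.0, base_beats), PacingSegment(1.0, 5)],
            ca_o=1.0, naadp=15.0, iso=100.0, analysis_beats=5)
    else:
        raise ValueError(
            f"unknown protocol {name!r}; valid names: {', '.join(PROTOCOL_NAMES)}")
    spec.release_block = bool(release_block or ko)
    spec.uptake_block = bool(uptake_block)
    spec.ncx_multiplier = 3.0 if ncx3 else 1.0
    return spec


def stimulus_onsets(spec: ProtocolSpec) -> np.ndarray:
    """Stimulus onset times (ms) over the whole protocol, starting at t=0."""
    onsets = []
    t0 = 0.0
    for seg in spec.segments:
        cl = seg.cycle_length_ms
        onsets.extend(t0 + k * cl for k in range(seg.n_beats))
        t0 += seg.duration_ms
    return np.asarray(onsets)


def stimulus_current(t: float, spec: ProtocolSpec, amplitude: float,
                     duration: float) -> float:
    """Rectangular stimulus current (A/F) at time t."""
    if not 0.0 <= t <= spec.duration_ms:
        return 0.0
    t0 = 0.0
    for seg in spec.segments:
        if t < t0 + seg.duration_ms or seg is spec.segments[-1]:
            phase = (t - t0) % seg.cycle_length_ms
            return amplitude if phase < duration else 0.0
        t0 += seg.duration_ms
    return 0.0
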