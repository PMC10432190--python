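"""Population of models: Latin-hypercube variability, calibration, paired runs.

Cell-to-cell variability is represented by per-model multiplicative scaling
factors on ten maximal conductances/fluxes (L-type current, RyR release,
lysosomal uptake/release and their leaks, NCX, SERCA, I_to, I_Kr), sampled
by uniform Latin hypercube over [0.5, 2].  A model enters the accepted
(wild-type) population only if it shows no spontaneous cytosolic calcium
release in any of the baseline protocols (CTRL, NAADP-AM, ISO); solver
failures are logged and excluded.  Every analysis that contrasts genotypes
simulates the same scaling set twice, once with intact lysosomal release
(WT) and once with release set to zero (TPC2-KO).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import qmc

from .events import DetectorConfig, biomarkers, detect_spontaneous_release, flag_ambiguous
from .integrate import simulate
from .model import CellParameters
from .protocols import make_protocol

log = logging.getLogger(__name__)

__all__ = ["FACTOR_NAMES", "ScalingFactorSet", "PopulationSpec",
           "sample_population", "apply_scalings", "run_model",
           "calibrate_population", "run_paired", "CalibrationResult"]

FACTOR_NAMES = ("i_cal", "j_ryr", "j_clc", "j_tpc", "j_clc_leak",
                "j_tpc_leak", "i_ncx", "j_serca", "i_to", "i_kr")

# parameter touched by each scaling factor: (object, attribute)
_FACTOR_TARGETS = {
    "i_cal": ("cell", "p_ca"),
    "j_ryr": ("cell", "ks_ryr"),
    "j_clc": ("lyso", "j_clc"),
    "j_tpc": ("lyso", "j_tpc"),
    "j_clc_leak": ("lyso", "j_clc_leak"),
    "j_tpc_leak": ("lyso", "j_tpc_leak"),
    "i_ncx": ("cell", "ibar_ncx"),
    "j_serca": ("cell", "vmax_serca"),
    "i_to": ("cell", "g_to"),
    "i_kr": ("cell", "g_kr"),
}


@dataclass(frozen=True)
class ScalingFactorSet:
    """One population member: ten dimensionless multipliers."""

    factors: tuple

    def __post_init__(self):
        if len(self.factors) != len(FACTOR_NAMES):
            raise ValueError(f"need {len(FACTOR_NAMES)} factors")

    def as_dict(self) -> dict:
        return dict(zip(FACTOR_NAMES, self.factors))

    def __getitem__(self, name: str) -> float:
        return self.factors[FACTOR_NAMES.index(name)]


@dataclass
class PopulationSpec:
    n_models: int = 1000
    lower: float = 0.5
    upper: float = 2.0
    seed: int = 0
    ncx_extra_multiplier: float = 1.0   # 3.0 for the enhanced-NCX DAD study

    def validate(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not 0 < self.lower < self.upper:
            raise ValueError("factor bounds must satisfy 0 < lower < upper")


def sample_population(spec: PopulationSpec) -> list[ScalingFactorSet]:
    """Uniform Latin hypercube sample of scaling factors, seeded.

    Each factor column is stratified into ``n_models`` equal-probability
    bins with exactly one sample per bin.
    """
    spec.validate()
    sampler = qmc.LatinHypercube(d=len(FACTOR_NAMES), seed=spec.seed)
    unit = sampler.random(n=spec.n_models)
    scaled = qmc.scale(unit, [spec.lower] * len(FACTOR_NAMES),
                       [spec.upper] * len(FACTOR_NAMES))
    return [ScalingFactorSet(tuple(row)) for row in scaled]


def apply_scalings(base: CellParameters, scalings: ScalingFactorSet,
                   ncx_extra: float = 1.0) -> CellParameters:
    """Baseline parameters scaled by one population member's factors."""
    out = base.copy()
    for name, f in scalings.as_dict().items():
        kind, attr = _FACTOR_TARGETS[name]
        obj = out if kind == "cell" else out.lysosome
        setattr(obj, attr, getattr(obj, attr) * f)
    out.ibar_ncx *= ncx_extra
    return out


# ---------------------------------------------------------------------------
# batch execution
# ---------------------------------------------------------------------------

@dataclass
class ModelRun:
    model_id: int
    protocol: str
    arm: str                     # "WT" | "KO"
    status: str                  # "ok" | "failed"
    n_events: int = 0
    ambiguous: bool = False
    biomarkers: object = None
    events: list = field(default_factory=list)
    reference: object = None     # optional SimulationResult


def run_model(params: CellParameters, protocol_name: str, *, ko: bool = False,
              uptake_block: bool = False, n_beats: int | None = None,
              detector: DetectorConfig = DetectorConfig(),
              keep_result: bool = False, model_id: int = -1) -> ModelRun:
    """Simulate one model under one protocol arm and analyze the trace."""
    proto = make_protocol(protocol_name, ko=ko, uptake_block=uptake_block,
                          n_beats=n_beats)
    res = simulate(params, proto)
    arm = "KO" if ko else "WT"
    if not res.ok:
        log.warning("model %s %s/%s: solver failure, excluded",
                    model_id, protocol_name, arm)
        return ModelRun(model_id, protocol_name, arm, "failed")
    t0 = res.stim_times[-proto.analysis_beats]
    m = res.t >= t0
    events = detect_spontaneous_release(res.t[m], res.trace("C_i")[m],
                                        res.stim_times, detector)
    ambiguous = flag_ambiguous(res.t[m], res.trace("C_i")[m],
                               res.stim_times, detector)
    return ModelRun(model_id, protocol_name, arm, "ok",
                    n_events=len(events), ambiguous=ambiguous,
                    biomarkers=biomarkers(res), events=events,
                    reference=res if keep_result else None)


@dataclass
class CalibrationResult:
    accepted: list                    # model ids
    rejected: dict                    # model id -> first failing protocol
    failed: list                      # model ids with solver failures
    runs: dict                        # (model_id, protocol) -> ModelRun (WT)

    @property
    def acceptance_fraction(self) -> float:
        n = len(self.accepted) + len(self.rejected)
        return len(self.accepted) / n if n else np.nan


BASELINE_PROTOCOLS = ("CTRL", "NAADP_AM", "ISO")

# Physiological envelope for the CTRL Ca2+ transient amplitude (mM).  Models
# whose baseline transient falls outside this band do not behave within the
# experimental calcium-transient envelope (near-abolished or grossly
# oversized transients) and are not carried into the accepted population.
AMPLITUDE_ENVELOPE = (1.1e-4, 6.7e-4)


def calibrate_population(base: CellParameters, population: list[ScalingFactorSet],
                         n_beats: int | None = None, ncx_extra: float = 1.0,
                         detector: DetectorConfig = DetectorConfig(),
                         protocols=BASELINE_PROTOCOLS,
                         amplitude_envelope=AMPLITUDE_ENVELOPE) -> CalibrationResult:
    """Accept models that stay within the physiological calibration envelope.

    A model enters the accepted population when (a) it exhibits no
    spontaneous calcium release in any baseline protocol and (b) its CTRL
    transient amplitude lies within the experimental envelope.  Acceptance
    is evaluated on the wild-type arm; the rejection log records the first
    failing protocol (or ``envelope``).  Models whose integration fails are
    logged separately and excluded.
    """
    accepted, rejected, failed, runs = [], {}, [], {}
    for i, scal in enumerate(population):
        params = apply_scalings(base, scal, ncx_extra=ncx_extra)
        verdict = None
        for proto in protocols:
            run = run_model(params, proto, n_beats=n_beats,
                            detector=detector, model_id=i)
            runs[(i, proto)] = run
            if run.status == "failed":
                verdict = "failed"
                break
            if run.n_events > 0:
                verdict = proto
                break
            if (proto == "CTRL" and amplitude_envelope is not None
                    and not (amplitude_envelope[0] <= run.biomarkers.amp_ci
                             <= amplitude_envelope[1])):
                verdict = "envelope"
                break
        if verdict is None:
            accepted.append(i)
        elif verdict == "failed":
            failed.append(i)
        else:
            rejected[i] = verdict
        if (i + 1) % 25 == 0:
            log.info("calibration: %d/%d models, %d accepted",
                     i + 1, len(population), len(accepted))
    return CalibrationResult(accepted, rejected, failed, runs)


def run_paired(base: CellParameters, population: list[ScalingFactorSet],
               model_ids, protocol_name: str, *, n_beats: int | None = None,
               ncx_extra: float = 1.0, uptake_block: bool = False,
               detector: DetectorConfig = DetectorConfig(),
               keep_results: bool = False) -> dict:
    """Run selected models in paired WT / TPC2-KO configuration.

    Both arms share the identical scaling-factor set and differ only in the
    release-blocked flag.  Returns {model_id: {"WT": ModelRun, "KO": ModelRun}}.
    """
    out = {}
    for i in model_ids:
        params = apply_scalings(base, population[i], ncx_extra=ncx_extra)
        out[i] = {
            "WT": run_model(params, protocol_name, ko=False,
                            uptake_block=uptake_block, n_beats=n_beats,
                            detector=detector, keep_result=keep_results,
                            model_id=i),
            "KO": run_model(params, protocol_name, ko=True,
                            uptake_block=uptake_block, n_beats=n_beats,
                            detector=detector, keep_result=keep_results,
                            model_id=i),
        }
    return out
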