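"""End-to-end in-silico studies: population statistics behind the headline results.

Two composite experiments cover the quantitative outputs of the study:

* :func:`baseline_response_study` — generate and calibrate a population,
  simulate CTRL / NAADP-AM / ISO in paired WT and TPC2-KO arms, and compute
  normalized amplitude changes and fold changes of the cytosolic Ca2+
  transient;
* :func:`overload_incidence_study` — expose the accepted population to a
  calcium-overload protocol (hypercalcemia + ISO, or fast-to-slow pacing),
  classify paired WT/KO outcomes, and report spontaneous-release incidences
  plus the effect of lysosomal-flux blocks on the TPC-specific subgroup.

Problem sizes default to the package's reduced preset (~10^2 models, 100
beats to steady state), which reproduces the population statistics at
desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import (classify_pair, classify_population, fold_change,
                     normalized_change, reverted_fraction)
from .model import CellParameters
from .population import (PopulationSpec, apply_scalings, calibrate_population,
                         run_model, run_paired, sample_population)

log = logging.getLogger(__name__)

__all__ = ["BaselineStudy", "baseline_response_study", "overload_incidence_study"]


@dataclass
class BaselineStudy:
    """Calibrated population with paired baseline-protocol amplitudes."""

    seed: int
    population: list
    calibration: object
    amplitudes: dict          # (protocol, arm) -> np.ndarray over accepted models
    accepted: list
    base: CellParameters = field(repr=False, default=None)
    n_beats: int = 100

    def normalized(self, protocol: str, arm: str) -> dict:
        return normalized_change(self.amplitudes[(protocol, arm)],
                                 self.amplitudes[("CTRL", arm)])

    def fold(self, protocol: str, arm: str = "WT") -> float:
        return fold_change(self.amplitudes[(protocol, arm)],
                           self.amplitudes[("CTRL", arm)])


def baseline_response_study(seed: int, n_models: int = 120,
                            n_beats: int = 100,
                            base: CellParameters | None = None) -> BaselineStudy:
    """Calibrate a population and quantify NAADP-AM and ISO responses.

    The wild-type arm of every sampled model is simulated under the three
    baseline protocols for calibration; accepted models are additionally
    simulated in the TPC2-KO arm, and per-model steady-state cytosolic
    amplitude matrices are assembled for both arms.
    """
    base = base or CellParameters()
    pop = sample_population(PopulationSpec(n_models=n_models, seed=seed))
    cal = calibrate_population(base, pop, n_beats=n_beats)
    log.info("calibration: %d/%d accepted (%.0f%%)", len(cal.accepted),
             n_models, 100 * cal.acceptance_fraction)
    amplitudes = {}
    for proto in ("CTRL", "NAADP_AM", "ISO"):
        amplitudes[(proto, "WT")] = np.array(
            [cal.runs[(i, proto)].biomarkers.amp_ci for i in cal.accepted])
        ko = []
        for i in cal.accepted:
            params = apply_scalings(base, pop[i])
            run = run_model(params, proto, ko=True, n_beats=n_beats, model_id=i)
            ko.append(run.biomarkers.amp_ci if run.status == "ok" else np.nan)
        amplitudes[(proto, "KO")] = np.array(ko)
    # exclude models whose KO arm failed, and apply the physiological
    # amplitude envelope to the knockout genotype as well: the calibration
    # data cover both WT and TPC2-KO transients, and a member whose KO arm
    # collapses outside the envelope is not a valid paired preparation
    from .population import AMPLITUDE_ENVELOPE
    lo, hi = AMPLITUDE_ENVELOPE
    ko_ctrl = amplitudes[("CTRL", "KO")]
    keep = ~np.any([np.isnan(amplitudes[(p, "KO")])
                    for p in ("CTRL", "NAADP_AM", "ISO")], axis=0)
    keep &= (ko_ctrl >= lo) & (ko_ctrl <= hi)
    for key in list(amplitudes):
        amplitudes[key] = amplitudes[key][keep]
    accepted = [i for i, k in zip(cal.accepted, keep) if k]
    return BaselineStudy(seed=seed, population=pop, calibration=cal,
                         amplitudes=amplitudes, accepted=accepted,
                         base=base, n_beats=n_beats)


def overload_incidence_study(study: BaselineStudy,
                             protocol: str = "HYPERCALCEMIA_ISO",
                             n_beats: int | None = None,
                             with_uptake_block: bool = True,
                             keep_results: bool = False) -> dict:
    """Paired WT/KO calcium-overload exposure of the accepted population.

    Returns the incidence summary, per-model classifications, and (for the
    TPC-specific subgroup) the event reduction under lysosomal uptake block
    and the median lysosomal reversal fraction under release block.
    """
    n_beats = n_beats if n_beats is not None else study.n_beats
    paired = run_paired(study.base, study.population, study.accepted, protocol,
                        n_beats=n_beats, keep_results=keep_results)
    classifications = []
    for i, arms in paired.items():
        failed = arms["WT"].status != "ok" or arms["KO"].status != "ok"
        classifications.append(classify_pair(
            i, arms["WT"].events, [] if failed else arms["KO"].events,
            ambiguous=(not failed and arms["WT"].ambiguous), failed=failed))
    summary = classify_population(classifications)
    tpc_ids = [c.model_id for c in classifications if c.label == "TPC_specific"]

    out = {"summary": summary, "classifications": classifications,
           "paired": paired if keep_results else None, "tpc_specific": tpc_ids}

    if with_uptake_block and tpc_ids:
        blocked_events = 0
        for i in tpc_ids:
            params = apply_scalings(study.base, study.population[i])
            run = run_model(params, protocol, uptake_block=True,
                            n_beats=n_beats, model_id=i)
            if run.status == "ok" and run.n_events > 0:
                blocked_events += 1
        out["uptake_block_event_fraction"] = blocked_events / len(tpc_ids)

    if tpc_ids:
        fractions = []
        for i in tpc_ids[:10]:  # median over a subgroup sample
            params = apply_scalings(study.base, study.population[i])
            run = run_model(params, protocol, ko=True, n_beats=n_beats,
                            keep_result=True, model_id=i)
            if run.status == "ok":
                fractions.append(reverted_fraction(run.reference))
        if fractions:
            out["reverted_fraction_median"] = float(np.median(fractions))
    return out
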