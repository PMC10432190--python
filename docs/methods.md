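# Methods

## Model overview

`cardiolyso` implements a reduced-order mouse ventricular cardiomyocyte model
whose purpose is to study how a lysosomal calcium pool modulates
calcium-induced calcium release (CICR) and spontaneous-release
arrhythmogenesis. The electrophysiology is a compartmental
Shannon-family formulation: membrane potential V with an L-type Ca²⁺ current
(GHK flux, junctional), Na⁺/Ca²⁺ exchanger (NCX, junctional/subsarcolemmal
split, with allosteric Ca²⁺ activation), transient-outward, steady-state,
rapid delayed-rectifier and inward-rectifier K⁺ currents, and a background
Ca²⁺ leak. Calcium cycles through five pools — junctional cleft (C_j),
subsarcolemmal space (C_sl), bulk cytosol (C_i), SR (C_sr) and lysosome
(C_ls) — linked by volumetric diffusion, a reversible-Hill SERCA pump, a
passive SR leak, and a four-state ryanodine-receptor (RyR) scheme
(rest/open/inactivated/rest-inactivated) with luminal-Ca²⁺-dependent
modulation.

Deliberate reductions relative to a full biophysically detailed mouse model:

* intracellular Na⁺ and K⁺ are clamped (no I_Na, I_NaK; the upstroke is
  driven by the stimulus pulse). Rate-dependent Na⁺ accumulation is
  therefore not represented; calcium accumulation under fast pacing arises
  from the calcium fluxes themselves.
* Ca²⁺ buffering (troponin/calmodulin-class cytosolic sites, sarcolemmal
  sites, calsequestrin) uses the rapid-equilibrium approximation, so
  buffer-bound calcium is an algebraic function of free calcium
  (`StateVector.bound_calcium`). Total calcium — free plus bound, summed with
  compartment volumes — is conserved by the equations to machine precision
  when sarcolemmal fluxes are disabled; this is enforced by a test.
* β-adrenergic stimulation is a static parameter scaling (no dynamic
  PKA/CaMKII signaling), applied at protocol start for 100 nM isoprenaline:
  L-type availability ×1.56, RyR opening rate ×2, SERCA forward-mode
  half-saturation ×0.45 (phospholamban relief), and a slowing of L-type
  voltage inactivation (τ_f ×2 at 100 nM) so that per-beat L-type calcium
  influx roughly doubles under full PKA activation.

## Lysosomal compartment

The lysosome exchanges Ca²⁺ with the junctional cleft through a calcium
loading channel (CLC) and releases Ca²⁺ to the cytosol through TPC2
channels; both carry an ungated leak and share an NAADP-gated open
probability (positive flux = out of the lysosome):

    J_ls,up  = (j_clc·PO + j_clc,leak)·(C_ls − C_j)
    J_ls,rel = (j_tpc·PO + j_tpc,leak)·(C_ls − C_i)
    PO([NAADP]) = PO_max · exp(−(log₁₀[NAADP] − log₁₀ PO_mean)² / (2·PO_sd²))

The conservation equations couple these fluxes with volume ratios
(V_ls/V_j, V_ls/V_i) and with slow diffusion terms J_ls,j, J_ls,i, so that
volume-weighted lysosomal exchange is exactly mass conserving.

PO calibration: the peak open probability is 0.016 and PO at 15 nM NAADP
(the "channels fully open" pharmacological condition, used for both
NAADP-AM and isoprenaline protocols) is 0.0134. Placing the peak at
PO_mean = 30 nM fixes PO_sd ≈ 0.505 (log₁₀ units) in closed form and gives
PO(1 nM) ≈ 2.2·10⁻⁴ at the endogenous NAADP level, consistent with the
near-silent channel at rest. The log base is a pure parameterization
convention (absorbed into PO_sd).

Flux-magnitude calibration: j_clc, j_tpc, the leaks, V_ls and the diffusion
rates were calibrated jointly, against the population targets below, so that
(i) at endogenous NAADP the lysosome is functionally inert (WT ≈ KO under
CTRL), (ii) NAADP-AM raises the wild-type cytosolic transient by ≈20% while
the TPC2-KO transient changes by only a few percent (slightly negative:
gated CLC exchange buffers part of the junctional trigger without the
compensating release pathway), and (iii) the lysosomal shunt adds ≈25% to
the β-adrenergic amplitude response of WT over KO. Final values live in
`LysosomeParams` defaults and can be exported/imported as a commented YAML
parameter file.

## Working regime and the store-overload gate

The calibrated operating point runs CICR at high gain with deep fractional
SR release per beat; the transient amplitude is largely SR-content-limited,
which is what lets β-adrenergic stimulation (larger influx, more avid
SERCA) raise the amplitude ≈2.3-fold. The RyR luminal modulation is
configured as a flat sub-threshold factor with a steep store-overload gate
(midpoint 0.26 mM SR Ca²⁺, Hill 12): below the gate the opening/inactivation
rates are the baseline ones; above it the opening rate rises sharply
(×1/min_SR = ×12.5) and inactivation weakens, producing diastolic
spontaneous release when calcium overload (hypercalcemia, fast pacing, or
adverse scaling-factor combinations) pushes the diastolic SR load over the
gate. This separation — graded triggered release below, a crisp overload
cliff above — was a deliberate design choice: an in-range luminal feedback
(classic formulations) pins the SR load and suppresses the β-adrenergic
amplitude gain in a reduced common-pool model.

The TPC-specific proarrhythmic mechanism emerges at this operating point:
with identical scaling factors, the wild-type arm fires diastolic
spontaneous release under hypercalcemia + ISO while the paired TPC2-KO arm
does not, because diastolic TPC2 release supplies the extra junctional and
cytosolic calcium that tips RyR ignition.

## Population of models

Cell-to-cell variability multiplies ten parameters (I_CaL, J_RyR, j_clc,
j_tpc, j_clc,leak, j_tpc,leak, I_NCX, J_SERCA, I_to, I_Kr) by factors drawn
with uniform Latin hypercube sampling on [0.5, 2], seeded (SciPy
`qmc.LatinHypercube`). A model is accepted into the population when

1. it shows no spontaneous cytosolic calcium-release event in any baseline
   protocol (CTRL, NAADP-AM, ISO; wild-type arm), and
2. its CTRL transient amplitude lies within a physiological envelope
   (0.11–0.67 µM, about 0.4–2.5× the baseline transient; applied to the CTRL transient of both genotype arms).

The second criterion encodes calibration against the experimental
calcium-transient envelope: a common-pool reduced model produces a
sub-population of members (chiefly low L-type density combined with strong
extrusion) whose CICR fails to ignite, leaving near-abolished transients
that no experimental cardiomyocyte preparation would show; carrying them
into the population would let a handful of unphysiological members dominate
the normalized-change statistics. Both criteria together accept roughly
half of the sampled models at the default operating point.

Classification of overload outcomes follows the paired-arm definitions:
TPC-specific (events in WT, none in KO), other proarrhythmic (events in
both), nonproarrhythmic (events in neither); traces with sub-threshold
relaxation-phase ripple (prominence between 2% and 10% of the paced
amplitude) are excluded as ambiguous before computing incidences.

## Detection conventions

Spontaneous release: diastolic C_i upstroke starting after the stimulated
transient has decayed (refractory window = time to 90% decay of the last
paced transient), prominence ≥10% of the paced amplitude (SciPy
`find_peaks`). DADs: diastolic membrane-potential peaks with prominence
≥1 mV after repolarization below −70 mV, excluding stimulus-driven
depolarizations. All thresholds are relative and config-exposed
(`DetectorConfig`); detection of the test fixtures is robust to ±50%
threshold changes.

## Numerics

The right-hand side is formulated to be only mildly stiff (rapid-equilibrium
buffering, bounded gating rates, junctional diffusion time constant
~0.15 ms) and integrated with an embedded Dormand–Prince 5(4) pair compiled
with numba: rtol 10⁻⁶, per-state absolute tolerances (10⁻⁹ mM on
concentrations), dense cubic-Hermite output on a fixed 1 kHz grid,
beat-segmented so the rectangular 2 ms, −40 A/F stimulus never introduces a
discontinuity inside an integration interval. This explicit pair was chosen
over an implicit stiff method for population-scale throughput on one CPU;
agreement with a SciPy BDF reference solve at 100× tighter tolerance is
within 0.5% on the cytosolic transient and is enforced by a test. Step-size
collapse marks a model "failed"; failed models are excluded downstream and
logged, never raised from batch runs. Concentrations are floor-clamped at
10⁻⁹ mM inside the kernel only to protect fractional powers from transient
negative trial states of the explicit pair.

## Problem sizes

Population statistics run at a reduced desk scale chosen by the package:
~120 sampled models (≥50 accepted), 100 beats per protocol to steady state
(beat-to-beat drift of diastolic C_i is <0.1% well before beat 100 from the
packaged initial state; the full preset uses 150 beats). The fast-pacing
protocol paces 150 beats at 10 Hz (or 25 Hz) followed by five 1 Hz beats
that form the analysis window.

## What the synthetic conditions do and do not show

The population emulates cell-to-cell variability in channel/transporter
densities only; it does not emulate stochastic channel gating, spatial
calcium sparks/waves, Na⁺-mediated rate dependence, or dynamic
phosphorylation kinetics. Passing tests therefore demonstrate that the
implemented mechanisms — lysosomal shunting of junctional calcium into the
cytosol, SERCA/SR-load amplification, store-overload spontaneous release,
and their interventions (TPC2-KO, flux blocks, NCX enhancement) — behave
and quantify as described; they do not certify predictions for real
cardiomyocytes beyond the calibrated envelope.

## Known limitations

* The per-model β-adrenergic amplitude response is more heterogeneous
  across the population than in the biophysically detailed parent class of
  models: the common-pool CICR response surface is concave around the
  calibrated operating point, so the population-typical ISO fold change
  (~1.6–1.9) sits below the baseline cell's (~2.2) and population means of
  ISO-response statistics land below the detailed-model values. The
  NAADP-AM statistics do not suffer from this (the lysosomal shunt is a
  small perturbation in every member).
* In the TPC2-KO arm the population-mean NAADP-AM response is close to
  zero rather than slightly negative: the two opposing CLC-only effects
  (junctional spike buffering versus diastolic return) nearly cancel in the
  typical member. A junctional-microdomain treatment finer than a single
  well-mixed cleft would be needed to separate them robustly.
* DAD amplitudes at basal NCX density are small (a few mV); the threefold
  NCX enhancement study magnifies them, as expected from the NCX-mediated
  mechanism.
* The 25 Hz fast-pacing variant captures 1:1 but leaves little diastolic
  interval; event counting there relies on the 1 Hz analysis window only.
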