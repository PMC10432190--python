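"""Reduced-order mouse ventricular myocyte model with a lysosomal Ca2+ compartment.

The cell is described by a membrane-potential equation plus compartmental
calcium handling in five pools: the dyadic junctional cleft (``C_j``), the
subsarcolemmal space (``C_sl``), the bulk cytosol (``C_i``), the sarcoplasmic
reticulum (``C_sr``) and the lysosome (``C_ls``).  Sarcolemmal currents are
the L-type Ca2+ current (GHK formulation, junctional), the Na+/Ca2+ exchanger
(junctional/subsarcolemmal split), the transient outward and rapid delayed
rectifier K+ currents, the inward rectifier and a background Ca2+ leak.
SR cycling uses a reversible-Hill SERCA pump, a passive SR leak and a
four-state ryanodine-receptor scheme with luminal-Ca-dependent sensitivity,
which produces store-overload-induced spontaneous release.  Intracellular
Na+ is held constant, and cytosolic/membrane Ca2+ buffering uses the
rapid-equilibrium approximation, so the buffer-bound pools are algebraic
functions of the free concentrations.

beta-adrenergic stimulation is represented by static scalings of the PKA
targets (L-type availability, RyR opening rate, SERCA forward-mode
affinity); see :func:`apply_iso`.

Units: mV, ms, mM, pL; membrane currents in A/F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from numba import njit

from .lysosome import LysosomeParams

__all__ = [
    "CellParameters",
    "IsoScalings",
    "StateVector",
    "apply_iso",
    "pack_params",
    "rhs",
    "compute_rhs",
    "compute_fluxes",
    "initial_state",
    "STATE_NAMES",
    "NSTATE",
    "FLUX_NAMES",
]

# ---------------------------------------------------------------------------
# state layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "V",       # membrane potential (mV)
    "d",       # L-type activation gate
    "f",       # L-type voltage inactivation gate
    "fcab",    # L-type Ca-dependent inactivation (bound fraction)
    "xto",     # I_to activation
    "yto",     # I_to inactivation
    "xkr",     # I_Kr activation
    "ryr_r",   # RyR resting state occupancy
    "ryr_o",   # RyR open state occupancy
    "ryr_i",   # RyR inactivated state occupancy
    "C_j",     # junctional cleft free Ca (mM)
    "C_sl",    # subsarcolemmal free Ca (mM)
    "C_i",     # cytosolic free Ca (mM)
    "C_sr",    # SR free Ca (mM)
    "C_ls",    # lysosomal free Ca (mM)
)
NSTATE = len(STATE_NAMES)

iV, iD, iF, iFCAB, iXTO, iYTO, iXKR, iRYR_R, iRYR_O, iRYR_I, \
    iCJ, iCSL, iCI, iCSR, iCLS = range(NSTATE)

GATE_INDICES = (iD, iF, iFCAB, iXTO, iYTO, iXKR)
CONC_INDICES = (iCJ, iCSL, iCI, iCSR, iCLS)
RYR_INDICES = (iRYR_R, iRYR_O, iRYR_I)

FLUX_NAMES = ("J_SERCA", "J_RyR", "J_ls_up", "J_ls_rel", "ryr_po", "I_NCX")

FARADAY = 96485.0      # C/mol
RGAS = 8314.0          # J/(kmol K)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class IsoScalings:
    """Static PKA-target multipliers representing beta-adrenergic tone.

    All neutral (identity) in the absence of isoprenaline.  ``serca_kmf``
    multiplies the SERCA forward-mode half-saturation constant; values below
    one correspond to phospholamban-phosphorylation relief of SERCA
    inhibition.
    """

    cal_availability: float = 1.0   # multiplier on L-type permeability
    cal_tau_f: float = 1.0          # multiplier on L-type inactivation time constant
    ryr_open: float = 1.0           # multiplier on RyR opening rate
    serca_kmf: float = 1.0          # multiplier on SERCA forward Km

    def is_identity(self) -> bool:
        return (
            self.cal_availability == 1.0
            and self.cal_tau_f == 1.0
            and self.ryr_open == 1.0
            and self.serca_kmf == 1.0
        )

    def validate(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"ISO scaling {f_.name} must be finite and >= 0, got {v}")


@dataclass
class CellParameters:
    """Baseline electrophysiology and calcium-handling constants.

    Defaults are the calibrated operating point used throughout the package:
    a 1 Hz-stable mouse ventricular phenotype whose Ca2+ transient roughly
    doubles under beta-adrenergic stimulation and whose SR sits close enough
    to the store-overload release threshold that calcium-overload protocols
    can trigger spontaneous RyR release.
    """

    # --- geometry (pL) and physics ---
    cm: float = 135.0            # membrane capacitance (pF)
    v_cell: float = 33.0
    v_i: float = 21.45           # bulk cytosol
    v_sr: float = 1.155
    v_sl: float = 0.66
    v_j: float = 0.0178
    temp: float = 310.0          # K

    # --- ionic milieu (mM); Na+ and K+ are clamped ---
    ca_o: float = 1.0
    na_i: float = 10.0
    na_o: float = 140.0
    k_i: float = 120.0
    k_o: float = 5.4

    # --- stimulus (rectangular current pulse) ---
    stim_amplitude: float = -40.0   # A/F
    stim_duration: float = 2.0      # ms

    # --- sarcolemmal currents ---
    p_ca: float = 3.5e-4         # L-type permeability (cm/s), all junctional
    g_to: float = 0.80           # mS/uF
    g_ss: float = 0.30           # non-inactivating steady-state K current
    g_kr: float = 0.06
    g_k1: float = 0.50
    ibar_ncx: float = 1.6        # A/F
    fj_ncx: float = 0.11         # junctional fraction of NCX
    km_cai: float = 3.59e-3
    km_cao: float = 1.3
    km_nai: float = 12.29
    km_nao: float = 87.5
    k_sat: float = 0.27
    nu: float = 0.35
    kd_act: float = 2.56e-4      # allosteric Ca activation of NCX (mM)
    g_cab: float = 1.0e-4        # background Ca conductance (subsarcolemmal)

    # --- SR calcium cycling ---
    vmax_serca: float = 6.0e-4   # mM/ms (cytosolic volume)
    kmf_serca: float = 2.46e-4   # mM
    kmr_serca: float = 1.7       # mM
    hill_serca: float = 1.787
    ks_ryr: float = 25.0         # RyR release rate (1/ms, SR volume)
    ko_ca: float = 5.2          # RyR opening (1/mM^2/ms)
    kom: float = 0.12
    ki_ca: float = 1.5
    kim: float = 0.005
    ec50_sr: float = 0.26        # luminal sensitivity midpoint (mM)
    hill_sr: float = 12.0         # steepness of the luminal (store-overload) gate
    max_sr: float = 1.0
    min_sr: float = 0.08
    k_leak: float = 5.348e-6     # SR leak (1/ms, cytosolic volume)

    # --- inter-compartment diffusion (pL/ms) ---
    j_j_sl: float = 0.82
    j_sl_i: float = 3.72

    # --- rapid-equilibrium buffers: capacity (mM), Kd (mM) ---
    b_cyt1: float = 0.07         # troponin-C low-affinity sites
    kd_cyt1: float = 6.0e-4
    b_cyt2: float = 0.0471       # lumped calmodulin + SR-membrane sites
    kd_cyt2: float = 2.0e-3
    b_jl: float = 1.2            # junctional sarcolemma, low affinity
    kd_jl: float = 1.3e-2
    b_jh: float = 0.30           # junctional sarcolemma, high affinity
    kd_jh: float = 3.0e-4
    b_sll: float = 0.60
    kd_sll: float = 1.3e-2
    b_slh: float = 0.15
    kd_slh: float = 3.0e-4
    b_csqn: float = 4.0          # calsequestrin
    kd_csqn: float = 0.65

    # beta-adrenergic slowing of L-type voltage inactivation at 100 nM ISO
    # (sets the per-beat Ca influx gain of the PKA response)
    iso_tau_f: float = 2.0

    # --- switches ---
    sarcolemma_enabled: bool = True   # False disables I_CaL/I_NCX/I_Cab (tests)
    lysosome_enabled: bool = True     # False compiles the model without C_ls

    iso: IsoScalings = field(default_factory=IsoScalings)
    lysosome: LysosomeParams = field(default_factory=LysosomeParams)

    def copy(self, **changes) -> "CellParameters":
        out = replace(self)
        out.iso = replace(self.iso)
        out.lysosome = replace(self.lysosome)
        for k, v in changes.items():
            setattr(out, k, v)
        return out

    def validate(self) -> None:
        for name in ("v_cell", "v_i", "v_sr", "v_sl", "v_j", "ca_o", "temp", "cm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name} must be finite and > 0, got {v}")
        if not self.lysosome.v_ls < self.v_i:
            raise ValueError("lysosomal volume must be small relative to the cytosol")
        self.iso.validate()
        self.lysosome.validate()


def apply_iso(params: CellParameters, iso_concentration: float) -> CellParameters:
    """Return parameters with the static beta-adrenergic scalings applied.

    The protocol is binary: 0 nM (identity) or 100 nM isoprenaline, which at
    maximal PKA phosphorylation raises L-type availability by 56%, doubles
    the RyR opening rate and lowers the SERCA forward-mode half-saturation
    constant by 55% (phospholamban relief).
    """
    if iso_concentration == 0:
        return params.copy(iso=IsoScalings())
    if iso_concentration == 100:
        return params.copy(
            iso=IsoScalings(cal_availability=1.56, cal_tau_f=params.iso_tau_f,
                            ryr_open=2.0, serca_kmf=0.45)
        )
    raise ValueError(
        f"unsupported ISO concentration {iso_concentration} nM: protocols use 0 or 100 nM"
    )


# ---------------------------------------------------------------------------
# parameter packing for the compiled kernels
# ---------------------------------------------------------------------------

_PARAM_ORDER = [
    "cm", "v_j", "v_sl", "v_i", "v_sr", "temp",
    "ca_o", "na_i", "na_o", "k_i", "k_o",
    "p_ca", "g_to", "g_ss", "g_kr", "g_k1",
    "ibar_ncx", "fj_ncx", "km_cai", "km_cao", "km_nai", "km_nao",
    "k_sat", "nu", "kd_act", "g_cab",
    "vmax_serca", "kmf_serca", "kmr_serca", "hill_serca",
    "ks_ryr", "ko_ca", "kom", "ki_ca", "kim", "ec50_sr", "hill_sr", "max_sr", "min_sr",
    "k_leak", "j_j_sl", "j_sl_i",
    "b_cyt1", "kd_cyt1", "b_cyt2", "kd_cyt2",
    "b_jl", "kd_jl", "b_jh", "kd_jh",
    "b_sll", "kd_sll", "b_slh", "kd_slh",
    "b_csqn", "kd_csqn",
]
# lysosome block
_LYSO_ORDER = [
    "v_ls", "j_clc", "j_tpc", "j_clc_leak", "j_tpc_leak",
    "po_max", "po_mean", "po_sd", "j_ls_j", "j_ls_i", "naadp",
]
# derived / flags appended after the named blocks
_N_BASE = len(_PARAM_ORDER)
_N_LYSO = len(_LYSO_ORDER)

for _i, _name in enumerate(_PARAM_ORDER):
    globals()["P_" + _name.upper()] = _i
for _i, _name in enumerate(_LYSO_ORDER):
    globals()["P_LS_" + _name.upper()] = _N_BASE + _i

_FLAGS_AT = _N_BASE + _N_LYSO
P_RELEASE_BLOCKED = _FLAGS_AT + 0
P_UPTAKE_BLOCKED = _FLAGS_AT + 1
P_LYSO_ENABLED = _FLAGS_AT + 2
P_SARCO_ENABLED = _FLAGS_AT + 3
P_ISO_CAL = _FLAGS_AT + 4
P_ISO_RYR = _FLAGS_AT + 5
P_ISO_KMF = _FLAGS_AT + 6
P_ISO_TAUF = _FLAGS_AT + 7
P_PO_CACHED = _FLAGS_AT + 8   # open probability, precomputed from [NAADP]
NPARAM = _FLAGS_AT + 9


def pack_params(params: CellParameters) -> np.ndarray:
    """Flatten parameters into the vector consumed by the compiled RHS."""
    params.validate()
    p = np.empty(NPARAM)
    for i, name in enumerate(_PARAM_ORDER):
        p[i] = getattr(params, name)
    ls = params.lysosome
    for i, name in enumerate(_LYSO_ORDER):
        p[_N_BASE + i] = getattr(ls, name)
    p[P_RELEASE_BLOCKED] = 1.0 if ls.release_blocked else 0.0
    p[P_UPTAKE_BLOCKED] = 1.0 if ls.uptake_blocked else 0.0
    p[P_LYSO_ENABLED] = 1.0 if params.lysosome_enabled else 0.0
    p[P_SARCO_ENABLED] = 1.0 if params.sarcolemma_enabled else 0.0
    p[P_ISO_CAL] = params.iso.cal_availability
    p[P_ISO_RYR] = params.iso.ryr_open
    p[P_ISO_KMF] = params.iso.serca_kmf
    p[P_ISO_TAUF] = params.iso.cal_tau_f
    p[P_PO_CACHED] = ls.open_probability(ls.naadp)
    return p


# ---------------------------------------------------------------------------
# compiled right-hand side
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def rhs(t, y, p, i_stim):  # noqa: C901 - a monolithic kernel on purpose
    """Time derivatives of the full state.  ``i_stim`` in A/F (constant)."""
    dy = np.zeros(NSTATE)

    V = y[iV]
    d = y[iD]
    f = y[iF]
    fcab = y[iFCAB]
    xto = y[iXTO]
    yto = y[iYTO]
    xkr = y[iXKR]
    r_ry = y[iRYR_R]
    o_ry = y[iRYR_O]
    i_ry = y[iRYR_I]
    # floor-clamp concentrations: transient negative excursions of an
    # explicit trial step must not poison fractional powers/logs with NaNs
    cj = max(y[iCJ], 1e-9)
    csl = max(y[iCSL], 1e-9)
    ci = max(y[iCI], 1e-9)
    csr = max(y[iCSR], 1e-9)
    cls = max(y[iCLS], 1e-9)

    fort = FARADAY / (RGAS * p[P_TEMP])     # 1/mV
    ek = (1.0 / fort) * math.log(p[P_K_O] / p[P_K_I])

    sarco = p[P_SARCO_ENABLED]

    # --- L-type Ca current (GHK), junctional ---
    z = 2.0 * V * fort
    if abs(z) < 1e-7:
        ghk = 2.0 * FARADAY * 0.341 * (cj - p[P_CA_O])
    else:
        ghk = (2.0 * FARADAY * z * 0.341 * (cj * math.exp(z) - p[P_CA_O])
               / (math.exp(z) - 1.0))
    ibarca = p[P_P_CA] * p[P_ISO_CAL] * ghk
    i_cal = sarco * ibarca * d * f * (1.0 - fcab)

    # --- NCX (junctional + subsarcolemmal) ---
    exp_nu = math.exp(p[P_NU] * V * fort)
    exp_num1 = math.exp((p[P_NU] - 1.0) * V * fort)
    na3 = p[P_NA_I] ** 3
    nao3 = p[P_NA_O] ** 3

    ka_j = 1.0 / (1.0 + (p[P_KD_ACT] / cj) ** 3)
    s1_j = exp_nu * na3 * p[P_CA_O]
    s2_j = exp_num1 * nao3 * cj
    s3_j = (p[P_KM_CAI] * nao3 * (1.0 + (p[P_NA_I] / p[P_KM_NAI]) ** 3)
            + p[P_KM_NAO] ** 3 * cj * (1.0 + cj / p[P_KM_CAI])
            + p[P_KM_CAO] * na3 + na3 * p[P_CA_O] + nao3 * cj)
    i_ncx_j = (p[P_FJ_NCX] * p[P_IBAR_NCX] * ka_j * (s1_j - s2_j)
               / (s3_j * (1.0 + p[P_K_SAT] * exp_num1)))

    ka_sl = 1.0 / (1.0 + (p[P_KD_ACT] / csl) ** 3)
    s2_sl = exp_num1 * nao3 * csl
    s3_sl = (p[P_KM_CAI] * nao3 * (1.0 + (p[P_NA_I] / p[P_KM_NAI]) ** 3)
             + p[P_KM_NAO] ** 3 * csl * (1.0 + csl / p[P_KM_CAI])
             + p[P_KM_CAO] * na3 + na3 * p[P_CA_O] + nao3 * csl)
    i_ncx_sl = ((1.0 - p[P_FJ_NCX]) * p[P_IBAR_NCX] * ka_sl * (s1_j - s2_sl)
                / (s3_sl * (1.0 + p[P_K_SAT] * exp_num1)))
    i_ncx_j *= sarco
    i_ncx_sl *= sarco

    # --- background Ca leak (subsarcolemmal) ---
    eca_sl = (0.5 / fort) * math.log(p[P_CA_O] / csl)
    i_cab = sarco * p[P_G_CAB] * (V - eca_sl)

    # --- K currents ---
    i_to = p[P_G_TO] * xto * yto * (V - ek)
    # non-inactivating steady-state K current (instantaneous activation)
    i_ss = p[P_G_SS] * (V - ek) / (1.0 + math.exp(-(V + 10.0) / 10.0))
    rkr = 1.0 / (1.0 + math.exp((V + 74.0) / 24.0))
    i_kr = p[P_G_KR] * xkr * rkr * (V - ek)
    aki = 1.02 / (1.0 + math.exp(0.2385 * (V - ek - 59.215)))
    bki = ((0.49124 * math.exp(0.08032 * (V - ek + 5.476))
            + math.exp(0.06175 * (V - ek - 594.31)))
           / (1.0 + math.exp(-0.5143 * (V - ek + 4.753))))
    kiss = aki / (aki + bki)
    i_k1 = p[P_G_K1] * math.sqrt(p[P_K_O] / 5.4) * kiss * (V - ek)

    i_ion = i_cal + i_ncx_j + i_ncx_sl + i_cab + i_to + i_ss + i_kr + i_k1
    dy[iV] = -(i_ion + i_stim)

    # --- gates ---
    vd = V + 14.5
    dss = 1.0 / (1.0 + math.exp(-vd / 6.0))
    if abs(vd) < 1e-4:
        taud = 1.0 / (0.035 * 12.0)
    else:
        taud = dss * (1.0 - math.exp(-vd / 6.0)) / (0.035 * vd)
    dy[iD] = (dss - d) / taud

    fss = min(1.0, 1.0 / (1.0 + math.exp((V + 35.06) / 3.6))
              + 0.6 / (1.0 + math.exp((50.0 - V) / 20.0)))
    tauf = p[P_ISO_TAUF] / (0.0197 * math.exp(-(0.0337 * vd) ** 2) + 0.02)
    dy[iF] = (fss - f) / tauf

    dy[iFCAB] = 1.7 * cj * (1.0 - fcab) - 0.0119 * fcab

    xtoss = 1.0 / (1.0 + math.exp(-(V + 3.0) / 13.0))
    tauxto = 1.5 + 3.5 * math.exp(-(V / 30.0) ** 2)
    dy[iXTO] = (xtoss - xto) / tauxto
    ytoss = 1.0 / (1.0 + math.exp((V + 40.5) / 5.0))
    tauyto = 20.0 + 60.0 / (1.0 + math.exp((V + 45.0) / 5.0))
    dy[iYTO] = (ytoss - yto) / tauyto

    xkrss = 1.0 / (1.0 + math.exp(-(V + 10.0) / 5.0))
    tauxkr = 30.0 + 220.0 / (1.0 + math.exp((V + 25.0) / 10.0))
    dy[iXKR] = (xkrss - xkr) / tauxkr

    # --- RyR with luminal-Ca-dependent sensitivity ---
    kcasr = p[P_MAX_SR] - (p[P_MAX_SR] - p[P_MIN_SR]) / (1.0 + (p[P_EC50_SR] / csr) ** p[P_HILL_SR])
    ko_srca = p[P_KO_CA] * p[P_ISO_RYR] / kcasr
    ki_srca = p[P_KI_CA] * kcasr
    ri = 1.0 - r_ry - o_ry - i_ry
    dy[iRYR_R] = (p[P_KIM] * ri - ki_srca * cj * r_ry
                  - (ko_srca * cj * cj * r_ry - p[P_KOM] * o_ry))
    dy[iRYR_O] = (ko_srca * cj * cj * r_ry - p[P_KOM] * o_ry
                  - (ki_srca * cj * o_ry - p[P_KIM] * i_ry))
    dy[iRYR_I] = (ki_srca * cj * o_ry - p[P_KIM] * i_ry
                  - (p[P_KOM] * i_ry - ko_srca * cj * cj * ri))

    j_ryr = p[P_KS_RYR] * o_ry * (csr - cj)          # mM/ms, SR volume
    j_leak = p[P_K_LEAK] * (csr - cj)                # mM/ms, cytosolic volume

    # --- SERCA (reversible Hill), cytosolic volume ---
    kmf = p[P_KMF_SERCA] * p[P_ISO_KMF]
    fwd = (ci / kmf) ** p[P_HILL_SERCA]
    rev = (csr / p[P_KMR_SERCA]) ** p[P_HILL_SERCA]
    j_serca = p[P_VMAX_SERCA] * (fwd - rev) / (1.0 + fwd + rev)

    # --- lysosomal fluxes (lysosomal volume; positive = out of lysosome) ---
    po = p[P_PO_CACHED]
    if p[P_LYSO_ENABLED] != 0.0:
        if p[P_UPTAKE_BLOCKED] != 0.0:
            j_ls_up = 0.0
        else:
            j_ls_up = (p[P_LS_J_CLC] * po + p[P_LS_J_CLC_LEAK]) * (cls - cj)
        if p[P_RELEASE_BLOCKED] != 0.0:
            j_ls_rel = 0.0
        else:
            j_ls_rel = (p[P_LS_J_TPC] * po + p[P_LS_J_TPC_LEAK]) * (cls - ci)
        dif_j = p[P_LS_J_LS_J] * (cj - cls)   # pL/ms * mM
        dif_i = p[P_LS_J_LS_I] * (ci - cls)
    else:
        j_ls_up = 0.0
        j_ls_rel = 0.0
        dif_j = 0.0
        dif_i = 0.0

    # --- membrane current -> flux conversion (mM/ms) ---
    # electrodiffusive Ca currents: J = -I * Cm / (2 F V) (2 charges per Ca);
    # NCX moves one Ca per net charge, with inward (negative) current in
    # forward mode corresponding to Ca extrusion: J = +I * Cm / (F V).
    cfac = p[P_CM] / (2.0 * FARADAY)
    j_cal_j = -i_cal * cfac / p[P_V_J]
    j_ncx_j = 2.0 * i_ncx_j * cfac / p[P_V_J]
    j_ncx_sl = 2.0 * i_ncx_sl * cfac / p[P_V_SL]
    j_cab_sl = -i_cab * cfac / p[P_V_SL]

    # --- rapid-buffering factors ---
    beta_j = 1.0 / (1.0 + p[P_B_JL] * p[P_KD_JL] / (p[P_KD_JL] + cj) ** 2
                    + p[P_B_JH] * p[P_KD_JH] / (p[P_KD_JH] + cj) ** 2)
    beta_sl = 1.0 / (1.0 + p[P_B_SLL] * p[P_KD_SLL] / (p[P_KD_SLL] + csl) ** 2
                     + p[P_B_SLH] * p[P_KD_SLH] / (p[P_KD_SLH] + csl) ** 2)
    beta_i = 1.0 / (1.0 + p[P_B_CYT1] * p[P_KD_CYT1] / (p[P_KD_CYT1] + ci) ** 2
                    + p[P_B_CYT2] * p[P_KD_CYT2] / (p[P_KD_CYT2] + ci) ** 2)
    beta_sr = 1.0 / (1.0 + p[P_B_CSQN] * p[P_KD_CSQN] / (p[P_KD_CSQN] + csr) ** 2)

    v_j = p[P_V_J]
    v_sl = p[P_V_SL]
    v_i = p[P_V_I]
    v_sr = p[P_V_SR]
    v_ls = p[P_LS_V_LS]

    dcj = (p[P_J_J_SL] * (csl - cj) / v_j
           + j_cal_j + j_ncx_j
           + j_ryr * v_sr / v_j
           + j_leak * v_i / v_j
           + j_ls_up * v_ls / v_j
           + dif_j * (-1.0) / v_j)           # J_ls,j (C_ls - C_j) / V_j
    dcsl = (p[P_J_J_SL] * (cj - csl) / v_sl
            + p[P_J_SL_I] * (ci - csl) / v_sl
            + j_ncx_sl + j_cab_sl)
    dci = (p[P_J_SL_I] * (csl - ci) / v_i
           - j_serca
           + j_ls_rel * v_ls / v_i
           + dif_i * (-1.0) / v_i)           # J_ls,i (C_ls - C_i) / V_i
    dcsr = j_serca * v_i / v_sr - j_ryr - j_leak * v_i / v_sr
    dcls = (dif_j / v_ls - j_ls_up + dif_i / v_ls - j_ls_rel)

    dy[iCJ] = beta_j * dcj
    dy[iCSL] = beta_sl * dcsl
    dy[iCI] = beta_i * dci
    dy[iCSR] = beta_sr * dcsr
    dy[iCLS] = dcls
    return dy


@njit(cache=True)
def fluxes_kernel(y, p):
    """Reported fluxes at one state: J_SERCA, J_RyR, J_ls_up, J_ls_rel, RyR PO, I_NCX."""
    V = y[iV]
    cj = max(y[iCJ], 1e-9)
    csl = max(y[iCSL], 1e-9)
    ci = max(y[iCI], 1e-9)
    csr = max(y[iCSR], 1e-9)
    cls = max(y[iCLS], 1e-9)

    kmf = p[P_KMF_SERCA] * p[P_ISO_KMF]
    fwd = (ci / kmf) ** p[P_HILL_SERCA]
    rev = (csr / p[P_KMR_SERCA]) ** p[P_HILL_SERCA]
    j_serca = p[P_VMAX_SERCA] * (fwd - rev) / (1.0 + fwd + rev)

    j_ryr = p[P_KS_RYR] * y[iRYR_O] * (csr - cj)

    po = p[P_PO_CACHED]
    if p[P_LYSO_ENABLED] != 0.0 and p[P_UPTAKE_BLOCKED] == 0.0:
        j_ls_up = (p[P_LS_J_CLC] * po + p[P_LS_J_CLC_LEAK]) * (cls - cj)
    else:
        j_ls_up = 0.0
    if p[P_LYSO_ENABLED] != 0.0 and p[P_RELEASE_BLOCKED] == 0.0:
        j_ls_rel = (p[P_LS_J_TPC] * po + p[P_LS_J_TPC_LEAK]) * (cls - ci)
    else:
        j_ls_rel = 0.0

    fort = FARADAY / (RGAS * p[P_TEMP])
    exp_nu = math.exp(p[P_NU] * V * fort)
    exp_num1 = math.exp((p[P_NU] - 1.0) * V * fort)
    na3 = p[P_NA_I] ** 3
    nao3 = p[P_NA_O] ** 3
    ka_j = 1.0 / (1.0 + (p[P_KD_ACT] / cj) ** 3)
    s1 = exp_nu * na3 * p[P_CA_O]
    s2_j = exp_num1 * nao3 * cj
    s3_j = (p[P_KM_CAI] * nao3 * (1.0 + (p[P_NA_I] / p[P_KM_NAI]) ** 3)
            + p[P_KM_NAO] ** 3 * cj * (1.0 + cj / p[P_KM_CAI])
            + p[P_KM_CAO] * na3 + na3 * p[P_CA_O] + nao3 * cj)
    i_ncx = (p[P_FJ_NCX] * p[P_IBAR_NCX] * ka_j * (s1 - s2_j)
             / (s3_j * (1.0 + p[P_K_SAT] * exp_num1)))
    ka_sl = 1.0 / (1.0 + (p[P_KD_ACT] / csl) ** 3)
    s2_sl = exp_num1 * nao3 * csl
    s3_sl = (p[P_KM_CAI] * nao3 * (1.0 + (p[P_NA_I] / p[P_KM_NAI]) ** 3)
             + p[P_KM_NAO] ** 3 * csl * (1.0 + csl / p[P_KM_CAI])
             + p[P_KM_CAO] * na3 + na3 * p[P_CA_O] + nao3 * csl)
    i_ncx += ((1.0 - p[P_FJ_NCX]) * p[P_IBAR_NCX] * ka_sl * (s1 - s2_sl)
              / (s3_sl * (1.0 + p[P_K_SAT] * exp_num1)))
    i_ncx *= p[P_SARCO_ENABLED]

    return j_serca, j_ryr, j_ls_up, j_ls_rel, y[iRYR_O], i_ncx


def compute_fluxes(states: np.ndarray, params: CellParameters) -> dict:
    """Evaluate the reported fluxes along a trajectory (n_samples x NSTATE)."""
    p = pack_params(params)
    states = np.atleast_2d(np.asarray(states, dtype=float))
    out = np.empty((states.shape[0], len(FLUX_NAMES)))
    for k in range(states.shape[0]):
        out[k] = fluxes_kernel(states[k], p)
    return {name: out[:, j] for j, name in enumerate(FLUX_NAMES)}


# ---------------------------------------------------------------------------
# python-facing state helpers
# ---------------------------------------------------------------------------

@dataclass
class StateVector:
    """Named view of the dynamical state with invariant checking."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (NSTATE,):
            raise ValueError(f"state must have {NSTATE} components")

    def __getattr__(self, name):
        try:
            idx = STATE_NAMES.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return self.values[idx]

    def bound_calcium(self, params: CellParameters) -> dict:
        """Buffer-bound Ca (mM) in each compartment under rapid equilibrium."""
        cj, csl, ci, csr = (self.values[i] for i in (iCJ, iCSL, iCI, iCSR))
        bound = {
            "C_j": params.b_jl * cj / (params.kd_jl + cj)
                   + params.b_jh * cj / (params.kd_jh + cj),
            "C_sl": params.b_sll * csl / (params.kd_sll + csl)
                    + params.b_slh * csl / (params.kd_slh + csl),
            "C_i": params.b_cyt1 * ci / (params.kd_cyt1 + ci)
                   + params.b_cyt2 * ci / (params.kd_cyt2 + ci),
            "C_sr": params.b_csqn * csr / (params.kd_csqn + csr),
            "C_ls": 0.0,
        }
        return bound

    def total_calcium(self, params: CellParameters) -> float:
        """Total Ca content (pmol-scale: mM * pL) over all compartments."""
        bound = self.bound_calcium(params)
        vols = {"C_j": params.v_j, "C_sl": params.v_sl, "C_i": params.v_i,
                "C_sr": params.v_sr, "C_ls": params.lysosome.v_ls}
        free = {"C_j": self.values[iCJ], "C_sl": self.values[iCSL],
                "C_i": self.values[iCI], "C_sr": self.values[iCSR],
                "C_ls": self.values[iCLS]}
        return sum(vols[k] * (free[k] + bound[k]) for k in vols)

    def check_invariants(self) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            bad = STATE_NAMES[int(np.argmin(np.isfinite(v)))]
            raise ValueError(f"non-finite state component: {bad}")
        for i in CONC_INDICES:
            if v[i] <= 0:
                raise ValueError(f"non-positive concentration: {STATE_NAMES[i]}")
        for i in GATE_INDICES:
            if not (-1e-9 <= v[i] <= 1.0 + 1e-9):
                raise ValueError(f"gating variable out of [0,1]: {STATE_NAMES[i]}")
        occ = v[iRYR_R] + v[iRYR_O] + v[iRYR_I]
        if occ < -1e-6 or occ > 1.0 + 1e-6 or np.any(v[list(RYR_INDICES)] < -1e-6):
            raise ValueError("RyR occupancies must be nonnegative with sum <= 1")


def compute_rhs(state, params: CellParameters, t: float = 0.0,
                i_stim: float = 0.0) -> np.ndarray:
    """Validated wrapper around the compiled RHS kernel."""
    sv = state if isinstance(state, StateVector) else StateVector(np.asarray(state))
    sv.check_invariants()
    p = pack_params(params)
    if not np.all(np.isfinite(p)):
        names = _PARAM_ORDER + _LYSO_ORDER
        bad = names[int(np.argmin(np.isfinite(p[:len(names)])))]
        raise ValueError(f"non-finite parameter: {bad}")
    return rhs(t, sv.values, p, i_stim)


def initial_state() -> np.ndarray:
    """A physiological quiescent starting point (refined by pre-pacing)."""
    y = np.zeros(NSTATE)
    y[iV] = -80.0
    y[iD] = 1e-6
    y[iF] = 1.0
    y[iFCAB] = 0.02
    y[iXTO] = 0.004
    y[iYTO] = 0.95
    y[iXKR] = 0.0
    y[iRYR_R] = 0.85
    y[iRYR_O] = 1e-6
    y[iRYR_I] = 1e-6
    y[iCJ] = 1.0e-4
    y[iCSL] = 1.0e-4
    y[iCI] = 1.0e-4
    y[iCSR] = 0.50
    y[iCLS] = 0.05
    return y
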