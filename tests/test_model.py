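"""Right-hand-side correctness against an independent term-by-term oracle."""

import math

import numpy as np
import pytest

from cardiolyso import model as M
from cardiolyso.model import (CellParameters, IsoScalings, StateVector,
                              apply_iso, compute_rhs)

from conftest import random_physiological_state

F = 96485.0
R = 8314.0


def oracle_rhs(y, p: CellParameters, i_stim: float = 0.0) -> np.ndarray:
    """Independent evaluation of every flux term of the model equations.

    Each term is computed separately, then assembled into the conservation
    equations; shares no code with the compiled kernel.
    """
    (V, d, f, fcab, xto, yto, xkr, r_ry, o_ry, i_ry,
     cj, csl, ci, csr, cls) = y
    ls = p.lysosome
    fort = F / (R * p.temp)
    ek = math.log(p.k_o / p.k_i) / fort

    # --- L-type current (GHK) ---
    z = 2.0 * V * fort
    if abs(z) < 1e-7:
        ghk = 2.0 * F * 0.341 * (cj - p.ca_o)
    else:
        ghk = 2.0 * F * z * 0.341 * (cj * math.exp(z) - p.ca_o) / (math.exp(z) - 1.0)
    i_cal = p.p_ca * p.iso.cal_availability * ghk * d * f * (1.0 - fcab)

    # --- NCX, junctional and subsarcolemmal ---
    def ncx(ca, frac):
        ka = 1.0 / (1.0 + (p.kd_act / ca) ** 3)
        s1 = math.exp(p.nu * V * fort) * p.na_i ** 3 * p.ca_o
        s2 = math.exp((p.nu - 1.0) * V * fort) * p.na_o ** 3 * ca
        s3 = (p.km_cai * p.na_o ** 3 * (1.0 + (p.na_i / p.km_nai) ** 3)
              + p.km_nao ** 3 * ca * (1.0 + ca / p.km_cai)
              + p.km_cao * p.na_i ** 3 + p.na_i ** 3 * p.ca_o + p.na_o ** 3 * ca)
        ksat = 1.0 + p.k_sat * math.exp((p.nu - 1.0) * V * fort)
        return frac * p.ibar_ncx * ka * (s1 - s2) / (s3 * ksat)

    i_ncx_j = ncx(cj, p.fj_ncx)
    i_ncx_sl = ncx(csl, 1.0 - p.fj_ncx)
    i_cab = p.g_cab * (V - 0.5 / fort * math.log(p.ca_o / csl))
    if not p.sarcolemma_enabled:
        i_cal = i_ncx_j = i_ncx_sl = i_cab = 0.0

    # --- potassium currents ---
    i_to = p.g_to * xto * yto * (V - ek)
    i_ss = p.g_ss * (V - ek) / (1.0 + math.exp(-(V + 10.0) / 10.0))
    i_kr = p.g_kr * xkr * (V - ek) / (1.0 + math.exp((V + 74.0) / 24.0))
    aki = 1.02 / (1.0 + math.exp(0.2385 * (V - ek - 59.215)))
    bki = ((0.49124 * math.exp(0.08032 * (V - ek + 5.476))
            + math.exp(0.06175 * (V - ek - 594.31)))
           / (1.0 + math.exp(-0.5143 * (V - ek + 4.753))))
    i_k1 = p.g_k1 * math.sqrt(p.k_o / 5.4) * aki / (aki + bki) * (V - ek)

    dV = -(i_cal + i_ncx_j + i_ncx_sl + i_cab + i_to + i_ss + i_kr + i_k1 + i_stim)

    # --- gating kinetics ---
    vd = V + 14.5
    dss = 1.0 / (1.0 + math.exp(-vd / 6.0))
    taud = (1.0 / (0.035 * 12.0) if abs(vd) < 1e-4
            else dss * (1.0 - math.exp(-vd / 6.0)) / (0.035 * vd))
    fss = min(1.0, 1.0 / (1.0 + math.exp((V + 35.06) / 3.6))
              + 0.6 / (1.0 + math.exp((50.0 - V) / 20.0)))
    tauf = p.iso.cal_tau_f / (0.0197 * math.exp(-(0.0337 * vd) ** 2) + 0.02)
    xtoss = 1.0 / (1.0 + math.exp(-(V + 3.0) / 13.0))
    tauxto = 1.5 + 3.5 * math.exp(-(V / 30.0) ** 2)
    ytoss = 1.0 / (1.0 + math.exp((V + 40.5) / 5.0))
    tauyto = 20.0 + 60.0 / (1.0 + math.exp((V + 45.0) / 5.0))
    xkrss = 1.0 / (1.0 + math.exp(-(V + 10.0) / 5.0))
    tauxkr = 30.0 + 220.0 / (1.0 + math.exp((V + 25.0) / 10.0))
    gates = [(dss - d) / taud, (fss - f) / tauf,
             1.7 * cj * (1.0 - fcab) - 0.0119 * fcab,
             (xtoss - xto) / tauxto, (ytoss - yto) / tauyto,
             (xkrss - xkr) / tauxkr]

    # --- RyR four-state scheme with luminal modulation ---
    kcasr = p.max_sr - (p.max_sr - p.min_sr) / (1.0 + (p.ec50_sr / csr) ** p.hill_sr)
    ko = p.ko_ca * p.iso.ryr_open / kcasr
    ki = p.ki_ca * kcasr
    ri = 1.0 - r_ry - o_ry - i_ry
    dr = p.kim * ri - ki * cj * r_ry - (ko * cj ** 2 * r_ry - p.kom * o_ry)
    do = ko * cj ** 2 * r_ry - p.kom * o_ry - (ki * cj * o_ry - p.kim * i_ry)
    di = ki * cj * o_ry - p.kim * i_ry - (p.kom * i_ry - ko * cj ** 2 * ri)

    j_ryr = p.ks_ryr * o_ry * (csr - cj)
    j_leak = p.k_leak * (csr - cj)
    kmf = p.kmf_serca * p.iso.serca_kmf
    fwd = (ci / kmf) ** p.hill_serca
    rev = (csr / p.kmr_serca) ** p.hill_serca
    j_serca = p.vmax_serca * (fwd - rev) / (1.0 + fwd + rev)

    # --- lysosomal fluxes, printed-equation form ---
    po = ls.open_probability()
    j_up = 0.0 if ls.uptake_blocked else (ls.j_clc * po + ls.j_clc_leak) * (cls - cj)
    j_rel = 0.0 if ls.release_blocked else (ls.j_tpc * po + ls.j_tpc_leak) * (cls - ci)
    if not p.lysosome_enabled:
        j_up = j_rel = 0.0
        dif_j = dif_i = 0.0
    else:
        dif_j = ls.j_ls_j * (cj - cls)
        dif_i = ls.j_ls_i * (ci - cls)

    # --- current-to-flux conversions ---
    cf = p.cm / (2.0 * F)
    j_cal_j = -i_cal * cf / p.v_j
    j_ncx_j = i_ncx_j * p.cm / F / p.v_j
    j_ncx_sl = i_ncx_sl * p.cm / F / p.v_sl
    j_cab_sl = -i_cab * cf / p.v_sl

    def beta(c, b1, kd1, b2, kd2):
        return 1.0 / (1.0 + b1 * kd1 / (kd1 + c) ** 2 + b2 * kd2 / (kd2 + c) ** 2)

    beta_j = beta(cj, p.b_jl, p.kd_jl, p.b_jh, p.kd_jh)
    beta_sl = beta(csl, p.b_sll, p.kd_sll, p.b_slh, p.kd_slh)
    beta_i = beta(ci, p.b_cyt1, p.kd_cyt1, p.b_cyt2, p.kd_cyt2)
    beta_sr = 1.0 / (1.0 + p.b_csqn * p.kd_csqn / (p.kd_csqn + csr) ** 2)

    v_ls = ls.v_ls
    dcj = beta_j * (p.j_j_sl * (csl - cj) / p.v_j + j_cal_j + j_ncx_j
                    + j_ryr * p.v_sr / p.v_j + j_leak * p.v_i / p.v_j
                    + j_up * v_ls / p.v_j + ls.j_ls_j * (cls - cj) / p.v_j
                    * (1.0 if p.lysosome_enabled else 0.0))
    dcsl = beta_sl * (p.j_j_sl * (cj - csl) / p.v_sl
                      + p.j_sl_i * (ci - csl) / p.v_sl + j_ncx_sl + j_cab_sl)
    dci = beta_i * (p.j_sl_i * (csl - ci) / p.v_i - j_serca
                    + j_rel * v_ls / p.v_i + ls.j_ls_i * (cls - ci) / p.v_i
                    * (1.0 if p.lysosome_enabled else 0.0))
    dcsr = beta_sr * (j_serca * p.v_i / p.v_sr - j_ryr - j_leak * p.v_i / p.v_sr)
    dcls = dif_j / v_ls - j_up + dif_i / v_ls - j_rel

    return np.array([dV, *gates, dr, do, di, dcj, dcsl, dci, dcsr, dcls])


def test_rhs_matches_oracle_on_random_states(params, rng):
    """Compiled RHS equals independently assembled flux terms to 1e-12."""
    for _ in range(150):
        y = random_physiological_state(rng)
        got = compute_rhs(y, params)
        want = oracle_rhs(y, params)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-18)


def test_rhs_matches_oracle_with_iso_and_blocks(rng):
    params = apply_iso(CellParameters(), 100)
    params.lysosome.uptake_blocked = True
    for _ in range(25):
        y = random_physiological_state(rng)
        np.testing.assert_allclose(compute_rhs(y, params),
                                   oracle_rhs(y, params), rtol=1e-12, atol=1e-18)


def test_lysosome_equilibrium_gives_zero_lysosomal_derivative(params):
    """Equal Ca in lysosome, junction and cytosol: all gradients vanish."""
    y = M.initial_state()
    c = 2e-4
    y[M.iCJ] = y[M.iCI] = y[M.iCLS] = c
    dy = compute_rhs(y, params)
    ls = params.lysosome
    # isolate lysosomal terms: they are the only contributions to dC_ls
    assert dy[M.iCLS] == pytest.approx(0.0, abs=1e-18)


def test_lysosome_exchange_conserves_mass(params, rng):
    """Volume-weighted lysosomal contributions cancel across compartments."""
    for _ in range(20):
        y = random_physiological_state(rng)
        with_ls = compute_rhs(y, params)
        without = compute_rhs(y, params.copy(lysosome_enabled=False))
        delta = with_ls - without
        # undo rapid-buffering factors to recover total-Ca fluxes
        def beta(c, b1, kd1, b2, kd2):
            return 1.0 / (1.0 + b1 * kd1 / (kd1 + c) ** 2 + b2 * kd2 / (kd2 + c) ** 2)
        bj = beta(y[M.iCJ], params.b_jl, params.kd_jl, params.b_jh, params.kd_jh)
        bi = beta(y[M.iCI], params.b_cyt1, params.kd_cyt1,
                  params.b_cyt2, params.kd_cyt2)
        total = (params.lysosome.v_ls * delta[M.iCLS]
                 + params.v_j * delta[M.iCJ] / bj
                 + params.v_i * delta[M.iCI] / bi)
        scale = max(abs(delta[M.iCLS]) * params.lysosome.v_ls, 1e-12)
        assert abs(total) / scale < 1e-9


def test_iso_scalings():
    params = CellParameters()
    assert apply_iso(params, 0).iso.is_identity()
    iso = apply_iso(params, 100).iso
    assert iso.cal_availability == 1.56
    assert iso.ryr_open == 2.0
    assert iso.serca_kmf == pytest.approx(0.45)
    with pytest.raises(ValueError, match="ISO"):
        apply_iso(params, 50)


def test_invalid_state_names_offending_component(params):
    y = M.initial_state()
    y[M.iCSR] = -0.1
    with pytest.raises(ValueError, match="C_sr"):
        compute_rhs(y, params)
    y = M.initial_state()
    y[M.iD] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        compute_rhs(y, params)


def test_state_vector_total_calcium(params):
    sv = StateVector(M.initial_state())
    total = sv.total_calcium(params)
    assert total > 0
    bound = sv.bound_calcium(params)
    assert all(v >= 0 for v in np.atleast_1d(list(bound.values())))
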