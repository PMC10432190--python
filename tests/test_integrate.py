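"""Integration driver: quiescence, conservation, reference cross-checks."""

import numpy as np
import pytest

from cardiolyso import model as M
from cardiolyso.integrate import simulate, simulate_reference
from cardiolyso.model import CellParameters, StateVector
from cardiolyso.protocols import ProtocolSpec, PacingSegment, make_protocol


def quiescent_protocol(duration_ms=5000.0):
    # one "beat" with zero-amplitude stimulus covering the whole window
    return ProtocolSpec("QUIESCENT", [PacingSegment(1000.0 / duration_ms, 1)])


def test_quiescent_cell_reaches_rest(params):
    params = params.copy(stim_amplitude=0.0)
    res = simulate(params, quiescent_protocol(), record_ms=5000.0)
    assert res.ok
    dy = M.rhs(0.0, res.final_state, M.pack_params(res.params), 0.0)
    scale = np.maximum(np.abs(res.final_state), 1e-3)
    assert np.max(np.abs(dy) / scale) < 5e-4  # per-ms relative drift


def test_total_calcium_rate_is_zero_without_sarcolemmal_fluxes(params, rng):
    """The equations conserve total (free+bound) Ca exactly in a closed cell."""
    from conftest import random_physiological_state

    closed = params.copy(sarcolemma_enabled=False)
    p = M.pack_params(closed)
    for _ in range(50):
        y = random_physiological_state(rng)
        dy = M.rhs(0.0, y, p, 0.0)

        def beta(c, b1, k1, b2, k2):
            return 1.0 / (1.0 + b1 * k1 / (k1 + c) ** 2 + b2 * k2 / (k2 + c) ** 2)

        rate = (closed.v_j * dy[M.iCJ] / beta(y[M.iCJ], closed.b_jl, closed.kd_jl,
                                              closed.b_jh, closed.kd_jh)
                + closed.v_sl * dy[M.iCSL] / beta(y[M.iCSL], closed.b_sll,
                                                  closed.kd_sll, closed.b_slh,
                                                  closed.kd_slh)
                + closed.v_i * dy[M.iCI] / beta(y[M.iCI], closed.b_cyt1,
                                                closed.kd_cyt1, closed.b_cyt2,
                                                closed.kd_cyt2)
                + closed.v_sr * dy[M.iCSR]
                * (1.0 + closed.b_csqn * closed.kd_csqn
                   / (closed.kd_csqn + y[M.iCSR]) ** 2)
                + closed.lysosome.v_ls * dy[M.iCLS])
        scale = max(abs(closed.v_sr * dy[M.iCSR]), 1e-6)
        assert abs(rate) / scale < 1e-12


def test_total_calcium_conserved_over_ten_seconds(params):
    """Closed-cell total Ca drifts only by accumulated integration error."""
    params = params.copy(sarcolemma_enabled=False, stim_amplitude=0.0)
    proto = quiescent_protocol(10_000.0)
    res = simulate(params, proto, record_ms=10_000.0)
    assert res.ok
    start = StateVector(res.states[0]).total_calcium(res.params)
    end = StateVector(res.final_state).total_calcium(res.params)
    assert end == pytest.approx(start, rel=1e-3)


def test_matches_reference_integrator(params):
    """Explicit pair vs implicit BDF at 100x tighter tolerance, short run."""
    proto = make_protocol("CTRL", n_beats=3)
    res = simulate(params, proto, record_ms=proto.duration_ms)
    ref = simulate_reference(params, proto, rtol=1e-8, atol=1e-11)
    n = min(res.t.size, ref.t.size)
    # last beat of cytosolic calcium within 0.5% relative
    m = res.t[:n] >= 2000.0
    ci, ci_ref = res.states[:n][m, M.iCI], ref.states[:n][m, M.iCI]
    err = np.max(np.abs(ci - ci_ref)) / (ci_ref.max() - ci_ref.min())
    assert err < 0.005


def test_steady_state_after_pacing(params):
    """Beat-to-beat diastolic drift is negligible at the end of the protocol."""
    proto = make_protocol("CTRL", n_beats=150)
    res = simulate(params, proto)
    stim = res.record_stim_times
    ci = res.trace("C_i")
    dia = []
    for k in (-2, -1):
        m = (res.t >= stim[k] - 50.0) & (res.t <= stim[k])
        dia.append(ci[m].min())
    assert dia[1] == pytest.approx(dia[0], rel=1e-3)


def test_baseline_reduction_without_lysosome(params):
    """Zeroed lysosomal rates reproduce the lysosome-free model to 0.1%."""
    zeroed = params.copy()
    for attr in ("j_clc", "j_tpc", "j_clc_leak", "j_tpc_leak", "j_ls_j", "j_ls_i"):
        setattr(zeroed.lysosome, attr, 0.0)
    absent = params.copy(lysosome_enabled=False)
    proto = make_protocol("CTRL", n_beats=20)
    res_zeroed = simulate(zeroed, proto)
    res_absent = simulate(absent, proto)
    for name in ("C_j", "C_i", "C_sr"):
        a, b = res_zeroed.trace(name), res_absent.trace(name)
        scale = np.abs(b).max()
        assert np.max(np.abs(a - b)) / scale < 1e-3


def test_solver_failure_is_flagged_not_raised(params):
    broken = params.copy(vmax_serca=1e9)  # forces step-size collapse
    res = simulate(broken, make_protocol("CTRL", n_beats=2))
    assert res.status == "failed"
    assert res.final_state is None


def test_gates_and_concentrations_stay_physiological(params):
    res = simulate(params, make_protocol("ISO", n_beats=30))
    assert res.ok
    for i in M.GATE_INDICES:
        g = res.states[:, i]
        assert g.min() >= -1e-6 and g.max() <= 1.0 + 1e-6
    for i in M.CONC_INDICES:
        assert res.states[:, i].min() > 0

def test_fast_pacing_captures_one_to_one(params):
    proto = make_protocol("FASTPACE_ISO", n_beats=30)
    res = simulate(proto and params, proto, record_ms=proto.duration_ms)
    assert res.ok
    v = res.trace("V")
    # each 10 Hz stimulus elicits a depolarization above -40 mV
    for s in res.stim_times[5:30]:
        m = (res.t >= s) & (res.t <= s + 30.0)
        assert v[m].max() > -40.0
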