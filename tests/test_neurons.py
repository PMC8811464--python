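"""Solver-suite correctness: propagators, RK, Parker-Sochacki."""

import numpy as np
import pytest
from scipy.linalg import expm

from procsnn.neurons import (
    ADEX_DEFAULT,
    IZHIKEVICH_TONIC,
    LifParams,
    LifState,
    build_propagator,
    coba_current,
    make_rhs,
    rhs_adex,
    rhs_izhikevich,
    step_exact,
    step_ps,
    step_rk,
)
from procsnn.neurons import _system_matrix

LIF = LifParams()  # microcircuit defaults: tau_m = 10 ms, tau_s = 0.5 ms


# ---------------------------------------------------------------------------
# exact integration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kernel,params", [
    ("exp", LifParams(C_m=250.0, g_m=25.0, tau_s_e=0.5, tau_s_i=0.5)),
    ("exp", LifParams(C_m=250.0, g_m=500.0)),          # tau_m == tau_s limit
    ("alpha", LifParams()),
    ("beta", LifParams(tau_s_e=2.0, tau_r_e=0.5, tau_s_i=4.0, tau_r_i=0.25)),
])
def test_propagator_matches_matrix_exponential(kernel, params):
    dt = 0.1
    prop = build_propagator(params, dt, kernel)
    oracle = expm(_system_matrix(params, kernel) * dt)
    assert np.abs(prop.P - oracle).max() < 1e-12
    # upper triangular, diagonals are the pure decay factors
    assert np.allclose(np.tril(prop.P, -1), 0.0)


def test_propagator_small_dt_identity():
    prop = build_propagator(LIF, 1e-9, "exp")
    assert np.abs(prop.P - np.eye(3)).max() < 1e-6


def test_propagator_inhibitory_diagonal():
    p = LifParams(tau_s_i=0.7)
    prop = build_propagator(p, 0.1, "exp")
    assert prop.P[2, 2] == pytest.approx(np.exp(-0.1 / 0.7), abs=1e-15)


def test_propagator_rejects_bad_dt():
    with pytest.raises(ValueError):
        build_propagator(LIF, 0.0, "exp")


def test_time_translation_two_half_steps_equal_one():
    """Exact integration composes: P(dt/2)^2 == P(dt) to double precision."""
    full = build_propagator(LIF, 0.1, "exp").P
    half = build_propagator(LIF, 0.05, "exp").P
    assert np.abs(half @ half - full).max() < 1e-14


def test_step_exact_fixed_point_and_threshold():
    prop = build_propagator(LIF, 0.1, "exp")
    s = LifState.zeros(3, LIF)
    zero = np.zeros(3, dtype=np.float32)
    spikes = step_exact(s, prop, zero, zero, LIF)
    assert not spikes.any()
    assert np.allclose(s.V, LIF.E_L)
    # force a crossing
    s.V[1] = np.float32(LIF.V_th + 1.0)
    spikes = step_exact(s, prop, zero, zero, LIF)
    assert list(spikes) == [False, True, False]
    assert s.V[1] == np.float32(LIF.V_reset)


def test_single_psp_matches_closed_form():
    """One excitatory spike of weight J at an exponential synapse produces
    the difference-of-exponentials PSP at every grid point."""
    J, dt = 100.0, 0.1
    prop = build_propagator(LIF, dt, "exp")
    P = prop.P  # double precision
    tau_m, tau_s, C = LIF.tau_m, LIF.tau_s_e, LIF.C_m
    y = np.array([0.0, 0.0, 0.0])  # V relative to E_L
    y[1] = J  # arrival
    for k in range(1, 200):
        y = P @ y
        t = k * dt
        v_exact = (J / C) * (np.exp(-t / tau_m) - np.exp(-t / tau_s)) / (1 / tau_s - 1 / tau_m)
        assert abs(y[0] - v_exact) < 1e-9
    # the single-precision engine path tracks the same curve
    s = LifState.zeros(1, LIF)
    forc = np.zeros(1, dtype=np.float32)
    step_exact(s, prop, np.array([J], dtype=np.float32), forc, LIF)
    vpk = []
    for _ in range(200):
        step_exact(s, prop, forc, forc, LIF)
        vpk.append(float(s.V[0]) - LIF.E_L)
    t = dt * np.arange(1, 201)
    v_exact = (J / C) * (np.exp(-t / tau_m) - np.exp(-t / tau_s)) / (1 / tau_s - 1 / tau_m)
    assert np.abs(np.array(vpk) - v_exact).max() < 1e-4


def test_refractory_spacing():
    """A strongly driven neuron never fires two spikes closer than t_ref."""
    p = LifParams(I_ext=1000.0)
    prop = build_propagator(p, 0.1, "exp")
    s = LifState.zeros(1, p)
    zero = np.zeros(1, dtype=np.float32)
    spike_steps = []
    for t in range(2000):
        if step_exact(s, prop, zero, zero, p)[0]:
            spike_steps.append(t)
    assert len(spike_steps) > 3
    isi = np.diff(spike_steps) * 0.1
    assert np.all(isi > p.t_ref - 1e-9)


def test_alpha_kernel_peak_normalization():
    """With the peak-normalized alpha kernel, a weight-J spike drives the
    synaptic current to a maximum of J."""
    p = LifParams(tau_s_e=2.0)
    prop = build_propagator(p, 0.01, "alpha")
    s = LifState.zeros(1, p, kernel="alpha")
    zero = np.zeros(1, dtype=np.float32)
    step_exact(s, prop, np.array([50.0], dtype=np.float32), zero, p)
    peak = 0.0
    for _ in range(2000):
        step_exact(s, prop, zero, zero, p)
        peak = max(peak, float(s.I_e[0]))
    assert peak == pytest.approx(50.0, rel=1e-3)


# ---------------------------------------------------------------------------
# nonlinear right-hand sides
# ---------------------------------------------------------------------------

def test_izhikevich_fixed_point():
    dv, du = rhs_izhikevich(-70.0, -14.0, 0.0, IZHIKEVICH_TONIC)
    assert abs(dv) < 1e-10 and abs(du) < 1e-10


def test_coba_zero_conductance():
    assert coba_current(0.0, 0.0, -60.0) == 0.0


def test_adex_linear_limit():
    """Far below V_T the exponential term is negligible and AdEx reduces
    to the linear leak."""
    p = ADEX_DEFAULT
    V = p.V_T - 40.0
    dV, _ = rhs_adex(V, 0.0, 0.0, p)
    linear = -p.g_L * (V - p.E_L) / p.C
    assert dV == pytest.approx(linear, abs=1e-6)


# ---------------------------------------------------------------------------
# Runge-Kutta
# ---------------------------------------------------------------------------

def test_rk_zero_rhs_identity():
    y = np.array([1.0, -2.0])
    for order in (1, 2, 4):
        assert np.array_equal(step_rk(lambda _: np.zeros(2), order, y, 0.1), y)


def test_rk1_is_forward_euler():
    rhs = make_rhs("izhikevich", IZHIKEVICH_TONIC, I_ext=5.0)
    y = np.array([-60.0, -12.0])
    assert np.allclose(step_rk(rhs, 1, y, 0.1), y + 0.1 * rhs(y))


def test_rk4_local_error_order():
    """Richardson: halving dt shrinks the local error of RK4 by ~2^5 on
    linear decay."""
    rhs = lambda y: -y / 0.5
    y0 = np.array([1.0])
    errs = []
    for dt in (0.1, 0.05):
        errs.append(abs(step_rk(rhs, 4, y0, dt)[0] - np.exp(-dt / 0.5)))
    ratio = errs[0] / errs[1]
    assert 2**4.5 < ratio < 2**5.5


def test_rk_invalid_order():
    with pytest.raises(ValueError):
        step_rk(lambda y: y, 3, np.zeros(1), 0.1)


# ---------------------------------------------------------------------------
# Parker-Sochacki
# ---------------------------------------------------------------------------

def test_ps_order_bounds():
    with pytest.raises(ValueError):
        step_ps("izhikevich", 0, np.array([-65.0, -13.0]), 0.1, IZHIKEVICH_TONIC)
    with pytest.raises(ValueError):
        step_ps("izhikevich", 7, np.array([-65.0, -13.0]), 0.1, IZHIKEVICH_TONIC)


@pytest.mark.parametrize("model,y0,p,kw", [
    ("lif_cuba_exp", np.array([-60.0, 30.0, -10.0]), LIF, {}),
    ("izhikevich", np.array([-60.0, -12.0]), IZHIKEVICH_TONIC, {"I_ext": 5.0}),
    ("adex", np.array([-60.0, 10.0]), ADEX_DEFAULT, {"I_ext": 100.0}),
    ("lif_coba_exp", np.array([-60.0, 5.0, 3.0]), LIF, {}),
])
def test_ps1_equals_forward_euler(model, y0, p, kw):
    ps = step_ps(model, 1, y0, 0.1, p, **kw)
    rhs = make_rhs(model, p, **kw)
    assert np.allclose(ps, y0 + 0.1 * rhs(y0), rtol=1e-12, atol=1e-12)


def test_ps6_matches_exact_propagator_linear():
    """On the linear LIF system (states of order one), PS-6 agrees with
    the exact propagator to 1e-8 per 0.1 ms step for tau >= 0.5 ms."""
    prop = build_propagator(LIF, 0.1, "exp")
    ystar = np.array([prop.V_inf, 0.0, 0.0])
    y0 = np.array([LIF.E_L + 1.0, 1.0, -1.0])
    exact = prop.P @ (y0 - ystar) + ystar
    ps = step_ps("lif_cuba_exp", 6, y0, 0.1, LIF)
    assert np.abs(ps - exact).max() < 1e-8


def test_ps4_rk4_agree_at_fifth_order():
    """PS-4 and RK4 share the fourth-order Taylor expansion; their
    one-step difference on tonic-spiking Izhikevich dynamics shrinks
    like dt^5."""
    y0 = np.array([-60.0, -12.0])
    rhs = make_rhs("izhikevich", IZHIKEVICH_TONIC, I_ext=10.0)
    diffs = []
    for dt in (0.2, 0.1):
        d = np.abs(step_rk(rhs, 4, y0, dt)
                   - step_ps("izhikevich", 4, y0, dt, IZHIKEVICH_TONIC, I_ext=10.0)).max()
        diffs.append(d)
    ratio = diffs[0] / diffs[1]
    assert 2**4 < ratio < 2**6


@pytest.mark.parametrize("method,nominal", [
    (("rk", 1), 1), (("rk", 2), 2), (("rk", 4), 4),
    (("ps", 1), 1), (("ps", 2), 2), (("ps", 3), 3),
    (("ps", 4), 4), (("ps", 5), 5), (("ps", 6), 6),
])
def test_empirical_convergence_orders(method, nominal):
    """Global-error log-log slope on the smooth linear LIF trajectory
    (exact solution = matrix exponential, machine precision) is within
    0.2 of the nominal order."""
    M = _system_matrix(LIF, "exp")
    y0 = np.array([-60.0, 100.0, -50.0])
    ystar = np.array([LIF.E_L, 0.0, 0.0])
    T = 2.0
    ref = expm(M * T) @ (y0 - ystar) + ystar
    rhs = make_rhs("lif_cuba_exp", LIF)
    dts = np.array([0.2, 0.1, 0.05, 0.025])
    errs = []
    for dt in dts:
        y = y0.astype(np.float64)
        for _ in range(int(round(T / dt))):
            if method[0] == "rk":
                y = step_rk(rhs, method[1], y, dt)
            else:
                y = step_ps("lif_cuba_exp", method[1], y, dt, LIF)
        errs.append(np.abs(y - ref).max())
    slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
    assert abs(slope - nominal) < 0.2


def test_spike_raster_invariance_exact_vs_ps6():
    """On a 100-neuron linear LIF fixture at dt = 0.1 ms, exact
    integration and PS-6 (with identical threshold handling) produce
    identical spike rasters."""
    n, steps, dt = 100, 2000, 0.1
    rng = np.random.default_rng(5)
    I = rng.uniform(300.0, 600.0, size=n)  # suprathreshold constant drives
    pr = build_propagator(LIF, dt, "exp")
    V_star = LIF.E_L + I / LIF.g_m  # per-neuron fixed point
    rasters = []
    for solver in ("exact", "ps6"):
        y = np.stack([np.full(n, -58.0), np.zeros(n), np.zeros(n)])
        ref = np.zeros(n, dtype=int)
        raster = []
        for t in range(steps):
            if solver == "exact":
                out = np.tensordot(pr.P, y, axes=(1, 0))
                out[0] += V_star * (1 - pr.P[0, 0])
            else:
                out = step_ps("lif_cuba_exp", 6, y, dt, LIF, I_ext=I)
            V = out[0]
            in_ref = ref > 0
            V[in_ref] = LIF.V_reset
            ref[in_ref] -= 1
            sp = (~in_ref) & (V >= LIF.V_th)
            V[sp] = LIF.V_reset
            ref[sp] = int(round(LIF.t_ref / dt))
            y = out
            raster.extend((t, i) for i in np.nonzero(sp)[0])
        rasters.append(raster)
    assert rasters[0] == rasters[1]
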