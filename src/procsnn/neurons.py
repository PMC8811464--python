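"""Neuron/synapse dynamics and the ODE solver suite.

Models
------
* **LIF** with lumped current-based (CUBA) synapses,
  ``C_m dV/dt = -g_m (V - E_L) + I_e + I_i + I_ext``, one synaptic state
  per receptor type.  Kernels: exponential decay (3 coupled states
  [V, I_e, I_i]) or alpha/beta shapes (5 states [V, I_e, Z_e, I_i, Z_i]).
  The linear system is advanced error-free on the time grid by the
  matrix exponential of the system matrix ("exact integration"); the
  propagator is upper triangular in the state ordering above.
* **Izhikevich** (quadratic adaptation model) and **AdEx** (adaptive
  exponential integrate-and-fire) in their published forms, with
  current- or conductance-based coupling.
* **COBA** coupling, ``I = g_e (E_e - V) + g_i (E_i - V)``.

Solvers
-------
Exact integration (linear systems only), classical Runge-Kutta of order
1/2/4 (single step per grid interval, no sub-stepping), and
Parker-Sochacki integration of order 1..6, which builds the exact
Maclaurin coefficients of the solution via recurrences on the
(polynomialized) right-hand side.

Simulation state is held in 32-bit floats; propagator entries are
computed in double precision and cast once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import expm as _expm

__all__ = [
    "LifParams",
    "IzhikevichParams",
    "AdExParams",
    "LifState",
    "Propagator",
    "build_propagator",
    "step_exact",
    "rhs_izhikevich",
    "rhs_adex",
    "coba_current",
    "make_rhs",
    "step_rk",
    "step_ps",
    "MICROCIRCUIT_LIF",
    "IZHIKEVICH_TONIC",
    "ADEX_DEFAULT",
]


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifParams:
    """Leaky integrate-and-fire parameters.

    Units: capacitance pF, conductance nS, voltage mV, time ms,
    current pA — mutually consistent (pA/pF = mV/ms, pF/nS = ms).
    """

    C_m: float = 250.0       # pF
    g_m: float = 25.0        # nS  (tau_m = C_m/g_m = 10 ms)
    E_L: float = -65.0       # mV
    V_th: float = -50.0      # mV
    V_reset: float = -65.0   # mV
    t_ref: float = 2.0       # ms
    tau_s_e: float = 0.5     # ms
    tau_s_i: float = 0.5     # ms
    I_ext: float = 0.0       # pA
    # rise constants for the beta kernel; None means alpha (rise = decay)
    tau_r_e: float | None = None
    tau_r_i: float | None = None

    def __post_init__(self) -> None:
        if min(self.C_m, self.g_m, self.tau_s_e, self.tau_s_i) <= 0:
            raise ValueError("capacitance, conductance and time constants must be > 0")
        if self.V_reset >= self.V_th:
            raise ValueError("V_reset must lie below V_th")

    @property
    def tau_m(self) -> float:
        return self.C_m / self.g_m


@dataclass(frozen=True)
class IzhikevichParams:
    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_peak: float = 30.0


@dataclass(frozen=True)
class AdExParams:
    C: float = 281.0         # pF
    g_L: float = 30.0        # nS
    E_L: float = -70.6       # mV
    V_T: float = -50.4       # mV
    Delta_T: float = 2.0     # mV
    a: float = 4.0           # nS
    b: float = 80.5          # pA
    tau_w: float = 144.0     # ms
    V_reset: float = -70.6   # mV
    v_peak: float = 0.0      # mV (numerical spike cutoff)

    def __post_init__(self) -> None:
        if self.Delta_T <= 0 or self.tau_w <= 0:
            raise ValueError("Delta_T and tau_w must be > 0")


#: LIF parameterization of the cortical microcircuit benchmark.
MICROCIRCUIT_LIF = LifParams()

#: Published tonic-spiking regime of the Izhikevich model.
IZHIKEVICH_TONIC = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=6.0)

ADEX_DEFAULT = AdExParams()


# ---------------------------------------------------------------------------
# exact integration
# ---------------------------------------------------------------------------

@dataclass
class Propagator:
    """One-step update matrix of the linear LIF system.

    ``P = expm(M dt)`` for the system matrix M over the state ordering
    [V, I_e, I_i] (exponential kernel) or [V, I_e, Z_e, I_i, Z_i]
    (alpha/beta).  ``V_inf`` is the fixed point of the membrane equation
    under the constant external current; the affine update is
    ``y' = P (y - y*) + y*`` with y* zero in all synaptic coordinates.

    ``forcing_scale_e/i`` convert an incoming weight J (pA) into the
    jump of the kernel state it feeds (the decaying current itself for
    the exponential kernel; the auxiliary state Z, peak-normalized, for
    alpha/beta).
    """

    P: np.ndarray                # float64, (dim, dim), upper triangular
    dt: float
    kernel: str
    V_inf: float
    ref_steps: int
    forcing_scale_e: float
    forcing_scale_i: float
    P32: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.P32 = self.P.astype(np.float32)

    @property
    def dim(self) -> int:
        return self.P.shape[0]


def _phi(tau_a: float, tau_b: float, dt: float, rtol: float = 1e-9) -> float:
    """(exp(-dt/tau_a) - exp(-dt/tau_b)) / (1/tau_b - 1/tau_a), with the
    analytic limit dt*exp(-dt/tau) when the time constants coincide."""
    if abs(tau_a - tau_b) <= rtol * max(tau_a, tau_b):
        tau = 0.5 * (tau_a + tau_b)
        return dt * np.exp(-dt / tau)
    ra, rb = 1.0 / tau_a, 1.0 / tau_b
    return (np.exp(-dt * ra) - np.exp(-dt * rb)) / (rb - ra)


def _system_matrix(p: LifParams, kernel: str) -> np.ndarray:
    tau_m = p.tau_m
    if kernel == "exp":
        return np.array(
            [
                [-1.0 / tau_m, 1.0 / p.C_m, 1.0 / p.C_m],
                [0.0, -1.0 / p.tau_s_e, 0.0],
                [0.0, 0.0, -1.0 / p.tau_s_i],
            ]
        )
    if kernel in ("alpha", "beta"):
        tr_e = p.tau_r_e if (kernel == "beta" and p.tau_r_e) else p.tau_s_e
        tr_i = p.tau_r_i if (kernel == "beta" and p.tau_r_i) else p.tau_s_i
        return np.array(
            [
                [-1.0 / tau_m, 1.0 / p.C_m, 0.0, 1.0 / p.C_m, 0.0],
                [0.0, -1.0 / p.tau_s_e, 1.0 / p.tau_s_e, 0.0, 0.0],
                [0.0, 0.0, -1.0 / tr_e, 0.0, 0.0],
                [0.0, 0.0, 0.0, -1.0 / p.tau_s_i, 1.0 / p.tau_s_i],
                [0.0, 0.0, 0.0, 0.0, -1.0 / tr_i],
            ]
        )
    raise ValueError(f"unknown kernel {kernel!r}")


def _kernel_peak_scale(tau_d: float, tau_r: float) -> float:
    """Jump of Z per unit weight such that the resulting postsynaptic
    current peaks at exactly the weight (peak-normalized kernel)."""
    if abs(tau_d - tau_r) <= 1e-9 * max(tau_d, tau_r):
        return float(np.e)  # alpha: I(t) = (Z0/tau) t e^{-t/tau}, peak Z0/e
    rr, rd = 1.0 / tau_r, 1.0 / tau_d
    t_peak = np.log(tau_d / tau_r) / (rr - rd)
    peak = (np.exp(-t_peak * rr) - np.exp(-t_peak * rd)) / ((rd - rr) * tau_d)
    return float(1.0 / peak)


def build_propagator(p: LifParams, dt: float, kernel: str = "exp") -> Propagator:
    """Closed-form exact-integration propagator for one step of size dt.

    The 3-state (exponential kernel) entries are assembled analytically,
    including the degenerate equal-time-constant limit; the 5-state
    (alpha/beta) propagator is the matrix exponential of the system
    matrix, evaluated in double precision.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    tau_m = p.tau_m
    if kernel == "exp":
        P = np.zeros((3, 3))
        P[0, 0] = np.exp(-dt / tau_m)
        P[1, 1] = np.exp(-dt / p.tau_s_e)
        P[2, 2] = np.exp(-dt / p.tau_s_i)
        P[0, 1] = _phi(p.tau_s_e, tau_m, dt) / p.C_m
        P[0, 2] = _phi(p.tau_s_i, tau_m, dt) / p.C_m
        fs_e = fs_i = 1.0
    elif kernel in ("alpha", "beta"):
        P = _expm(_system_matrix(p, kernel) * dt)
        P = np.triu(P)  # zero the ~1e-17 numerical noise below the diagonal
        tr_e = p.tau_r_e if (kernel == "beta" and p.tau_r_e) else p.tau_s_e
        tr_i = p.tau_r_i if (kernel == "beta" and p.tau_r_i) else p.tau_s_i
        fs_e = _kernel_peak_scale(p.tau_s_e, tr_e)
        fs_i = _kernel_peak_scale(p.tau_s_i, tr_i)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return Propagator(
        P=P,
        dt=dt,
        kernel=kernel,
        V_inf=p.E_L + p.I_ext / p.g_m,
        ref_steps=int(round(p.t_ref / dt)),
        forcing_scale_e=fs_e,
        forcing_scale_i=fs_i,
    )


@dataclass
class LifState:
    """Vectorized LIF state: membrane voltage, synaptic states, and the
    per-neuron refractory countdown (steps remaining clamped)."""

    V: np.ndarray
    I_e: np.ndarray
    I_i: np.ndarray
    Z_e: np.ndarray | None = None
    Z_i: np.ndarray | None = None
    ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ref is None:
            self.ref = np.zeros(self.V.shape, dtype=np.int32)

    @classmethod
    def zeros(cls, n: int, p: LifParams, kernel: str = "exp") -> "LifState":
        z = lambda: np.zeros(n, dtype=np.float32)
        s = cls(V=np.full(n, p.E_L, dtype=np.float32), I_e=z(), I_i=z())
        if kernel in ("alpha", "beta"):
            s.Z_e, s.Z_i = z(), z()
        return s


def step_exact(state: LifState, prop: Propagator, syn_e: np.ndarray,
               syn_i: np.ndarray, p: LifParams) -> np.ndarray:
    """Advance all neurons one step by the exact propagator.

    ``syn_e``/``syn_i`` are the summed weights (pA) arriving this step;
    they jump the kernel state after the linear update, so a spike first
    affects the membrane on the following step (grid-delay convention).
    Refractory neurons keep V clamped at V_reset while their synaptic
    states continue to evolve.  Returns the boolean spike mask.
    """
    if not np.all(np.isfinite(state.V)):
        raise FloatingPointError("non-finite membrane state")
    P = prop.P32
    V_inf = np.float32(prop.V_inf)
    in_ref = state.ref > 0
    if prop.kernel == "exp":
        V = P[0, 0] * (state.V - V_inf) + V_inf + P[0, 1] * state.I_e + P[0, 2] * state.I_i
        state.I_e = P[1, 1] * state.I_e + syn_e.astype(np.float32)
        state.I_i = P[2, 2] * state.I_i + syn_i.astype(np.float32)
    else:
        V = (P[0, 0] * (state.V - V_inf) + V_inf
             + P[0, 1] * state.I_e + P[0, 2] * state.Z_e
             + P[0, 3] * state.I_i + P[0, 4] * state.Z_i)
        I_e = P[1, 1] * state.I_e + P[1, 2] * state.Z_e
        I_i = P[3, 3] * state.I_i + P[3, 4] * state.Z_i
        state.Z_e = P[2, 2] * state.Z_e + np.float32(prop.forcing_scale_e) * syn_e.astype(np.float32)
        state.Z_i = P[4, 4] * state.Z_i + np.float32(prop.forcing_scale_i) * syn_i.astype(np.float32)
        state.I_e, state.I_i = I_e, I_i
    V = V.astype(np.float32)
    V[in_ref] = np.float32(p.V_reset)
    state.ref[in_ref] -= 1
    spikes = (~in_ref) & (V >= np.float32(p.V_th))
    V[spikes] = np.float32(p.V_reset)
    state.ref[spikes] = prop.ref_steps
    state.V = V
    return spikes


# ---------------------------------------------------------------------------
# nonlinear right-hand sides
# ---------------------------------------------------------------------------

def rhs_izhikevich(v, u, I, p: IzhikevichParams = IZHIKEVICH_TONIC):
    """Published quadratic model: dv = 0.04 v^2 + 5 v + 140 - u + I,
    du = a (b v - u)."""
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I
    du = p.a * (p.b * v - u)
    return dv, du


def rhs_adex(V, w, I, p: AdExParams = ADEX_DEFAULT):
    """Adaptive exponential integrate-and-fire subthreshold dynamics."""
    dV = (-p.g_L * (V - p.E_L)
          + p.g_L * p.Delta_T * np.exp((V - p.V_T) / p.Delta_T)
          - w + I) / p.C
    dw = (p.a * (V - p.E_L) - w) / p.tau_w
    return dV, dw


def coba_current(g_e, g_i, V, E_e: float = 0.0, E_i: float = -85.0):
    """Conductance-based synaptic current g_e (E_e - V) + g_i (E_i - V)."""
    return g_e * (E_e - V) + g_i * (E_i - V)


def make_rhs(model: str, p, I_ext: float = 0.0,
             E_e: float = 0.0, E_i: float = -85.0) -> Callable:
    """Right-hand side f(y) -> dy over stacked state rows, for the RK
    solvers.  Rows follow the model's state ordering.

    ``lif_cuba_exp``: [V, I_e, I_i]; ``lif_coba_exp``: [V, g_e, g_i]
    (conductances in nS, exponential decay); ``izhikevich``: [v, u];
    ``adex``: [V, w].
    """
    if model == "lif_cuba_exp":
        M = _system_matrix(p, "exp")
        b0 = (p.g_m * p.E_L + np.asarray(I_ext)) / p.C_m  # scalar or per neuron

        def f(y):
            d = np.tensordot(M, y, axes=(1, 0))
            d[0] = d[0] + b0
            return d
        return f
    if model == "lif_coba_exp":
        def f(y):
            V, ge, gi = y
            dV = (-p.g_m * (V - p.E_L) + coba_current(ge, gi, V, E_e, E_i) + I_ext) / p.C_m
            return np.stack([dV, -ge / p.tau_s_e, -gi / p.tau_s_i])
        return f
    if model == "izhikevich":
        def f(y):
            dv, du = rhs_izhikevich(y[0], y[1], I_ext, p)
            return np.stack([dv, du])
        return f
    if model == "adex":
        def f(y):
            dV, dw = rhs_adex(y[0], y[1], I_ext, p)
            return np.stack([dV, dw])
        return f
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Runge-Kutta
# ---------------------------------------------------------------------------

def step_rk(rhs: Callable, order: int, y: np.ndarray, dt: float) -> np.ndarray:
    """One classical Runge-Kutta step (no sub-stepping).

    order 1: forward Euler; order 2: modified Euler (midpoint);
    order 4: the standard 4-stage tableau.
    """
    if order == 1:
        return y + dt * rhs(y)
    if order == 2:
        k1 = rhs(y)
        return y + dt * rhs(y + 0.5 * dt * k1)
    if order == 4:
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    raise ValueError("order must be 1, 2 or 4")


# ---------------------------------------------------------------------------
# Parker-Sochacki
# ---------------------------------------------------------------------------

def _cauchy(a: list, b: list, j: int):
    """Coefficient j of the product of two power series."""
    return sum(a[m] * b[j - m] for m in range(j + 1))


def step_ps(model: str, q: int, y: np.ndarray, dt: float, p,
            I_ext: float = 0.0, E_e: float = 0.0, E_i: float = -85.0) -> np.ndarray:
    """One Parker-Sochacki step of order q (1 <= q <= 6).

    Builds the Maclaurin coefficients y_0..y_q of the exact solution by
    recurrences on the right-hand side (polynomial via Cauchy products;
    the AdEx exponential through an auxiliary series E = exp((V-V_T)/D)
    obeying E' = E V'/D) and evaluates y(dt) = sum_j y_j dt^j.  q = 1
    reduces to one forward-Euler step for every model.
    """
    if not 1 <= q <= 6:
        raise ValueError("Parker-Sochacki order must satisfy 1 <= q <= 6")
    if model == "lif_cuba_exp":
        M = _system_matrix(p, "exp")
        b0 = (p.g_m * p.E_L + np.asarray(I_ext)) / p.C_m  # scalar or per neuron
        coeffs = [y.astype(np.float64)]
        for j in range(q):
            d = np.tensordot(M, coeffs[j], axes=(1, 0))
            if j == 0:
                d[0] = d[0] + b0
            coeffs.append(d / (j + 1))
    elif model == "izhikevich":
        v = [np.asarray(y[0], dtype=np.float64)]
        u = [np.asarray(y[1], dtype=np.float64)]
        for j in range(q):
            dv = 0.04 * _cauchy(v, v, j) + 5.0 * v[j] - u[j]
            if j == 0:
                dv = dv + 140.0 + I_ext
            du = p.a * (p.b * v[j] - u[j])
            v.append(dv / (j + 1))
            u.append(du / (j + 1))
        coeffs = [np.stack([vj, uj]) for vj, uj in zip(v, u)]
    elif model == "adex":
        V = [np.asarray(y[0], dtype=np.float64)]
        w = [np.asarray(y[1], dtype=np.float64)]
        E = [np.exp((V[0] - p.V_T) / p.Delta_T)]
        for j in range(q):
            # the affine terms (E_L, I_ext) enter the order-0 coefficient only
            dV = (-p.g_L * (V[j] - (p.E_L if j == 0 else 0.0))
                  + p.g_L * p.Delta_T * E[j] - w[j]
                  + (I_ext if j == 0 else 0.0)) / p.C
            dw = (p.a * (V[j] - (p.E_L if j == 0 else 0.0)) - w[j]) / p.tau_w
            V.append(dV / (j + 1))
            w.append(dw / (j + 1))
            # E' = E V'/Delta_T; coefficient j of V' is (j+1) V_{j+1}
            dE = sum((m + 1) * V[m + 1] * E[j - m] for m in range(j + 1)) / p.Delta_T
            E.append(dE / (j + 1))
        coeffs = [np.stack([Vj, wj]) for Vj, wj in zip(V, w)]
    elif model == "lif_coba_exp":
        V = [np.asarray(y[0], dtype=np.float64)]
        ge = [np.asarray(y[1], dtype=np.float64)]
        gi = [np.asarray(y[2], dtype=np.float64)]
        for j in range(q):
            geV = _cauchy(ge, V, j)
            giV = _cauchy(gi, V, j)
            dV = (-p.g_m * (V[j] - (p.E_L if j == 0 else 0.0))
                  + (E_e * ge[j] - geV) + (E_i * gi[j] - giV)
                  + (I_ext if j == 0 else 0.0)) / p.C_m
            V.append(dV / (j + 1))
            ge.append(-ge[j] / p.tau_s_e / (j + 1))
            gi.append(-gi[j] / p.tau_s_i / (j + 1))
        coeffs = [np.stack([Vj, gej, gij]) for Vj, gej, gij in zip(V, ge, gi)]
    else:
        raise ValueError(f"unknown model {model!r}")
    # Horner evaluation of the truncated series at dt
    out = coeffs[q].astype(np.float64)
    for j in range(q - 1, -1, -1):
        out = coeffs[j] + dt * out
    return out
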