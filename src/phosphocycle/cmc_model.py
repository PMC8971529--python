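"""Covalent modification cycle (CMC) and phosphatase-feedback model.

A substrate transcription factor X (OmpR-VP64) is interconverted between
an unphosphorylated and a phosphorylated form (``X*``) by a kinase (total
``K_t``) and a phosphatase (total ``P_t``), following Goldbeter-Koshland
kinetics::

    dX*/dt = theta_k * (X_t - X*) * K_t / ((X_t - X*) + K_Mk)
             - theta_p * X* * P_t / (X* + K_Mp)

Phosphorylated X activates a Hill promoter phi(X*) that drives production
of the phosphatase itself (closed loop, CL)::

    dP_t/dt = alpha * (1 - w) * phi(X*) - gamma * P_t

with the measured output co-transcribed with the phosphatase, ``Y = rho *
P_t``.  ``w`` in [0, 1) is a disturbance: a fold reduction of the
production rate, modelling miRNA knockdown or transcriptional-resource
loading.  The module provides the CMC transfer curve (the steady-state
map ``h``), time courses, the closed-loop fixed point, and the relative
sensitivity of the output to the disturbance for open- and closed-loop
operation:

    S_OL = 1 / (1 - w)
    S_CL = S_OL / (1 + T),   T = (alpha/gamma) * (1 - w) * |d(phi o h)/dY|

In the quasi-integral regime (phosphatase saturated, K_Mp << X*; kinase
saturated, X_t >> K_Mk; promoter unsaturated) the output adapts almost
perfectly to w and settles near the setpoint rho * theta_k * K_t / theta_p.

All concentrations are in arbitrary consistent units; rates in inverse
time units of the same system.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "PromoterHill",
    "CMCParams",
    "SteadyState",
    "SensitivityResult",
    "DegenerateCycleWarning",
    "gk_transfer",
    "cmc_rate",
    "closedloop_rates",
    "simulate",
    "closedloop_steady_state",
    "closedloop_output",
    "quasi_integral_setpoint",
    "sensitivity_ol",
    "sensitivity_cl",
    "sensitivity_cl_fd",
]


class DegenerateCycleWarning(UserWarning):
    """Both enzymes absent: the cycle balance does not determine X*."""


def _check_finite_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")


@dataclass(frozen=True)
class PromoterHill:
    """Activating Hill promoter phi(X*) with cooperativity fixed at 2.

    phi(x) = basal + (1 - basal) * x^n / (K_D^n + x^n), strictly increasing,
    bounded in [basal, 1).  ``basal`` is the leaky activity fraction
    (default 0); ``K_D`` the half-activation concentration of X*.
    """

    K_D: float
    basal: float = 0.0
    n: float = 2.0

    def __post_init__(self) -> None:
        _check_finite_positive("K_D", self.K_D)
        if not 0.0 <= self.basal < 1.0:
            raise ValueError(f"basal must lie in [0, 1), got {self.basal!r}")
        if self.n != 2.0:
            raise ValueError("Hill cooperativity is fixed at 2")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        xn = x**2
        out = self.basal + (1.0 - self.basal) * xn / (self.K_D**2 + xn)
        return out if out.ndim else float(out)

    def derivative(self, x):
        """d phi / d x, analytic."""
        x = np.asarray(x, dtype=float)
        den = (self.K_D**2 + x**2) ** 2
        out = (1.0 - self.basal) * 2.0 * self.K_D**2 * x / den
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class CMCParams:
    """Rate constants, totals and promoter for the CMC/feedback model.

    theta_k, theta_p : catalytic rate constants of kinase and phosphatase
        (1/time per enzyme unit).
    K_Mk, K_Mp : Michaelis constants of the two enzymes (concentration).
    X_t : total substrate TF (concentration).
    K_t : total kinase (concentration, >= 0).
    alpha : lumped production rate of the phosphatase/output transcript at
        full promoter activity (concentration/time).
    gamma : protein decay rate constant (1/time).
    rho : output-to-phosphatase stoichiometric ratio (Y = rho * P_t).
    w : disturbance, fold reduction of production, in [0, 1).
    phi : the promoter Hill function.
    """

    theta_k: float
    theta_p: float
    K_Mk: float
    K_Mp: float
    X_t: float
    K_t: float
    alpha: float
    gamma: float
    phi: PromoterHill
    rho: float = 1.0
    w: float = 0.0

    def __post_init__(self) -> None:
        for name in ("theta_k", "theta_p", "K_Mk", "K_Mp", "X_t", "alpha", "gamma", "rho"):
            _check_finite_positive(name, getattr(self, name))
        if not (math.isfinite(self.K_t) and self.K_t >= 0):
            raise ValueError(f"K_t must be finite and >= 0, got {self.K_t!r}")
        if not 0.0 <= self.w < 1.0:
            raise ValueError(f"w must lie in [0, 1), got {self.w!r}")

    def with_(self, **kwargs) -> "CMCParams":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SteadyState:
    X_star: float
    P_t: float
    Y: float


@dataclass(frozen=True)
class SensitivityResult:
    S_CL: float
    S_OL: float
    T_gain: float
    w: float


# ---------------------------------------------------------------------------
# CMC transfer curve (Goldbeter-Koshland steady state)
# ---------------------------------------------------------------------------

def _gk_quadratic(theta_k, theta_p, K_Mk, K_Mp, X_t, K_t, P_t):
    """Vectorised physical root of the GK balance; no validation.

    Cross-multiplying the balance a*(X_t-X)/((X_t-X)+K_Mk) =
    b*X/(X+K_Mp), with a = theta_k*K_t and b = theta_p*P_t, gives

        A X^2 + B X + C = 0,
        A = b - a,  B = a*(X_t - K_Mp) - b*(X_t + K_Mk),  C = a*K_Mp*X_t.

    f(0) = C >= 0 and f(X_t) = -b*K_Mk*X_t <= 0, so when both enzymes are
    present exactly one root lies in [0, X_t].
    """
    a = theta_k * np.asarray(K_t, dtype=float)
    b = theta_p * np.asarray(P_t, dtype=float)
    a, b = np.broadcast_arrays(a, b)
    A = b - a
    B = a * (X_t - K_Mp) - b * (X_t + K_Mk)
    C = a * K_Mp * X_t

    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.maximum(B * B - 4.0 * A * C, 0.0)
        # numerically stable pair of roots
        q = -0.5 * (B + np.sign(B) * np.sqrt(disc))
        r1 = np.where(A != 0.0, q / np.where(A != 0.0, A, 1.0), np.inf)
        r2 = np.where(q != 0.0, C / np.where(q != 0.0, q, 1.0), 0.0)
        lin = np.where(B != 0.0, -C / np.where(B != 0.0, B, 1.0), 0.0)

    tol = 1e-9 * X_t
    in1 = (r1 >= -tol) & (r1 <= X_t + tol)
    in2 = (r2 >= -tol) & (r2 <= X_t + tol)
    # prefer a root inside the physical interval; fall back to the linear
    # solution when the quadratic degenerates (a == b)
    near_linear = np.abs(A) <= 1e-14 * np.maximum(np.abs(a) + np.abs(b), 1.0)
    root = np.where(in1, r1, np.where(in2, r2, lin))
    root = np.where(near_linear, lin, root)
    # degenerate corners
    root = np.where((a == 0.0) & (b > 0.0), 0.0, root)
    root = np.where((b == 0.0) & (a > 0.0), X_t, root)
    root = np.where((a == 0.0) & (b == 0.0), 0.0, root)
    return np.clip(root, 0.0, X_t)


def gk_transfer(params: CMCParams, K_t: float | None = None, P_t: float | None = None):
    """Steady-state phosphorylated substrate X* of the CMC (transfer curve h).

    Returns the unique root of the Goldbeter-Koshland balance in
    [0, X_t], from the closed-form quadratic with a bisection fallback
    when root selection is numerically marginal.  ``K_t`` and ``P_t``
    override the values in ``params`` and may be arrays (broadcast).

    With no kinase (K_t = 0) the phosphatase drains the cycle, X* = 0;
    with no phosphatase, phosphorylation is irreversible, X* = X_t.  With
    both absent the balance is undetermined and the convention X* = 0 is
    returned with a :class:`DegenerateCycleWarning`.
    """
    K_t = params.K_t if K_t is None else K_t
    if P_t is None:
        raise TypeError("gk_transfer requires an explicit phosphatase level P_t")
    K_arr = np.asarray(K_t, dtype=float)
    P_arr = np.asarray(P_t, dtype=float)
    if not (np.all(np.isfinite(K_arr)) and np.all(np.isfinite(P_arr))):
        raise ValueError("K_t and P_t must be finite")
    if np.any(K_arr < 0) or np.any(P_arr < 0):
        raise ValueError("K_t and P_t must be non-negative")
    if np.any((K_arr == 0) & (P_arr == 0)):
        warnings.warn(
            "K_t = P_t = 0: cycle balance undetermined, returning X* = 0",
            DegenerateCycleWarning,
            stacklevel=2,
        )

    root = _gk_quadratic(
        params.theta_k, params.theta_p, params.K_Mk, params.K_Mp,
        params.X_t, K_arr, P_arr,
    )

    if root.ndim == 0:
        x = float(root)
        k, p = float(K_arr), float(P_arr)
        if k > 0 and p > 0:
            # polish / rescue via bracketed root-finding on the rate itself
            f = lambda xx: cmc_rate(xx, params, p, K_t=k)
            lo, hi = 0.0, params.X_t
            if f(lo) > 0 > f(hi):  # guaranteed by the balance structure
                residual = abs(f(x))
                scale = params.theta_k * k + params.theta_p * p
                if residual > 1e-10 * scale * params.X_t:
                    x = brentq(f, lo, hi, xtol=1e-14 * params.X_t, rtol=8.9e-16)
        return x
    return root


def cmc_rate(X_star, params: CMCParams, P_t, K_t: float | None = None):
    """Net phosphorylation rate dX*/dt of the cycle at state X*."""
    K_t = params.K_t if K_t is None else K_t
    x = np.asarray(X_star, dtype=float)
    if np.any(x < -1e-12 * params.X_t) or np.any(x > params.X_t * (1 + 1e-12)):
        raise ValueError("X_star outside [0, X_t]")
    x = np.clip(x, 0.0, params.X_t)
    kin = params.theta_k * (params.X_t - x) * K_t / ((params.X_t - x) + params.K_Mk)
    dep = params.theta_p * x * np.asarray(P_t, dtype=float) / (x + params.K_Mp)
    out = kin - dep
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Closed-loop dynamics
# ---------------------------------------------------------------------------

def closedloop_rates(state, params: CMCParams):
    """(dX*/dt, dP_t/dt) for the feedback interconnection.

    ``state`` is (X_star, P_t).  Production of P_t is alpha*(1-w)*phi(X*)
    minus first-order decay gamma*P_t; the output is tracked as
    Y = rho * P_t.
    """
    X_star, P_t = state
    dX = cmc_rate(X_star, params, P_t)
    dP = params.alpha * (1.0 - params.w) * params.phi(X_star) - params.gamma * P_t
    return dX, dP


def simulate(
    params: CMCParams,
    init,
    t_grid,
    hold_phosphatase: bool = False,
):
    """Integrate the model over ``t_grid``; returns arrays (t, X_star, P_t, Y).

    ``init`` is (X_star0, P_t0).  With ``hold_phosphatase`` the open-loop
    variant is integrated: P_t stays at its initial value and only the
    cycle relaxes.  Uses a stiff-capable integrator (zero-order regimes
    make the cycle stiff), rtol 1e-8.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    x0, p0 = float(init[0]), float(init[1])
    if not (0.0 <= x0 <= params.X_t and p0 >= 0.0):
        raise ValueError("initial state violates 0 <= X* <= X_t, P_t >= 0")

    if hold_phosphatase:
        def rhs(_t, y):
            return [cmc_rate(min(max(y[0], 0.0), params.X_t), params, p0), 0.0]
    else:
        def rhs(_t, y):
            x = min(max(y[0], 0.0), params.X_t)
            dx, dp = closedloop_rates((x, max(y[1], 0.0)), params)
            return [dx, dp]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [x0, p0],
        method="LSODA",
        t_eval=t_grid,
        rtol=1e-8,
        atol=1e-10 * max(params.X_t, params.alpha / params.gamma, 1.0),
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    X = np.clip(sol.y[0], 0.0, params.X_t)
    P = np.maximum(sol.y[1], 0.0)
    return sol.t, X, P, params.rho * P


def closedloop_steady_state(params: CMCParams) -> SteadyState:
    """Unique fixed point of the feedback loop.

    Production alpha*(1-w)*phi(h(P_t)) is non-increasing in P_t (phi' > 0,
    h' < 0) while removal gamma*P_t increases, so the fixed point is unique
    and bracketed in P_t within [0, alpha*(1-w)/gamma].
    """
    prod_max = params.alpha * (1.0 - params.w) / params.gamma

    def g(P):
        x = gk_transfer(params, params.K_t, P) if P > 0 else (
            params.X_t if params.K_t > 0 else 0.0
        )
        return params.alpha * (1.0 - params.w) * params.phi(x) - params.gamma * P

    g0 = g(0.0)
    if g0 <= 0.0:
        # no production at zero phosphatase: dark fixed point
        x0 = 0.0 if params.K_t == 0 else params.X_t
        return SteadyState(X_star=x0 if g0 < 0 else 0.0, P_t=0.0, Y=0.0)
    hi = prod_max * (1.0 + 1e-9)
    if g(hi) > 0.0:
        raise RuntimeError(
            f"steady-state bracket failure on P_t in [0, {hi!r}]: g(hi) > 0"
        )
    P = brentq(g, 0.0, hi, xtol=1e-15 * max(hi, 1.0), rtol=8.9e-16, maxiter=200)
    X = gk_transfer(params, params.K_t, P) if P > 0 else (
        params.X_t if params.K_t > 0 else 0.0
    )
    return SteadyState(X_star=X, P_t=P, Y=params.rho * P)


def closedloop_output(params: CMCParams, K_t, alpha, w=0.0):
    """Vectorised closed-loop output Y for per-cell parameter arrays.

    Solves the fixed point by monotone bisection simultaneously for arrays
    of kinase totals ``K_t``, production rates ``alpha`` and disturbances
    ``w`` (broadcast); used by the synthetic-data generator where one
    solve per cell would dominate runtime.
    """
    K_t = np.asarray(K_t, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    w = np.asarray(w, dtype=float)
    K_t, alpha, w = np.broadcast_arrays(K_t, alpha, w)
    scale = alpha * (1.0 - w) / params.gamma

    def g(P):
        x = _gk_quadratic(
            params.theta_k, params.theta_p, params.K_Mk, params.K_Mp,
            params.X_t, K_t, np.maximum(P, 0.0),
        )
        # P == 0 with kinase present gives X* = X_t (quadratic handles it)
        return alpha * (1.0 - w) * params.phi(x) - params.gamma * P

    lo = np.zeros_like(scale)
    hi = scale * (1.0 + 1e-9) + 1e-300
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        pos = g(mid) > 0.0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    P = 0.5 * (lo + hi)
    P = np.where(K_t == 0.0, np.where(params.phi.basal > 0, P, 0.0), P)
    return params.rho * P


def quasi_integral_setpoint(params: CMCParams) -> float:
    """Output setpoint rho*theta_k*K_t/theta_p of the quasi-integral limit.

    In the saturated-enzyme regime (K_Mp << X*, X_t >> K_Mk) the cycle
    approximates dX*/dt = theta_k*K_t - theta_p*Y/rho, whose balance is
    independent of alpha, gamma and the disturbance w.
    """
    return params.rho * params.theta_k * params.K_t / params.theta_p


# ---------------------------------------------------------------------------
# Sensitivity to disturbance
# ---------------------------------------------------------------------------

def sensitivity_ol(w: float) -> float:
    """Open-loop relative sensitivity S_OL = 1/(1-w)."""
    if not 0.0 <= w < 1.0:
        raise ValueError(f"w must lie in [0, 1), got {w!r}")
    return 1.0 / (1.0 - w)


def _transfer_derivative(params: CMCParams, X_star: float, P_t: float) -> float:
    """dX*/dP_t of the transfer curve h by the implicit function theorem.

    With F(X, P) the GK net rate, h'(P) = -F_P / F_X evaluated at the
    balance; F_X < 0 and F_P < 0, so h' < 0.
    """
    x, p = X_star, P_t
    F_X = (
        -params.theta_k * params.K_t * params.K_Mk
        / ((params.X_t - x) + params.K_Mk) ** 2
        - params.theta_p * p * params.K_Mp / (x + params.K_Mp) ** 2
    )
    F_P = -params.theta_p * x / (x + params.K_Mp)
    return -F_P / F_X


def sensitivity_cl(params: CMCParams) -> SensitivityResult:
    """Closed-loop relative sensitivity (1/Y)|dY/dw| at the fixed point.

    Evaluated analytically: S_CL = S_OL / (1 + T) with loop gain
    T = (alpha/gamma)*(1-w)*|phi'(X*) * h'(P_t)|, where phi' is analytic
    and h' = dX*/dP_t comes from implicit differentiation of the cycle
    balance.  Written against the output Y = rho*P_t this is
    (alpha_Y/gamma)*(1-w)*|d(phi o h)/dY| with alpha_Y = rho*alpha the
    output production rate: the rho from the chain rule cancels, so the
    gain is independent of the stoichiometric ratio.  When the promoter
    is saturated (phi' -> 0) the loop gain vanishes and S_CL -> S_OL.
    """
    ss = closedloop_steady_state(params)
    s_ol = sensitivity_ol(params.w)
    if ss.P_t == 0.0:
        return SensitivityResult(S_CL=s_ol, S_OL=s_ol, T_gain=0.0, w=params.w)
    hprime = _transfer_derivative(params, ss.X_star, ss.P_t)  # dX*/dP_t < 0
    T = (params.alpha / params.gamma) * (1.0 - params.w) * abs(
        params.phi.derivative(ss.X_star) * hprime
    )
    return SensitivityResult(S_CL=s_ol / (1.0 + T), S_OL=s_ol, T_gain=T, w=params.w)


def sensitivity_cl_fd(params: CMCParams, dw: float = 1e-4) -> float:
    """Finite-difference oracle for S_CL: (1/Y)|dY/dw| by central differences.

    Two extra closed-loop solves at w +/- dw; the step balances truncation
    against cancellation given the tight fixed-point tolerance.
    """
    w = params.w
    lo, hi = max(w - dw, 0.0), min(w + dw, 1.0 - 1e-12)
    Y0 = closedloop_steady_state(params).Y
    Ylo = closedloop_steady_state(params.with_(w=lo)).Y
    Yhi = closedloop_steady_state(params.with_(w=hi)).Y
    if Y0 == 0.0:
        return sensitivity_ol(w)
    return abs(Yhi - Ylo) / (hi - lo) / Y0
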