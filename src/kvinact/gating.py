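"""Hodgkin–Huxley gating with an Erlang-chain N-type inactivation gate.

Open probability is modelled as ``P_open(t) = m(t)^p · h(t)`` where the
activation gate ``m`` obeys first-order relaxation toward a Boltzmann
steady state ``m_inf(V)`` and the inactivation gate ``h`` is the survival
function of a k-stage "ball docking" chain: the N-terminal inactivation
ball reaches its pore-blocking pose after k sequential steps, each at rate
λ, giving an Erlang(k, λ) latency.  A non-inactivating fraction ``f_ss``
models incomplete steady-state inactivation:

    h(t) = f_ss + (1 − f_ss) · P[Erlang(k, λ) > t]
         = f_ss + (1 − f_ss) · e^{−λt} Σ_{j=0}^{k−1} (λt)^j / j!

The mean docking latency of the Erlang component is k/λ and its CV is
1/√k, so longer chains at fixed mean delay give a sharper (more
deterministic) inactivation onset.

Units: ms, mV, nS; rates in 1/ms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants, special
from scipy.integrate import solve_ivp
from scipy.stats import poisson

from .errors import DomainError, ValidationError

__all__ = [
    "nernst_reversal",
    "inactivation_survival",
    "chain_survival_ode",
    "GatingModel",
    "ErlangChainState",
    "simulate_open_probability",
    "E_K_DEFAULT",
]


def nernst_reversal(k_out: float, k_in: float, temperature: float = 25.0) -> float:
    """Potassium Nernst reversal potential in mV.

    Parameters
    ----------
    k_out, k_in : float
        Extracellular / intracellular K⁺ concentrations (mM). Must be > 0.
    temperature : float
        Temperature in °C (default 25).

    Returns ``(R·T/F)·ln(k_out/k_in)`` in mV; the result is invariant to
    scaling both concentrations by the same factor.
    """
    if k_out <= 0 or k_in <= 0:
        raise DomainError(f"concentrations must be positive, got K_out={k_out}, K_in={k_in}")
    t_kelvin = temperature + 273.15
    if t_kelvin <= 0:
        raise DomainError(f"temperature below absolute zero: {temperature} °C")
    return 1e3 * constants.R * t_kelvin / constants.physical_constants["Faraday constant"][0] * math.log(
        k_out / k_in
    )


# Default E_K from the standard automated-patch solutions: 4 mM K⁺ outside,
# 110 mM inside (50 KCl + 60 K-fluoride), 25 °C  →  ≈ −85.15 mV.
E_K_DEFAULT: float = nernst_reversal(4.0, 110.0, 25.0)


def _validate_chain(k: int, lam: float, f_ss: float) -> None:
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise DomainError(f"chain length k must be an integer >= 1, got {k!r}")
    if not lam > 0:
        raise DomainError(f"chain rate lambda must be > 0, got {lam}")
    if not 0.0 <= f_ss <= 1.0:
        raise DomainError(f"f_ss must lie in [0, 1], got {f_ss}")


def inactivation_survival(t, k: int, lam: float, f_ss: float = 0.0):
    """Closed-form inactivation survival h(t) of the Erlang docking chain.

    ``h(t) = f_ss + (1−f_ss)·Q(k, λt)`` where Q is the regularized upper
    incomplete gamma function (equal to the truncated Poisson sum for
    integer k).  Monotone non-increasing, h(0) = 1, h(∞) = f_ss.
    """
    _validate_chain(k, lam, f_ss)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("t must be >= 0")
    h = f_ss + (1.0 - f_ss) * special.gammaincc(k, lam * t_arr)
    return float(h) if np.isscalar(t) or t_arr.ndim == 0 else h


def chain_survival_ode(
    t_grid: np.ndarray,
    k: int,
    lam: float,
    f_ss: float = 0.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Survival from direct ODE integration of the k-state docking chain.

    Independent numerical route used to cross-check the closed form:
    occupancy p_j of chain state j obeys ``dp_0/dt = −λp_0``,
    ``dp_j/dt = λ(p_{j−1} − p_j)``; survival is Σ_{j<k} p_j.
    """
    _validate_chain(k, lam, f_ss)
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(_t, p):
        dp = np.empty_like(p)
        dp[0] = -lam * p[0]
        dp[1:] = lam * (p[:-1] - p[1:])
        return dp

    p0 = np.zeros(k)
    p0[0] = 1.0
    sol = solve_ivp(
        rhs,
        (float(t_grid[0]), float(t_grid[-1])),
        p0,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        method="LSODA",
    )
    if not sol.success:  # pragma: no cover - LSODA on a linear chain
        raise RuntimeError(f"chain ODE integration failed: {sol.message}")
    return f_ss + (1.0 - f_ss) * sol.y.sum(axis=0)


@dataclass(frozen=True)
class GatingModel:
    """Parameters of one channel sub-population (glycoform).

    Attributes
    ----------
    g_max : float
        Maximal conductance, nS.
    p : int
        Activation-gate exponent (classic delayed-rectifier value 4).
    v_half, slope : float
        Boltzmann midpoint and steepness (mV) of ``m_inf``.
    tau_m : float
        Activation time constant, ms.
    k : int
        Inactivation chain length (number of docking steps).
    lam : float
        Per-step docking rate, 1/ms; mean inactivation latency = k/λ.
    f_ss : float
        Non-inactivating steady-state fraction in [0, 1].
    e_k : float
        K⁺ reversal potential, mV.
    """

    g_max: float
    p: int = 4
    v_half: float = 0.0
    slope: float = 9.0
    tau_m: float = 2.0
    k: int = 1
    lam: float = 0.1
    f_ss: float = 0.0
    e_k: float = E_K_DEFAULT

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValidationError(f"g_max must be >= 0, got {self.g_max}")
        if not (isinstance(self.p, (int, np.integer)) and self.p >= 1):
            raise ValidationError(f"activation exponent p must be an integer >= 1, got {self.p!r}")
        if self.slope == 0:
            raise ValidationError("slope must be non-zero")
        if self.tau_m <= 0:
            raise ValidationError(f"tau_m must be > 0, got {self.tau_m}")
        try:
            _validate_chain(self.k, self.lam, self.f_ss)
        except DomainError as exc:
            raise ValidationError(str(exc)) from None

    def m_inf(self, v) -> np.ndarray | float:
        """Steady-state activation, Boltzmann in V (strictly increasing for slope > 0)."""
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - self.v_half) / self.slope))

    def survival(self, t):
        """Inactivation survival h(t) with the chain engaged from t = 0."""
        return inactivation_survival(t, self.k, self.lam, self.f_ss)

    @property
    def mean_latency(self) -> float:
        """Mean Erlang docking latency k/λ, ms."""
        return self.k / self.lam

    @property
    def latency_variance(self) -> float:
        """Variance of the Erlang docking latency k/λ², ms²."""
        return self.k / self.lam**2


class ErlangChainState:
    """Occupancy of the docking chain, propagated analytically segment-wise.

    At constant rate the chain is a pure-birth process, so over a segment of
    duration T each state advances by a Poisson(λT) number of steps.  This
    lets a sweep with several voltage segments be simulated exactly without
    time-stepping: within an engaged segment the survival profile is a
    mixture of Erlang tails from the current occupancy.
    """

    def __init__(self, k: int, lam: float, f_ss: float = 0.0) -> None:
        _validate_chain(k, lam, f_ss)
        self.k = int(k)
        self.lam = float(lam)
        self.f_ss = float(f_ss)
        self._p = np.zeros(self.k)
        self._p[0] = 1.0  # mass in surviving (un-docked) states

    @property
    def survival_now(self) -> float:
        return self.f_ss + (1.0 - self.f_ss) * float(self._p.sum())

    def survival_profile(self, t_rel: np.ndarray) -> np.ndarray:
        """h over relative times within an engaged (chain running) segment."""
        t_rel = np.asarray(t_rel, dtype=float)
        s = np.zeros_like(t_rel)
        for j in range(self.k):
            if self._p[j] > 0.0:
                s += self._p[j] * special.gammaincc(self.k - j, self.lam * t_rel)
        return self.f_ss + (1.0 - self.f_ss) * s

    def advance(self, duration: float) -> None:
        """Propagate occupancy through an engaged segment of given duration."""
        if duration <= 0:
            return
        steps = poisson.pmf(np.arange(self.k), self.lam * duration)
        self._p = np.convolve(self._p, steps)[: self.k]


def simulate_open_probability(
    model: GatingModel,
    v: float,
    duration: float,
    dt: float,
    m0: float | None = None,
    holding_potential: float = -90.0,
    on_unstable: str = "warn",
) -> tuple[np.ndarray, np.ndarray]:
    """Open probability P_open(t) = m(t)^p · h(t) during a constant-V step.

    ``m`` relaxes exponentially from ``m0`` (default: steady state at the
    holding potential) toward ``m_inf(V)`` with time constant τ_m, solved
    exactly; ``h`` is the closed-form chain survival with the chain engaged
    at t = 0.  Returns ``(t, P_open)`` with t from 0 to ``duration``
    inclusive in steps of ``dt``.

    A step size coarse relative to the gating time scales (dt > τ_m/2 or
    dt > 1/(2λ)) under-resolves the kinetics; per ``on_unstable`` this
    warns (default), raises, or is ignored.
    """
    if dt <= 0 or dt > duration:
        raise ValidationError(f"dt must satisfy 0 < dt <= duration, got dt={dt}, duration={duration}")
    if dt > model.tau_m / 2 or dt > 1.0 / (2.0 * model.lam):
        msg = (
            f"dt={dt} ms under-resolves gating (tau_m={model.tau_m} ms, "
            f"1/lambda={1.0 / model.lam:.3g} ms)"
        )
        if on_unstable == "error":
            raise ValidationError(msg)
        if on_unstable == "warn":
            warnings.warn(msg, stacklevel=2)
        elif on_unstable != "ignore":
            raise ValidationError(f"on_unstable must be 'warn', 'error' or 'ignore', got {on_unstable!r}")
    t = np.arange(int(round(duration / dt)) + 1) * dt
    minf = float(model.m_inf(v))
    if m0 is None:
        m0 = float(model.m_inf(holding_potential))
    m = minf + (m0 - minf) * np.exp(-t / model.tau_m)
    h = inactivation_survival(t, model.k, model.lam, model.f_ss)
    return t, m**model.p * h
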