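"""Untreated Gompertz dynamics and the numerical oracle.

The Gompertz law (GL) describes sigmoid tumor growth through the
specific growth rate

    (1/N) dN/dt = a - k ln(N / N0) = k ln(Ninf / N),

with exponential-growth rate ``a`` (day^-1), limiting-factor rate ``k``
(day^-1), initial size ``N0`` and carrying capacity
``Ninf = N0 exp(a/k)``.  All dynamics in this package are handled in
log-size space ``u = ln N``, where the GL is a linear ODE: instantaneous
radiation kills become subtractions on ``u``, positivity is automatic,
and every therapy closed form follows by superposition.

:func:`integrate_growth` is the adaptive numerical integrator that
serves as the independent oracle for every closed form in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .trajectory import TumorTrajectory

__all__ = ["GompertzParams", "K_EPS", "specific_rate", "gompertz_log_size",
           "gompertz_size", "integrate_growth"]

#: Below this |k| (day^-1) the a/k closed form degenerates (0/0) and the
#: exponential-growth limit N0*exp(a*t) is used instead.
K_EPS = 1e-9


@dataclass(frozen=True)
class GompertzParams:
    """The (a, k, N0) triple defining Gompertz dynamics.

    For untreated growth ``a > 0`` and ``k > 0``; *effective* (fitted)
    parameters may carry either sign.  ``N0`` is the size at the time
    origin of the dynamics (t = 0, or the phase start when used as an
    anchor).
    """

    a: float
    k: float
    N0: float
    unit_label: str = "mm^3"

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or not np.isfinite(self.k):
            raise ValueError("a and k must be finite")
        if not (np.isfinite(self.N0) and self.N0 > 0):
            raise ValueError(f"N0 must be positive and finite, got {self.N0}")

    @property
    def carrying_capacity(self) -> float:
        """Ninf = N0 * exp(a/k); +inf in the exponential limit k -> 0 with a > 0."""
        if abs(self.k) < K_EPS:
            if self.a > 0:
                return np.inf
            return self.N0 if self.a == 0 else 0.0
        return self.N0 * np.exp(self.a / self.k)

    @property
    def log_carrying_capacity(self) -> float:
        if abs(self.k) < K_EPS:
            return np.inf if self.a > 0 else (np.log(self.N0) if self.a == 0 else -np.inf)
        return np.log(self.N0) + self.a / self.k


#: Additive perturbation of the specific rate, day^-1 (0 for untreated).
SpecificRatePerturbation = Callable[[float], float]


def specific_rate(params: GompertzParams, N):
    """Gompertz specific growth rate a - k ln(N/N0) at size ``N`` (day^-1).

    Vanishes at the carrying capacity; negative beyond it.  Accepts a
    scalar or array of positive sizes.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0) or not np.all(np.isfinite(N)):
        raise ValueError("size N must be positive and finite")
    out = params.a - params.k * np.log(N / params.N0)
    return float(out) if out.ndim == 0 else out


def gompertz_log_size(params: GompertzParams, t):
    """ln N(t) of the untreated closed form, with the k -> 0 limit handled.

    u(t) = ln N0 + (a/k)(1 - e^{-k t})  for |k| >= K_EPS,
    u(t) = ln N0 + a t                  otherwise.
    """
    t = np.asarray(t, dtype=float)
    u0 = np.log(params.N0)
    if abs(params.k) < K_EPS:
        u = u0 + params.a * t
    else:
        u = u0 + (params.a / params.k) * (1.0 - np.exp(-params.k * t))
    return float(u) if u.ndim == 0 else u


def gompertz_size(params: GompertzParams, t):
    """Closed-form untreated Gompertz size N(t) at time ``t`` (days, >= 0 typical).

    Saturates at the carrying capacity N0*exp(a/k) for a, k > 0.
    """
    u = gompertz_log_size(params, t)
    return np.exp(u)


def integrate_growth(
    params: GompertzParams,
    perturbation: SpecificRatePerturbation | None,
    kill_events: Sequence[tuple[float, float]] | None,
    t_grid: Sequence[float],
    rtol: float = 1e-11,
    atol: float = 1e-12,
) -> TumorTrajectory:
    """Adaptive numerical integration of the perturbed GL with kill events.

    Integrates ``du/dt = a - k (u - ln N0) + perturbation(t)`` between
    events; at each kill event ``(time, log_kill)`` the supplied
    log-kill is subtracted from ``u`` instantaneously.  The reported
    value AT an event time is post-kill (right-continuous), matching
    the surviving-fraction convention N_t+ = N_t- e^{-D}.

    This is the oracle every closed form in the package is checked
    against; relative accuracy against known closed forms is ~1e-9.

    Parameters
    ----------
    perturbation : callable or None
        Additive term on the specific rate, day^-1; None means untreated.
    kill_events : sequence of (time, log_kill) or None
        Instantaneous log-kills; times must lie within the grid span.
        Events sharing a time compose additively in log space.
    t_grid : array-like
        Strictly increasing evaluation times (days).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a 1-D array with at least one time")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    events = sorted((float(t), float(d)) for t, d in (kill_events or []))
    t0, t_end = t_grid[0], t_grid[-1]
    if events and (events[0][0] < t0 or events[-1][0] > t_end):
        raise ValueError("kill event times must lie within the grid span")

    pert = perturbation or (lambda t: 0.0)
    u0_log = np.log(params.N0)

    def rhs(t, u):
        p = pert(t)
        if not np.isfinite(p):
            raise ValueError(f"perturbation is non-finite at t={t}")
        return [params.a - params.k * (u[0] - u0_log) + p]

    # Segment boundaries: grid start, each distinct event time, grid end.
    event_times = sorted({t for t, _ in events if t > t0})
    boundaries = [t0] + [t for t in event_times if t < t_end] + [t_end]

    u_out = np.empty_like(t_grid)
    u = u0_log
    # kills exactly at the start apply immediately (post-kill convention)
    u -= sum(d for t, d in events if t == t0)
    if t_grid[0] == t0:
        u_out[0] = u

    segments = [] if t_end == t0 else list(zip(boundaries[:-1], boundaries[1:]))
    for left, right in segments:
        mask = (t_grid > left) & (t_grid < right)
        sol = solve_ivp(
            rhs, (left, right), [u], method="RK45", rtol=rtol, atol=atol,
            dense_output=True,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"integration failed on [{left}, {right}]: {sol.message}")
        if mask.any():
            u_out[mask] = sol.sol(t_grid[mask])[0]
        u = sol.y[0, -1]
        u -= sum(d for t, d in events if t == right)
        at_right = t_grid == right
        if at_right.any():
            u_out[at_right] = u

    return TumorTrajectory(
        times=t_grid, sizes=np.exp(u_out), subject_id="model", arm="model",
        unit_label=params.unit_label,
    )
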