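"""Therapy-perturbed Gompertz dynamics.

Covers the four ways treatment enters the growth law:

* **Immunotherapy (IT)** — an additive term ``-gamma * I(t)`` on the
  specific rate, with a constant or exponentially decaying drug/immune
  level ``I(t)``.  A positive ``gamma`` is antagonist (suppresses
  growth); a negative ``gamma`` is agonist (accelerates it).  For a
  constant profile the effect is a shifted carrying capacity
  ``Ninf_eff = Ninf * exp(-gamma I0 / k)``.

* **Radiotherapy (RT)** — instantaneous per-fraction kills from the
  linear-quadratic model, surviving fraction ``exp(-(alpha d + beta d^2))``.

* **Multi-fraction courses** — because the log-size dynamics are linear,
  a whole RT+IT course has a closed form: the untreated growth term
  minus two exponentially discounted therapy terms, the cumulative IT
  log-effect ``W_bar`` and the cumulative RT log-effect ``D_nf``.  The
  closed form is pinned (and tested) against recursive kill-and-regrow
  simulation; see docs/methods.md for the reconstruction argument.

* **RT-triggered synergy (abscopal effect)** — an unirradiated
  metastatic lesion regresses through an immune response triggered by
  fractions delivered to the primary tumor, modeled as per-fraction
  pulses ``Y0 * exp(-(t - t_i - lag)/tau)`` on the specific rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .growth import (
    K_EPS,
    GompertzParams,
    gompertz_log_size,
    gompertz_size,
)
from .trajectory import TumorTrajectory

__all__ = [
    "ImmunotherapyProfile",
    "RadiationSchedule",
    "SynergyParams",
    "TherapyCourse",
    "CombinedLogEffect",
    "RegressionAssessment",
    "lqm_survival",
    "lqm_log_kill",
    "it_trajectory",
    "combined_log_effect",
    "course_log_size",
    "regression_condition",
    "abscopal_trajectory",
]


@dataclass(frozen=True)
class ImmunotherapyProfile:
    """Immunotherapy drug/immune level and its coupling to the growth rate.

    ``gamma`` (day^-1 per I-unit) multiplies the level I(t); its sign
    carries the agonist (< 0) / antagonist (> 0) meaning.  ``rho``
    (day^-1) is the exponential decay rate of the level; ``rho = 0``
    means a constant profile.
    """

    gamma: float
    I0: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.I0 < 0:
            raise ValueError("I0 must be non-negative")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")

    @property
    def mode(self) -> str:
        return "constant" if self.rho == 0 else "exponential"

    def level(self, t):
        """I(t) = I0 (constant) or I0 * exp(-rho t), t measured from therapy start."""
        t = np.asarray(t, dtype=float)
        out = self.I0 * np.exp(-self.rho * t) if self.rho > 0 else self.I0 * np.ones_like(t)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RadiationSchedule:
    """Fraction times (days), per-fraction doses (Gy) and LQ sensitivities.

    The linear-quadratic surviving fraction after dose d is
    exp(-(alpha d + beta d^2)); radiobiology convention puts
    beta ~= alpha/10, which is a guideline, not enforced.  Fraction
    times must be non-decreasing; fractions sharing a time compose
    multiplicatively (their log-kills add).
    """

    fraction_times: tuple
    doses: tuple
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        ft = tuple(float(t) for t in self.fraction_times)
        ds = tuple(float(d) for d in self.doses)
        if len(ft) != len(ds):
            raise ValueError("fraction_times and doses must have equal length")
        if any(np.diff(ft) < 0):
            raise ValueError("fraction_times must be non-decreasing")
        if any(d < 0 for d in ds):
            raise ValueError("doses must be non-negative")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        object.__setattr__(self, "fraction_times", ft)
        object.__setattr__(self, "doses", ds)

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_times)

    @property
    def log_kills(self) -> np.ndarray:
        """Per-fraction log-kills alpha*d + beta*d^2 (>= 0)."""
        d = np.asarray(self.doses, dtype=float)
        return self.alpha * d + self.beta * d**2


@dataclass(frozen=True)
class SynergyParams:
    """RT-triggered immune response acting on an unirradiated lesion.

    Each fraction delivered to the primary at time t_i triggers, after
    an onset delay ``lag`` (days), a kill-rate pulse
    ``Y0 * exp(-(t - t_i - lag)/tau)`` on the metastatic specific rate,
    scaled by the coupling ``delta``.  ``tau`` (days) is the decay time
    of the activated response; ``Y0`` (day^-1) is the triggered
    amplitude per fraction.  Default ``lag = tau`` (onset delay and
    decay time are the same immunological timescale unless configured
    apart).  ``delta = 0`` or ``Y0 = 0`` switches the synergy off.
    """

    delta: float
    tau: float
    Y0: float
    lag: float | None = None
    t_in: float = 0.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.Y0 < 0:
            raise ValueError("Y0 must be non-negative")
        if self.lag is None:
            object.__setattr__(self, "lag", float(self.tau))
        elif self.lag < 0:
            raise ValueError("lag must be non-negative")

    def pulse_rate(self, t, fraction_times: Sequence[float]):
        """Summed triggered kill rate delta * sum_i Y0 e^{-(t-t_i-lag)/tau} (day^-1)."""
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t, dtype=float)
        for ti in fraction_times:
            onset = ti + self.lag
            dt = t - onset
            total += np.where(dt >= 0, self.Y0 * np.exp(-np.maximum(dt, 0) / self.tau), 0.0)
        out = self.delta * total
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TherapyCourse:
    """A complete treatment description: IT profile, RT schedule, synergy.

    Any component may be absent.  ``t0`` is the course start day:
    the IT clock (I(t) decay) runs from ``t0``.
    """

    it: ImmunotherapyProfile | None = None
    rt: RadiationSchedule | None = None
    synergy: SynergyParams | None = None
    t0: float = 0.0


@dataclass(frozen=True)
class CombinedLogEffect:
    """Decomposition of ln N(t) - ln N(t0) for a multi-fraction course.

    ``growth_term`` is the untreated GL exponent
    ln(Ninf/N(t0)) [1 - e^{-k (t - t0)}]; ``W_bar`` the cumulative IT
    log-effect; ``D_nf`` the cumulative RT log-effect.  The identity
    ln N(t) - ln N(t0) = growth_term - W_bar - D_nf holds exactly.
    """

    growth_term: float
    W_bar: float
    D_nf: float
    t0: float
    t: float
    N_t0: float

    @property
    def log_change(self) -> float:
        return self.growth_term - self.W_bar - self.D_nf

    @property
    def size(self) -> float:
        """Reconstructed N(t) = N(t0) * exp(growth_term - W_bar - D_nf)."""
        return self.N_t0 * math.exp(self.log_change)


@dataclass(frozen=True)
class RegressionAssessment:
    """Outcome of the regression (tumor-decrease) criterion for a course."""

    is_regressing: bool
    margin: float
    near_critical: bool


def lqm_survival(dose: float, alpha: float, beta: float) -> float:
    """Linear-quadratic surviving fraction exp(-(alpha d + beta d^2)) in (0, 1]."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    return math.exp(-(alpha * dose + beta * dose**2))


def lqm_log_kill(dose: float, alpha: float, beta: float) -> float:
    """Log-kill alpha*d + beta*d^2 of a single fraction (>= 0)."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return alpha * dose + beta * dose**2


def _w_bar(it: ImmunotherapyProfile | None, k: float, dt) -> np.ndarray | float:
    """Cumulative IT log-effect over an elapsed time dt = t - t0.

    W_bar = gamma * int_0^dt e^{-k (dt - s)} I(s) ds with I(s) decaying
    from the course start.  Closed forms:

    * constant profile: gamma I0 (1 - e^{-k dt}) / k  (-> gamma I0 dt as k -> 0)
    * exponential, k != rho: gamma I0 (e^{-rho dt} - e^{-k dt}) / (k - rho)
    * exponential, k == rho: gamma I0 dt e^{-k dt}
    """
    dt = np.asarray(dt, dtype=float)
    if it is None or it.gamma == 0 or it.I0 == 0:
        out = np.zeros_like(dt)
        return float(out) if out.ndim == 0 else out
    g = it.gamma * it.I0
    if it.rho == 0:
        if abs(k) < K_EPS:
            out = g * dt
        else:
            out = g * (1.0 - np.exp(-k * dt)) / k
    else:
        if abs(k - it.rho) < K_EPS:
            out = g * dt * np.exp(-k * dt)
        else:
            out = g * (np.exp(-it.rho * dt) - np.exp(-k * dt)) / (k - it.rho)
    return float(out) if out.ndim == 0 else out


def it_trajectory(gp: GompertzParams, it: ImmunotherapyProfile, t):
    """Size under the IT-perturbed GL, (1/N) dN/dt = k ln(Ninf/N) - gamma I(t).

    Closed form in log space: the untreated exponent minus the
    cumulative IT log-effect W(t).  For a constant profile the
    asymptotic size is the effective carrying capacity
    Ninf * exp(-gamma I0 / k).  Time ``t`` runs from therapy start.
    """
    t = np.asarray(t, dtype=float)
    u = gompertz_log_size(gp, t) - _w_bar(it, gp.k, t)
    out = np.exp(u)
    return float(out) if out.ndim == 0 else out


def _d_nf(schedule: RadiationSchedule | None, k: float, t: float, t0: float) -> float:
    """Cumulative RT log-effect: discounted sum of per-fraction log-kills.

    Each instantaneous log-kill at t_i relaxes under the linear
    log-space dynamics, contributing (alpha d_i + beta d_i^2) e^{-k (t - t_i)}
    at evaluation time t >= t_i.
    """
    if schedule is None or schedule.n_fractions == 0:
        return 0.0
    ft = np.asarray(schedule.fraction_times)
    kills = schedule.log_kills
    mask = ft <= t
    return float(np.sum(kills[mask] * np.exp(-k * (t - ft[mask]))))


def combined_log_effect(
    gp: GompertzParams,
    schedule: RadiationSchedule | None,
    it: ImmunotherapyProfile | None,
    t0: float,
    t: float,
) -> CombinedLogEffect:
    """Closed-form decomposition of a fractionated RT + IT course at time t.

    ``gp`` is anchored at the course start: ``gp.N0`` is the size at
    ``t0``.  All fraction times must lie in [t0, t].  The reconstructed
    size N(t0)*exp(growth_term - W_bar - D_nf) equals the recursive
    construction (Gompertz evolution alternating with instantaneous
    kills) exactly in log space.
    """
    if t < t0:
        raise ValueError("t must be >= t0")
    if schedule is not None and schedule.n_fractions:
        ft = schedule.fraction_times
        if ft[0] < t0 or ft[-1] > t:
            raise ValueError(
                f"fraction times must lie within [t0={t0}, t={t}], got {ft}"
            )
    dt = t - t0
    if abs(gp.k) < K_EPS:
        growth = gp.a * dt
    else:
        growth = (gp.a / gp.k) * (1.0 - math.exp(-gp.k * dt))
    w = float(_w_bar(it, gp.k, dt))
    d = _d_nf(schedule, gp.k, t, t0)
    return CombinedLogEffect(growth_term=growth, W_bar=w, D_nf=d, t0=t0, t=t, N_t0=gp.N0)


def course_log_size(
    gp: GompertzParams,
    course: TherapyCourse,
    times,
) -> np.ndarray:
    """ln N(t) of an IT + fractionated-RT course on an arbitrary time grid.

    Unlike :func:`combined_log_effect` (single evaluation time, all
    fractions inside the window), this sums only the fractions already
    delivered at each grid time, so it can tabulate a whole course.
    Synergy terms are not included here (see :func:`abscopal_trajectory`).
    """
    times = np.asarray(times, dtype=float)
    dt = times - course.t0
    if np.any(dt < 0):
        raise ValueError("all times must be >= course start t0")
    if abs(gp.k) < K_EPS:
        growth = gp.a * dt
    else:
        growth = (gp.a / gp.k) * (1.0 - np.exp(-gp.k * dt))
    u = np.log(gp.N0) + growth - _w_bar(course.it, gp.k, dt)
    if course.rt is not None and course.rt.n_fractions:
        ft = np.asarray(course.rt.fraction_times)
        kills = course.rt.log_kills
        for ti, D in zip(ft, kills):
            u = u - np.where(times >= ti, D * np.exp(-gp.k * np.maximum(times - ti, 0.0)), 0.0)
    return u


def regression_condition(
    effect: CombinedLogEffect, near_critical_tol: float = 0.05
) -> RegressionAssessment:
    """Does the course shrink the tumor below its start-of-course size?

    ``margin = growth_term - W_bar - D_nf``; the tumor regresses
    (N(t) < N(t0)) iff the margin is negative.  ``near_critical`` flags
    |growth_term - D_nf| <= near_critical_tol: RT alone nearly balances
    regrowth, so even a small immunotherapy contribution tips the course
    into regression.
    """
    margin = effect.log_change
    near = abs(effect.growth_term - effect.D_nf) <= near_critical_tol
    return RegressionAssessment(is_regressing=margin < 0, margin=margin, near_critical=near)


def abscopal_trajectory(
    gp_met: GompertzParams,
    syn: SynergyParams,
    schedule: RadiationSchedule | None,
    t_grid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> TumorTrajectory:
    """Metastatic-lesion response to RT delivered to the primary tumor.

    The unirradiated metastasis receives no dose (no instantaneous
    kills); it is attacked by the RT-triggered immune response.
    Piecewise dynamics:

    1. before the first pulse onset (first fraction + lag): untreated
       GL with the metastasis' own parameters;
    2. while pulses are active (through last fraction + lag): the
       specific rate k ln(Ninf/N) - delta * sum_i Y0 e^{-(t-t_i-lag)/tau}
       is integrated numerically;
    3. after the last pulse onset: if the specific rate at the end of
       the RT window is negative, the activated immune system keeps
       clearing the lesion at that frozen exponential rate,
       N(t) = N_end e^{r_end (t - t_end)}; otherwise the perturbed
       dynamics simply continue until the pulses decay.

    The trajectory is continuous everywhere.  ``gp_met.N0`` is the
    metastasis size at ``t_grid[0]``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")

    no_schedule = schedule is None or schedule.n_fractions == 0
    if no_schedule:
        if syn.delta > 0 and syn.Y0 > 0:
            raise ValueError("synergy requires an RT schedule: without dose there is no trigger")
        sizes = gompertz_size(gp_met, t_grid - t_grid[0])
        return TumorTrajectory(t_grid, np.atleast_1d(sizes), "model", "metastasis",
                               gp_met.unit_label)

    if syn.t_in > schedule.fraction_times[0]:
        raise ValueError("RT start day t_in must not exceed the first fraction time")

    # synergy off -> exact untreated closed form
    if syn.delta == 0 or syn.Y0 == 0:
        sizes = gompertz_size(gp_met, t_grid - t_grid[0])
        return TumorTrajectory(t_grid, np.atleast_1d(sizes), "model", "metastasis",
                               gp_met.unit_label)

    ft = schedule.fraction_times
    onsets = [ti + syn.lag for ti in ft]
    t_start, t_final = float(t_grid[0]), float(t_grid[-1])
    t_end_rt = onsets[-1]

    u0 = np.log(gp_met.N0)
    uinf = gp_met.log_carrying_capacity

    def rate(t, u):
        return gp_met.k * (uinf - float(u)) - syn.pulse_rate(float(t), ft)

    u_out = np.empty_like(t_grid)

    # phase 1: untreated closed form up to the first onset
    first_onset = onsets[0]
    pre = t_grid <= min(first_onset, t_final)
    u_out[pre] = np.log(gp_met.N0) + (
        gp_met.a * (t_grid[pre] - t_start)
        if abs(gp_met.k) < K_EPS
        else (gp_met.a / gp_met.k) * (1.0 - np.exp(-gp_met.k * (t_grid[pre] - t_start)))
    )

    if first_onset >= t_final:
        return TumorTrajectory(t_grid, np.exp(u_out), "model", "metastasis",
                               gp_met.unit_label)

    def integrate_piecewise(u_init, seg_bounds):
        """Integrate the pulsed dynamics across onset discontinuities."""
        u = u_init
        for left, right in zip(seg_bounds[:-1], seg_bounds[1:]):
            if right <= left:
                continue
            mask = (t_grid > left) & (t_grid <= right)
            sol = solve_ivp(lambda t, y: [rate(t, y[0])], (left, right), [u],
                            method="RK45", rtol=rtol, atol=atol, dense_output=True)
            if not sol.success:  # pragma: no cover - defensive
                raise RuntimeError(f"abscopal integration failed: {sol.message}")
            if mask.any():
                u_out[mask] = sol.sol(t_grid[mask])[0]
            u = sol.y[0, -1]
        return u

    # phase 2: pulsed dynamics from first onset through last onset
    u_first = float(
        np.log(gp_met.N0)
        + (gp_met.a * (first_onset - t_start) if abs(gp_met.k) < K_EPS
           else (gp_met.a / gp_met.k) * (1.0 - np.exp(-gp_met.k * (first_onset - t_start))))
    )
    interior = sorted({o for o in onsets if first_onset < o < min(t_end_rt, t_final)})
    rt_stop = min(t_end_rt, t_final)
    bounds = [first_onset] + interior + [rt_stop]
    u_end = integrate_piecewise(u_first, bounds)

    if t_end_rt >= t_final:
        return TumorTrajectory(t_grid, np.exp(u_out), "model", "metastasis",
                               gp_met.unit_label)

    # phase 3: frozen exponential continuation if regressing at RT end,
    # else resume the perturbed dynamics as the pulses decay.
    eps = 1e-6  # one integrator step past the last onset
    r_end = rate(t_end_rt + eps, u_end)
    post = t_grid > t_end_rt
    if r_end < 0:
        u_out[post] = u_end + r_end * (t_grid[post] - t_end_rt)
    else:
        sol = solve_ivp(lambda t, y: [rate(t, y[0])], (t_end_rt, t_final), [u_end],
                        method="RK45", rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"abscopal integration failed: {sol.message}")
        u_out[post] = sol.sol(t_grid[post])[0]

    return TumorTrajectory(t_grid, np.exp(u_out), "model", "metastasis",
                           gp_met.unit_label)
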