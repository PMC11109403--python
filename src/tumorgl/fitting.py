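"""Effective-parameter fitting of Gompertz dynamics to tumor-size data.

Therapy reshapes a Gompertz trajectory in ways that can be absorbed
into *effective* parameters (a_eff, k_eff) refit per treatment phase:
the untreated arm pins the baseline (a, k), and each treatment phase is
refit independently, with sign changes of the effective parameters
flagging the transition from growth to regression ("extinction regime").
A final-phase variant lets a_eff enter linearly in time,
specific rate = a_eff (t - t0) - k_eff ln(N / N(t0)), which captures the
accelerating post-therapy collapse (a_eff then carries day^-2 units).

Fits are nonlinear least squares on log size by default (multiplicative
measurement error); a raw-scale objective is available.  Parameter
uncertainties come from the chi^2/dof-scaled covariance of the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .growth import K_EPS
from .trajectory import TumorTrajectory

__all__ = [
    "EffectiveGompertzParams",
    "FitResult",
    "SpecificRateSeries",
    "FitError",
    "effective_log_size",
    "fit_gompertz",
    "fit_phasewise",
    "phase_sign_pattern",
    "estimate_specific_rate",
    "goodness_stats",
]

# multi-start grid; deterministic order, best chi^2 wins
_A_STARTS = (0.01, 0.05, 0.1, 0.3)
_K_STARTS = (0.005, -0.005, 0.05, -0.05, 0.3, -0.3)
_EXP_CLIP = 700.0  # keep exp() finite for wild optimizer excursions


class FitError(RuntimeError):
    """Raised when a fit cannot be performed or fails to converge."""


def _multistart(residuals, x0s, n_points):
    """Run least_squares from each start in deterministic order; best chi^2 wins.

    Stops early once several independent starts land on the same optimum
    (within 1e-6 relative in SSR) or an essentially exact fit is found.
    """
    best = None
    agreeing = 0
    for x0 in x0s:
        try:
            res = least_squares(residuals, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        ssr = float(np.sum(res.fun**2))
        if not np.isfinite(ssr):
            continue
        if best is None or ssr < best[0] - 1e-6 * max(best[0], 1e-300):
            best = (ssr, res)
            agreeing = 1
            if ssr < 1e-20 * n_points:
                break
        elif ssr <= best[0] + 1e-6 * max(best[0], 1e-300):
            agreeing += 1
            if agreeing >= 4:
                break
    return best


@dataclass(frozen=True)
class EffectiveGompertzParams:
    """Effective GL parameters for one treatment phase.

    ``a_eff`` is in day^-1, or day^-2 when ``a_linear_time`` is set (the
    specific rate is then a_eff (t - t0) - k_eff ln(N / N(t0))).
    ``k_eff`` (day^-1) may carry either sign; a negative value in a
    decaying phase signals complete depletion rather than saturation.
    ``n_t0`` anchors the phase: the (fitted or fixed) size at ``t0``.
    """

    a_eff: float
    k_eff: float
    t0: float
    n_t0: float
    a_linear_time: bool = False

    @property
    def effective_carrying_capacity(self) -> float | None:
        """N(t0) exp(a_eff/k_eff) when the phase saturates; None otherwise.

        Undefined for the linear-time parameterization and for the
        extinction regime (k_eff <= 0), where the trajectory has no
        finite positive asymptote.
        """
        if self.a_linear_time or self.k_eff <= K_EPS:
            return None
        return self.n_t0 * math.exp(self.a_eff / self.k_eff)

    @property
    def regime(self) -> str:
        if self.effective_carrying_capacity is not None:
            return "saturating"
        if self.a_eff < 0 or self.k_eff < 0:
            return "extinction"
        return "exponential"


@dataclass(frozen=True)
class FitResult:
    """Estimated effective parameters with uncertainty and goodness stats."""

    params: EffectiveGompertzParams
    a_err: float
    k_err: float
    correlation_coefficient: float
    rms_relative_error: float
    n_points: int
    chi2_per_dof: float
    objective: str
    degenerate: bool = False
    phase_label: str = ""


@dataclass(frozen=True)
class SpecificRateSeries:
    """Per-time estimates of the specific growth rate (1/N) dN/dt = d ln N / dt."""

    times: np.ndarray
    rates: np.ndarray
    method: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("times and rates must be 1-D arrays of equal length")
        if not np.all(np.isfinite(r)):
            raise ValueError("rates must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rates", r)


def effective_log_size(t, a: float, k: float, u0: float, t0: float,
                       a_linear_time: bool = False):
    """ln N(t) of the effective GL phase model.

    Standard form:   u0 + (a/k)(1 - e^{-k s}),            s = t - t0
    linear-a form:   u0 + (a/k)(s - (1 - e^{-k s})/k)
    with the k -> 0 limits a s and a s^2 / 2 respectively.
    """
    s = np.asarray(t, dtype=float) - t0
    if abs(k) < K_EPS:
        u = u0 + (0.5 * a * s**2 if a_linear_time else a * s)
    else:
        e = np.exp(np.clip(-k * s, -_EXP_CLIP, _EXP_CLIP))
        if a_linear_time:
            u = u0 + (a / k) * (s - (1.0 - e) / k)
        else:
            u = u0 + (a / k) * (1.0 - e)
    return u


def _goodness_from_log(observed: np.ndarray, u_fit: np.ndarray):
    fitted = np.exp(np.clip(u_fit, -_EXP_CLIP, _EXP_CLIP))
    return goodness_stats(observed, fitted)


def fit_gompertz(
    traj: TumorTrajectory,
    init: EffectiveGompertzParams | None = None,
    *,
    log_scale: bool = True,
    fit_n0: bool = False,
    a_linear_time: bool = False,
    t0: float | None = None,
    phase_label: str = "",
) -> FitResult:
    """Nonlinear least-squares fit of (a_eff, k_eff) to one trajectory.

    The phase anchor N(t0) is fixed to the first observation by default
    (``fit_n0=True`` co-estimates it).  Residuals are taken on log size
    unless ``log_scale=False``.  A deterministic multi-start grid guards
    against the shallow (a, k) likelihood valley; the best-chi^2 start
    wins.  Parameter errors are chi^2/dof-scaled standard errors.

    Raises
    ------
    FitError
        For fewer than 4 points or if no start converges.
    """
    if len(traj) < 4:
        raise FitError(f"need at least 4 points to fit, got {len(traj)}")
    t = traj.times
    y = traj.sizes
    logy = traj.log_sizes
    t0 = float(t[0]) if t0 is None else float(t0)
    u0_fixed = float(logy[0])

    # constant data: a ~ 0, k unidentifiable
    if np.ptp(logy) < 1e-12:
        params = EffectiveGompertzParams(0.0, 0.0, t0, float(y[0]), a_linear_time)
        corr, rms = goodness_stats(y, np.full_like(y, y[0])) if np.ptp(y) > 0 else (float("nan"), 0.0)
        return FitResult(params, float("nan"), float("nan"), corr, rms,
                         len(traj), 0.0, "log" if log_scale else "raw",
                         degenerate=True, phase_label=phase_label)

    def residuals(x):
        a, k = x[0], x[1]
        u0 = x[2] if fit_n0 else u0_fixed
        u = effective_log_size(t, a, k, u0, t0, a_linear_time)
        if log_scale:
            return logy - u
        return y - np.exp(np.clip(u, -_EXP_CLIP, _EXP_CLIP))

    # data-driven first guess: initial log-slope for a, small positive k
    a_guess = (logy[1] - logy[0]) / (t[1] - t[0])
    starts: list[tuple[float, float]] = []
    if init is not None:
        starts.append((init.a_eff, init.k_eff))
    starts.append((a_guess, 0.01))
    starts.extend((a, k) for a in _A_STARTS for k in _K_STARTS)

    x0s = [[a0, k0] + ([u0_fixed] if fit_n0 else []) for a0, k0 in starts]
    best = _multistart(residuals, x0s, len(traj))
    if best is None:
        raise FitError("no multi-start converged; data may be degenerate")

    ssr, res = best
    n, p = len(traj), res.x.size
    dof = max(n - p, 1)
    chi2_dof = ssr / dof
    # chi^2/dof-scaled covariance from the Jacobian at the optimum
    JtJ = res.jac.T @ res.jac
    degenerate = False
    try:
        cov = np.linalg.inv(JtJ) * chi2_dof
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
        if np.linalg.cond(JtJ) > 1e12:
            degenerate = True
    except np.linalg.LinAlgError:
        perr = np.full(p, np.nan)
        degenerate = True

    a_hat, k_hat = float(res.x[0]), float(res.x[1])
    n_t0 = float(np.exp(res.x[2])) if fit_n0 else float(y[0])
    params = EffectiveGompertzParams(a_hat, k_hat, t0, n_t0, a_linear_time)
    u_fit = effective_log_size(t, a_hat, k_hat, math.log(n_t0), t0, a_linear_time)
    corr, rms = _goodness_from_log(y, u_fit)
    return FitResult(params, float(perr[0]), float(perr[1]), corr, rms, n,
                     chi2_dof, "log" if log_scale else "raw",
                     degenerate=degenerate, phase_label=phase_label)


def fit_phasewise(
    traj: TumorTrajectory,
    phase_breaks: Sequence[float],
    linear_a_last_phase: bool = False,
    *,
    log_scale: bool = True,
    labels: Sequence[str] | None = None,
) -> list[FitResult]:
    """Independent effective-parameter fits per treatment phase.

    Phases are delimited by the caller-supplied break days (treatment
    days are known, so no change-point detection): phase i covers
    [break_{i-1}, break_i).  Each phase is anchored, for continuity, to
    the last value of the preceding phase's fitted curve: its t0 is the
    preceding phase's final observation time and N(t0) the fitted size
    there (evaluating inside the fitted range, never extrapolating).
    The first phase anchors at its first observation.  The final phase
    optionally uses the linear-time a_eff parameterization.  Sign
    changes of the effective parameters across phases are the package's
    regression indicators (see :func:`phase_sign_pattern`).
    """
    breaks = sorted(float(b) for b in phase_breaks)
    t = traj.times
    if breaks and (breaks[0] <= t[0] or breaks[-1] >= t[-1]):
        raise ValueError("phase breaks must lie strictly inside the trajectory time span")
    edges = [-np.inf] + breaks + [np.inf]
    n_phases = len(edges) - 1
    if labels is not None and len(labels) != n_phases:
        raise ValueError("labels must match the number of phases")

    results: list[FitResult] = []
    prev: FitResult | None = None
    for i in range(n_phases):
        mask = (t >= edges[i]) & (t < edges[i + 1])
        if i == n_phases - 1:
            mask = t >= edges[i]
        if mask.sum() < 3:
            raise FitError(f"phase {i} retains {int(mask.sum())} points; need at least 3")
        sub_t = t[mask]
        sub_y = traj.sizes[mask]
        if prev is None:
            t0_i = float(sub_t[0])
            anchor = float(sub_y[0])
        else:
            pp = prev.params
            t0_i = prev_t_last
            anchor = float(np.exp(effective_log_size(
                t0_i, pp.a_eff, pp.k_eff, math.log(pp.n_t0), pp.t0, pp.a_linear_time)))
        sub = TumorTrajectory(sub_t, sub_y, traj.subject_id, traj.arm, traj.unit_label)
        linear = linear_a_last_phase and i == n_phases - 1
        label = labels[i] if labels else f"phase{i}"
        if prev is None and len(sub) >= 4:
            res = fit_gompertz(sub, log_scale=log_scale, a_linear_time=linear,
                               phase_label=label)
        elif prev is None:
            res = _fit_anchored(sub, float(sub_y[0]), float(sub_t[0]), linear,
                                log_scale, phase_label=label)
        else:
            res = _fit_anchored(sub, anchor, t0_i, linear, log_scale,
                                phase_label=label)
        results.append(res)
        prev = res
        prev_t_last = float(sub_t[-1])
    return results


def _fit_anchored(traj, anchor, t0, a_linear_time, log_scale, phase_label):
    """fit_gompertz with N(t0) fixed to an externally supplied anchor."""
    t, y, logy = traj.times, traj.sizes, traj.log_sizes
    if len(traj) < 3:
        raise FitError("anchored phase fit needs at least 3 points")
    u0 = math.log(anchor)

    def residuals(x):
        u = effective_log_size(t, x[0], x[1], u0, t0, a_linear_time)
        if log_scale:
            return logy - u
        return y - np.exp(np.clip(u, -_EXP_CLIP, _EXP_CLIP))

    a_guess = (logy[-1] - logy[0]) / (t[-1] - t[0])
    starts = [(a_guess, 0.01)] + [(a, k) for a in _A_STARTS for k in _K_STARTS]
    starts += [(-a, k) for a in _A_STARTS for k in _K_STARTS]
    best = _multistart(residuals, [list(s) for s in starts], len(traj))
    if best is None:
        raise FitError(f"phase {phase_label!r}: no start converged")
    ssr, res = best
    dof = max(len(traj) - 2, 1)
    chi2_dof = ssr / dof
    JtJ = res.jac.T @ res.jac
    degenerate = False
    try:
        perr = np.sqrt(np.clip(np.diag(np.linalg.inv(JtJ) * chi2_dof), 0, None))
        degenerate = bool(np.linalg.cond(JtJ) > 1e12)
    except np.linalg.LinAlgError:
        perr = np.full(2, np.nan)
        degenerate = True
    a_hat, k_hat = float(res.x[0]), float(res.x[1])
    params = EffectiveGompertzParams(a_hat, k_hat, t0, anchor, a_linear_time)
    u_fit = effective_log_size(t, a_hat, k_hat, u0, t0, a_linear_time)
    corr, rms = _goodness_from_log(y, u_fit)
    return FitResult(params, float(perr[0]), float(perr[1]), corr, rms, len(traj),
                     chi2_dof, "log" if log_scale else "raw",
                     degenerate=degenerate, phase_label=phase_label)


def phase_sign_pattern(results: Sequence[FitResult]) -> list[tuple[int, int]]:
    """(sign a_eff, sign k_eff) per phase; a (-) k_eff flags depletion."""
    return [(int(np.sign(r.params.a_eff)), int(np.sign(r.params.k_eff))) for r in results]


def estimate_specific_rate(
    traj: TumorTrajectory, method: str = "central_difference"
) -> SpecificRateSeries:
    """Finite-difference specific growth rate d(ln N)/dt on the data grid.

    ``central_difference`` uses second-order central differences in the
    interior and one-sided differences at the ends; negative values
    flag regression.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 points to estimate the specific rate")
    t, u = traj.times, traj.log_sizes
    if method == "central_difference":
        rates = np.gradient(u, t)
    elif method == "forward_difference":
        d = np.diff(u) / np.diff(t)
        rates = np.concatenate([d, d[-1:]])
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpecificRateSeries(times=t, rates=rates, method=method)


def goodness_stats(observed, fitted) -> tuple[float, float]:
    """(Pearson correlation, RMS relative error) of observed vs fitted sizes.

    RMS relative error is sqrt(mean(((obs - fit)/fit)^2)).  Zero variance
    in either vector makes the correlation undefined (returned as NaN).
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and fitted must be equal-length 1-D arrays (n >= 2)")
    if np.any(fit <= 0):
        raise ValueError("fitted sizes must be positive")
    rms = float(np.sqrt(np.mean(((obs - fit) / fit) ** 2)))
    if np.std(obs) == 0 or np.std(fit) == 0:
        return float("nan"), rms
    corr = float(np.corrcoef(obs, fit)[0, 1])
    return corr, rms
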