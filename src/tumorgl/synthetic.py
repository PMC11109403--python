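"""Synthetic preclinical study generator.

Builds multi-arm tumor-growth studies with the statistical structure
the fitting layer assumes, so every analysis stage is testable without
external data.  Two packaged designs emulate the study structures the
effective-parameter approach targets:

* ``antibody_like_design`` — five arms of an autoantibody experiment:
  untreated, two agonist dose levels (faster growth: both effective
  parameters above the untreated values) and two antagonist dose levels
  (slowed growth).  Arm parameters are the fitted effective values of
  the corresponding published experiment, so the synthetic study lives
  on realistic scales; observations every 2 days over days 0-40.

* ``rt_abscopal_like_design`` — a primary fibrosarcoma-like tumor under
  0, 1 or 3 fractions of 8 Gy on days 9(-11), plus an unirradiated
  metastasis responding through the RT-triggered synergy; daily
  observations over days 0-25.

Measurement noise defaults to 5% multiplicative lognormal (tumor-size
error is scale-proportional); an additive Gaussian option suits
diameter-like data.  All randomness is reproducible from seeds: each
(arm, subject) pair draws from its own seeded stream, so changing one
arm's seed leaves every other arm bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .growth import GompertzParams, gompertz_size
from .therapy import (
    ImmunotherapyProfile,
    RadiationSchedule,
    SynergyParams,
    TherapyCourse,
    abscopal_trajectory,
    course_log_size,
)
from .trajectory import TumorTrajectory

__all__ = [
    "NoiseModel",
    "StudyArm",
    "StudyDesign",
    "model_trajectory",
    "generate_trajectory",
    "generate_study",
    "generate_phasewise_trajectory",
    "three_phase_rt_trajectory",
    "THREE_PHASE_PARAMS",
    "THREE_PHASE_BREAKS",
    "THREE_PHASE_DAYS",
    "antibody_like_design",
    "rt_abscopal_like_design",
]

logger = logging.getLogger(__name__)

_NOISE_KINDS = ("multiplicative_lognormal", "additive_gaussian")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    ``sd`` is the standard deviation of log residuals (dimensionless)
    for the multiplicative kind, or an absolute size for the additive
    kind.  The seed fully determines the output for a given design.
    """

    kind: str = "multiplicative_lognormal"
    sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"kind must be one of {_NOISE_KINDS}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def apply(self, sizes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Noisy sizes; zero sd reproduces the model exactly."""
        if self.sd == 0:
            return sizes.copy()
        if self.kind == "multiplicative_lognormal":
            return sizes * np.exp(rng.normal(0.0, self.sd, size=sizes.shape))
        noisy = sizes + rng.normal(0.0, self.sd, size=sizes.shape)
        bad = noisy <= 0
        if bad.any():
            # additive noise can push a small tumor negative; resample with a
            # floor at 1e-6 of the model value so sizes stay positive
            logger.info("resampling %d non-positive noisy sizes", int(bad.sum()))
            for i in np.flatnonzero(bad):
                for _ in range(100):
                    cand = sizes[i] + rng.normal(0.0, self.sd)
                    if cand > 0:
                        noisy[i] = cand
                        break
                else:
                    noisy[i] = 1e-6 * sizes[i]
        return noisy


@dataclass(frozen=True)
class StudyArm:
    """One arm of a study design."""

    label: str
    gp: GompertzParams
    course: TherapyCourse | None = None
    n_subjects: int = 1
    observation_days: tuple = ()
    seed: int | None = None  # overrides the design-level stream for this arm

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.observation_days)
        if len(days) < 2 or any(np.diff(days) <= 0):
            raise ValueError(f"arm {self.label!r}: observation_days must be strictly increasing")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        object.__setattr__(self, "observation_days", days)


@dataclass(frozen=True)
class StudyDesign:
    arms: tuple
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("design needs at least one arm")
        labels = [a.label for a in self.arms]
        if len(set(labels)) != len(labels):
            raise ValueError("arm labels must be unique")
        object.__setattr__(self, "arms", tuple(self.arms))


def model_trajectory(
    gp: GompertzParams, course: TherapyCourse | None, days
) -> TumorTrajectory:
    """Noiseless model trajectory for a therapy course.

    Synergy-bearing courses (the unirradiated metastasis) integrate the
    pulsed dynamics; IT and fractionated-RT courses use the closed
    forms; no course means untreated Gompertz growth.
    """
    days = np.asarray(days, dtype=float)
    if course is not None and course.synergy is not None:
        return abscopal_trajectory(gp, course.synergy, course.rt, days)
    if course is None:
        sizes = np.atleast_1d(gompertz_size(gp, days - days[0]))
        return TumorTrajectory(days, sizes, "model", "", gp.unit_label)
    u = course_log_size(gp, course, days)
    return TumorTrajectory(days, np.exp(u), "model", "", gp.unit_label)


def generate_trajectory(
    gp: GompertzParams,
    course: TherapyCourse | None,
    days,
    noise: NoiseModel,
    subject_id: str = "s1",
    arm: str = "",
) -> TumorTrajectory:
    """One noisy trajectory; same seed, same output."""
    model = model_trajectory(gp, course, days)
    rng = np.random.default_rng(noise.seed)
    sizes = noise.apply(model.sizes, rng)
    return TumorTrajectory(model.times, sizes, subject_id, arm, gp.unit_label)


def generate_study(design: StudyDesign) -> dict[str, list[TumorTrajectory]]:
    """Per-arm, per-subject noisy trajectories with independent streams.

    Subject streams are seeded as (arm seed, subject index); the arm
    seed is the arm's own ``seed`` if set, else (design seed, arm
    index), so re-seeding one arm never perturbs another.
    """
    out: dict[str, list[TumorTrajectory]] = {}
    for arm_idx, arm in enumerate(design.arms):
        model = model_trajectory(arm.gp, arm.course, arm.observation_days)
        trajs = []
        for subj in range(arm.n_subjects):
            if arm.seed is not None:
                rng = np.random.default_rng([arm.seed, subj])
            else:
                rng = np.random.default_rng([design.noise.seed, arm_idx, subj])
            sizes = design.noise.apply(model.sizes, rng)
            trajs.append(
                TumorTrajectory(model.times, sizes, f"{arm.label}-{subj + 1}",
                                arm.label, arm.gp.unit_label)
            )
        out[arm.label] = trajs
    return out


def generate_phasewise_trajectory(
    phases: Sequence[tuple[float, float, bool]],
    breaks: Sequence[float],
    days,
    n0: float,
    noise: NoiseModel,
    subject_id: str = "s1",
    arm: str = "phasewise",
) -> TumorTrajectory:
    """Piecewise-effective-parameter trajectory (RT-response-like shape).

    ``phases`` is a list of (a_eff, k_eff, a_linear_time) triples, one
    per segment delimited by ``breaks``; each segment continues from the
    previous segment's endpoint (continuous log size).  This is the
    generating model for therapy data whose response is absorbed into
    time-dependent effective parameters: e.g. growth, slowed growth,
    then an accelerating decay phase with negative effective rates.
    """
    from .fitting import effective_log_size  # local import avoids a cycle

    days = np.asarray(days, dtype=float)
    breaks = sorted(float(b) for b in breaks)
    if len(phases) != len(breaks) + 1:
        raise ValueError("need exactly one more phase than breaks")
    edges = [days[0]] + breaks + [np.inf]
    u = np.empty_like(days)
    u0, t0 = np.log(n0), days[0]
    for i, (a, k, linear) in enumerate(phases):
        mask = (days >= edges[i]) & (days < edges[i + 1])
        if i == 0:
            seg_t0, seg_u0 = t0, u0
        else:
            seg_t0 = edges[i]
            a_p, k_p, lin_p = phases[i - 1]
            seg_u0 = float(effective_log_size(seg_t0, a_p, k_p, prev_u0, prev_t0, lin_p))
        if mask.any():
            u[mask] = effective_log_size(days[mask], a, k, seg_u0, seg_t0, linear)
        prev_t0, prev_u0 = seg_t0, seg_u0
    model = np.exp(u)
    rng = np.random.default_rng(noise.seed)
    sizes = noise.apply(model, rng)
    return TumorTrajectory(days, sizes, subject_id, arm, "mm^3")


# ---------------------------------------------------------------------------
# Packaged study designs
# ---------------------------------------------------------------------------

#: Three-phase RT-response shape: growth, slowed growth under treatment,
#: then accelerating decay (negative effective rates, linear-time a_eff).
#: Phase spans and rates are chosen so each phase carries enough log-size
#: curvature for its k_eff sign to be identifiable at 5% measurement noise.
THREE_PHASE_PARAMS = ((0.25, 0.12, False), (0.08, 0.4, False), (-1e-3, -0.3, True))
THREE_PHASE_BREAKS = (12.0, 22.0)
THREE_PHASE_DAYS = tuple(np.arange(0.0, 37.0, 1.0))


def three_phase_rt_trajectory(seed: int, sd: float = 0.05) -> TumorTrajectory:
    """One noisy trajectory from the packaged three-phase RT-response fixture."""
    return generate_phasewise_trajectory(
        phases=THREE_PHASE_PARAMS,
        breaks=THREE_PHASE_BREAKS,
        days=THREE_PHASE_DAYS,
        n0=50.0,
        noise=NoiseModel(sd=sd, seed=seed),
        arm="rt-3phase",
    )

def antibody_like_design(
    n_subjects: int = 8, seed: int = 0, sd: float = 0.05
) -> StudyDesign:
    """Five-arm autoantibody study: untreated, agonist x2, antagonist x2.

    Arm dynamics use the fitted effective parameters of the emulated
    experiment (untreated a=0.049, k=0.011 day^-1; agonist arms grow
    faster, antagonist arms slower), N0 = 100, observations every 2
    days over days 0-40.
    """
    days = tuple(np.arange(0.0, 41.0, 2.0))

    def arm(label, a, k):
        return StudyArm(label, GompertzParams(a=a, k=k, N0=100.0), None,
                        n_subjects, days)

    arms = (
        arm("untreated", 0.049, 0.011),
        arm("agonist-10", 0.0714, 0.02),
        arm("agonist-30", 0.075, 0.024),
        arm("antagonist-10", 0.0285, 0.0096),
        arm("antagonist-30", 0.034, 4.7e-5),
    )
    return StudyDesign(arms=arms, noise=NoiseModel("multiplicative_lognormal", sd, seed))


def rt_abscopal_like_design(
    n_subjects: int = 8,
    seed: int = 0,
    sd: float = 0.05,
    synergy_y0: float = 0.2,
) -> StudyDesign:
    """Primary tumor under 0/1/3 x 8 Gy plus an abscopal metastasis arm.

    The primary grows with effective untreated parameters a=0.054,
    k=0.0164 day^-1, N0=50; fractions of 8 Gy are delivered on day 9
    (single-dose arm) or days 9, 10, 11 (full course), with LQ
    sensitivities alpha=0.3 Gy^-1, beta=alpha/10.  The metastasis arm
    shares the growth parameters and responds only through the
    RT-triggered synergy (delta=1, tau=lag=2 d, amplitude
    ``synergy_y0`` per fraction).  Daily observations, days 0-25.
    """
    days = tuple(np.arange(0.0, 26.0, 1.0))
    gp = GompertzParams(a=0.054, k=0.0164, N0=50.0)
    alpha, beta = 0.3, 0.03
    rt1 = RadiationSchedule((9.0,), (8.0,), alpha, beta)
    rt3 = RadiationSchedule((9.0, 10.0, 11.0), (8.0,) * 3, alpha, beta)
    syn = SynergyParams(delta=1.0, tau=2.0, Y0=synergy_y0, lag=2.0, t_in=9.0)
    arms = (
        StudyArm("untreated", gp, None, n_subjects, days),
        StudyArm("rt-1x8Gy", gp, TherapyCourse(rt=rt1), n_subjects, days),
        StudyArm("rt-3x8Gy", gp, TherapyCourse(rt=rt3), n_subjects, days),
        StudyArm("metastasis-abscopal", gp,
                 TherapyCourse(rt=rt3, synergy=syn), n_subjects, days),
    )
    return StudyDesign(arms=arms, noise=NoiseModel("multiplicative_lognormal", sd, seed))
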