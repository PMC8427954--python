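"""Three-compartment + effect-site PK simulation and synthetic-study generation.

The PK system is the standard mammillary model with first-order rate
constants (1/min) plus an effect compartment ``dCe/dt = ke0 (Cp - Ce)``.
Piecewise-constant infusions are propagated exactly with per-interval
matrix exponentials.  On top of it sit an idealized effect-site
target-controlled infusion (TCI) controller producing a step-up Ce
staircase, and a study generator that samples ordinal sedation scores on a
fixed observation grid and applies the modeling-point selection rule.

Times are seconds at every interface; rate constants and infusion rates
are per-minute quantities (conversion is centralized in ``_propagators``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.linalg import expm

from .core_model import PDParams, predicted_score, threshold_probs
from .dataset_io import (
    InfusionLog,
    ObservationRecord,
    SedationDataset,
    select_modeling_points,
)

__all__ = [
    "PKParams",
    "StudyDesign",
    "ConcentrationTrajectory",
    "TargetUnreachableError",
    "simulate_concentrations",
    "effect_site_step_protocol",
    "sample_umss",
    "generate_study",
    "DEFAULT_PK",
]

SEC_PER_MIN = 60.0


class TargetUnreachableError(RuntimeError):
    """The TCI controller could not reach a requested effect-site target."""


@dataclass(frozen=True)
class PKParams:
    """Three-compartment + effect-site parameters.

    ``v1`` is the central volume (L); ``k10, k12, k21, k13, k31`` are
    first-order rate constants and ``ke0`` the plasma/effect-site
    equilibration constant, all in 1/min.
    """

    v1: float
    k10: float
    k12: float
    k21: float
    k13: float
    k31: float
    ke0: float

    def __post_init__(self) -> None:
        for name in ("v1", "k10", "k12", "k21", "k13", "k31", "ke0"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k) for k in ("v1", "k10", "k12", "k21", "k13", "k31", "ke0")
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PKParams":
        return cls(**{k: float(d[k]) for k in ("v1", "k10", "k12", "k21", "k13", "k31", "ke0")})


#: Synthetic pediatric-scale defaults for fixtures and examples.  These are
#: plausible round numbers, not any published parameter set; real model
#: comparisons must supply their own constants via configuration.
DEFAULT_PK = PKParams(v1=9.5, k10=0.07, k12=0.11, k21=0.055, k13=0.042, k31=0.0033, ke0=0.8)


@dataclass(frozen=True)
class StudyDesign:
    """Step-up effect-site TCI protocol and observation grid."""

    targets: Tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    hold_after_reach: float = 120.0  # seconds at target before next step
    eval_step: float = 20.0  # seconds between sedation assessments
    ce_tolerance: float = 0.02  # ug/mL; |Ce - target| <= tol counts as reached
    control_tick: float = 1.0  # seconds per controller decision
    plasma_cap_factor: float = 4.0  # Cp may overshoot to this multiple of target
    max_rate: Optional[float] = None  # mass/min; None = uncapped
    max_step_time: float = 600.0  # seconds allowed to reach each target

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.targets)
        if not t or any(x <= 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("targets must be positive and strictly increasing")
        if self.eval_step <= 0 or self.hold_after_reach < 0:
            raise ValueError("eval_step must be > 0 and hold_after_reach >= 0")
        if self.hold_after_reach % self.eval_step != 0:
            raise ValueError("eval_step must divide hold_after_reach")
        object.__setattr__(self, "targets", t)


@dataclass
class ConcentrationTrajectory:
    """Concentrations on a regular time grid with the applied infusion rates."""

    times: np.ndarray  # seconds
    cp: np.ndarray  # ug/mL
    ce: np.ndarray  # ug/mL
    rates: np.ndarray  # mass/min applied on [times[i], times[i+1])

    def ce_at(self, t: float) -> float:
        """Linear interpolation of Ce at time ``t``."""
        return float(np.interp(t, self.times, self.ce))


# ---------------------------------------------------------------------------
# linear-system propagation


def _system_matrix(pk: PKParams) -> np.ndarray:
    """State (a1, a2, a3, ce): compartment amounts (mass) and Ce (mass/L)."""
    return np.array(
        [
            [-(pk.k10 + pk.k12 + pk.k13), pk.k21, pk.k31, 0.0],
            [pk.k12, -pk.k21, 0.0, 0.0],
            [pk.k13, 0.0, -pk.k31, 0.0],
            [pk.ke0 / pk.v1, 0.0, 0.0, -pk.ke0],
        ]
    )


def _propagators(pk: PKParams, dt_seconds: float) -> Tuple[np.ndarray, np.ndarray]:
    """Exact one-step propagator: x' = E @ x + rate * w for constant rate.

    ``E = expm(M dt)`` and ``w`` is the unit-rate forced response, both for
    a step of ``dt_seconds`` with ``M`` in 1/min.
    """
    m = _system_matrix(pk)
    dt_min = dt_seconds / SEC_PER_MIN
    aug = np.zeros((5, 5))
    aug[:4, :4] = m
    aug[0, 4] = 1.0  # unit infusion into the central compartment
    ea = expm(aug * dt_min)
    return ea[:4, :4], ea[:4, 4]


def simulate_concentrations(
    pk: PKParams,
    infusion: InfusionLog,
    dt: float,
    t_end: Optional[float] = None,
    x0: Optional[np.ndarray] = None,
) -> ConcentrationTrajectory:
    """Replay a piecewise-constant infusion through the PK system.

    Concentrations are reported on the regular grid ``0, dt, 2 dt, ...``
    up to ``t_end`` (default: last event time + 1 s, so a trailing zero-rate
    event cleanly terminates the log).  Propagation is exact per constant-
    rate interval via matrix exponentials; event times that fall between
    grid points are honoured by sub-stepping.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    for (t0, _), (t1, _) in zip(infusion.events, infusion.events[1:]):
        if dt > t1 - t0:
            raise ValueError(
                f"dt={dt} exceeds the shortest infusion interval ({t1 - t0} s)"
            )
    if t_end is None:
        t_end = (infusion.events[-1][0] + 1.0) if infusion.events else dt
    n_steps = int(round(t_end / dt))

    cache: Dict[float, Tuple[np.ndarray, np.ndarray]] = {}

    def props(step: float) -> Tuple[np.ndarray, np.ndarray]:
        key = round(step, 9)
        if key not in cache:
            cache[key] = _propagators(pk, step)
        return cache[key]

    event_times = [t for t, _ in infusion.events]
    x = np.zeros(4) if x0 is None else np.asarray(x0, dtype=float).copy()
    times = np.arange(n_steps + 1) * dt
    cp = np.empty(n_steps + 1)
    ce = np.empty(n_steps + 1)
    rates = np.zeros(n_steps + 1)
    cp[0], ce[0] = x[0] / pk.v1, x[3]
    for i in range(n_steps):
        t0, t1 = times[i], times[i + 1]
        rates[i] = infusion.rate_at(t0)
        # sub-step at any event inside (t0, t1)
        cuts = [t for t in event_times if t0 < t < t1]
        segs = [t0] + cuts + [t1]
        for a, b in zip(segs, segs[1:]):
            e_mat, w = props(b - a)
            x = e_mat @ x + infusion.rate_at(a) * w
        cp[i + 1], ce[i + 1] = x[0] / pk.v1, x[3]
    rates[-1] = infusion.rate_at(times[-1])
    return ConcentrationTrajectory(times=times, cp=cp, ce=ce, rates=rates)


# ---------------------------------------------------------------------------
# effect-site TCI controller


def effect_site_step_protocol(
    pk: PKParams, design: StudyDesign = StudyDesign()
) -> Tuple[InfusionLog, ConcentrationTrajectory]:
    """Emit an infusion schedule realizing the step-up Ce staircase.

    Idealized effect-site targeting: at each control tick the constant rate
    over the tick is chosen so that the predicted zero-input Ce peak equals
    the current target (bisection on the linear rate response), with plasma
    capped at ``plasma_cap_factor`` times the target.  A target counts as
    reached once ``|Ce - target| <= ce_tolerance`` on two consecutive
    ticks; it is then held for ``hold_after_reach`` seconds before stepping.
    """
    dt = design.control_tick
    e1, w1 = _propagators(pk, dt)
    horizon = max(60, int(round(6.0 * SEC_PER_MIN / (pk.ke0 * dt))))  # ticks

    x = np.zeros(4)
    times: List[float] = [0.0]
    cps: List[float] = [0.0]
    ces: List[float] = [0.0]
    rates: List[float] = []
    t = 0.0

    for target in design.targets:
        reached_streak = 0
        hold_left = design.hold_after_reach
        step_deadline = t + design.max_step_time
        reached = False
        while True:
            # linear response of the future Ce to the tick's rate:
            # ce_k(r) = a_k + r * b_k after k zero-input ticks
            u = e1 @ x
            v = w1.copy()
            a = np.empty(horizon + 1)
            b = np.empty(horizon + 1)
            a[0], b[0] = u[3], v[3]
            uu, vv = u, v
            for k in range(1, horizon + 1):
                uu = e1 @ uu
                vv = e1 @ vv
                a[k], b[k] = uu[3], vv[3]

            r_cap = math.inf
            if design.plasma_cap_factor is not None:
                cp_free = u[0] / pk.v1
                cp_unit = v[0] / pk.v1
                cap = design.plasma_cap_factor * target
                if cp_unit > 0:
                    r_cap = max(0.0, (cap - cp_free) / cp_unit)
            if design.max_rate is not None:
                r_cap = min(r_cap, design.max_rate)

            def peak(r: float) -> float:
                return float(np.max(a + r * b))

            if peak(0.0) >= target:
                rate = 0.0
            else:
                lo, hi = 0.0, 1.0
                while peak(hi) < target and hi < 1e9:
                    hi *= 2.0
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    if peak(mid) < target:
                        lo = mid
                    else:
                        hi = mid
                rate = min(hi, r_cap)

            x = e1 @ x + rate * w1
            t += dt
            times.append(t)
            cps.append(x[0] / pk.v1)
            ces.append(x[3])
            rates.append(rate)

            if not reached:
                if abs(x[3] - target) <= design.ce_tolerance:
                    reached_streak += 1
                    if reached_streak >= 2:
                        reached = True
                else:
                    reached_streak = 0
                if not reached and t > step_deadline:
                    raise TargetUnreachableError(
                        f"target {target} ug/mL not reached within "
                        f"{design.max_step_time:g} s"
                    )
            else:
                hold_left -= dt
                if hold_left <= 0:
                    break

    rates.append(0.0)  # terminal zero-rate marker
    traj = ConcentrationTrajectory(
        times=np.asarray(times),
        cp=np.asarray(cps),
        ce=np.asarray(ces),
        rates=np.asarray(rates),
    )
    # compress per-tick rates into a piecewise-constant event log
    events: List[Tuple[float, float]] = []
    for i, r in enumerate(rates[:-1]):
        if not events or events[-1][1] != r:
            events.append((float(times[i]), float(r)))
    events.append((float(times[-1]), 0.0))
    log = InfusionLog(subject_id="protocol", events=events)
    return log, traj


# ---------------------------------------------------------------------------
# ordinal sampling and study generation


def sample_umss(ce: float, params: PDParams, rng: np.random.Generator) -> int:
    """Draw one sedation score at ``ce``.

    A single latent uniform is compared against the four threshold
    probabilities (comonotone draw): the score is the number of thresholds
    whose P(score >= n) exceeds the draw.  Marginally each threshold
    indicator is exactly Bernoulli(P(score >= n)), which keeps pooled
    binary-likelihood estimation consistent for data from this sampler.
    """
    p = threshold_probs(float(ce), params)
    u = rng.random()
    return int(np.sum(u < p))


def generate_study(
    params_true: PDParams,
    pk: PKParams = DEFAULT_PK,
    design: StudyDesign = StudyDesign(),
    n_subjects: int = 30,
    seed: int = 0,
    mode: str = "independent",
    selection: str = "design",
    protocol: Optional[Tuple[InfusionLog, ConcentrationTrajectory]] = None,
) -> Tuple[SedationDataset, Dict[str, List[ObservationRecord]]]:
    """Simulate a step-up TCI sedation study and select modeling points.

    Every subject follows the same deterministic Ce staircase (the
    protocol is computed once, or supplied precomputed via ``protocol``).
    Scores are drawn on the ``eval_step`` grid — independently per time
    point (``mode="independent"``, matching the pooled-likelihood
    assumption) or as the running maximum of independent draws
    (``mode="monotone"``, for realism experiments).  Observation stops
    ``eval_step`` seconds after score 4 first occurs.

    ``selection`` controls how the modeling-point rule is applied:

    * ``"design"`` (default): the whole observation plan — selection times
      and the stop at score 4 + one step — is computed once from the
      deterministic most-probable-score course of the shared Ce staircase.
      The plan is then independent of the sampled responses (an ignorable
      design), so pooled ML on the output recovers the generating
      parameters (the pipeline's identifiability property).
    * ``"subject"``: the rule is applied to each subject's own sampled
      series, mirroring how points were chosen in a real study.  Because
      first-attainment and midpoint times then condition on the responses
      themselves, pooled ML on such data is *biased* (markedly so for
      ``mode="monotone"``); use for realism experiments only.
    * ``"none"``: keep every observation.

    Returns the pooled modeling dataset and the full per-subject
    observation series.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if mode not in ("independent", "monotone"):
        raise ValueError(f"unknown mode {mode!r}")
    if selection not in ("design", "subject", "none"):
        raise ValueError(f"unknown selection {selection!r}")
    if protocol is None:
        protocol = effect_site_step_protocol(pk, design)
    _, traj = protocol

    obs_times = np.arange(0.0, traj.times[-1] + 1e-9, design.eval_step)
    obs_ce = np.interp(obs_times, traj.times, traj.ce)
    rng = np.random.default_rng(seed)
    p_thr = threshold_probs(obs_ce, params_true)  # (n_times, 4)

    design_times: Optional[set] = None
    n_keep = len(obs_times)
    if selection == "design":
        course = predicted_score(obs_ce, params_true)
        ref = [
            ObservationRecord("design", float(t), float(c), int(s))
            for t, c, s in zip(obs_times, obs_ce, course)
        ]
        design_times = {r.time for r in select_modeling_points(ref, design.eval_step)}
        # observation stops at the design course's score-4 + one step point
        n_keep = int(np.searchsorted(obs_times, max(design_times))) + 1

    selected: List[ObservationRecord] = []
    full: Dict[str, List[ObservationRecord]] = {}
    for s in range(n_subjects):
        sid = f"S{s + 1:03d}"
        u = rng.random(len(obs_times))
        draws = np.sum(u[:, None] < p_thr, axis=1)
        if mode == "monotone":
            draws = np.maximum.accumulate(draws)
        series: List[ObservationRecord] = []
        if selection == "design":
            for t, ce, score in zip(
                obs_times[:n_keep], obs_ce[:n_keep], draws[:n_keep]
            ):
                series.append(ObservationRecord(sid, float(t), float(ce), int(score)))
            selected.extend([r for r in series if r.time in design_times])
        else:
            # subject-adaptive stop: one more observation after the first 4
            for t, ce, score in zip(obs_times, obs_ce, draws):
                series.append(ObservationRecord(sid, float(t), float(ce), int(score)))
                if score == 4:
                    break
            if series[-1].umss == 4 and len(series) < len(obs_times):
                i = len(series)
                series.append(
                    ObservationRecord(
                        sid, float(obs_times[i]), float(obs_ce[i]), int(draws[i])
                    )
                )
            if selection == "none":
                selected.extend(series)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # may be non-monotone
                    selected.extend(select_modeling_points(series, design.eval_step))
        full[sid] = series

    return SedationDataset(selected), full
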