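"""Ordinal sigmoid-Emax concentration-response model for sedation depth.

The model links effect-site concentration (Ce, ug/mL) to the 5-level
University of Michigan Sedation Scale (UMSS, 0 = awake ... 4 = unarousable)
through four threshold curves

    P(UMSS >= n) = Ce^gamma / (ce50[n]^gamma + Ce^gamma),   n = 1..4,

with a single slope ``gamma`` shared across thresholds and strictly
increasing half-maximal concentrations ``ce50``.  The probability of an
exact score is the product of "response" probabilities up to that score
and "non-response" probabilities above it; the most probable score at a
given Ce is the model's deterministic prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "PDParams",
    "UMSS_LEVELS",
    "NonSequentialTransitionWarning",
    "prob_response",
    "threshold_probs",
    "category_probs",
    "predicted_score",
    "score_breakpoints",
]

#: Valid ordinal sedation levels (0 awake/alert ... 4 unarousable).
UMSS_LEVELS = (0, 1, 2, 3, 4)

N_THRESHOLDS = 4


class NonSequentialTransitionWarning(UserWarning):
    """Raised when the most-probable score does not step 0->1->2->3->4."""


@dataclass(frozen=True)
class PDParams:
    """Parameter vector of the ordinal concentration-response model.

    Parameters
    ----------
    ce50
        Four strictly increasing positive concentrations (ug/mL);
        ``ce50[n-1]`` gives 50% probability of a score >= n.
    gamma
        Positive Hill coefficient shared by all four thresholds.
    """

    ce50: Tuple[float, float, float, float]
    gamma: float

    def __post_init__(self) -> None:
        ce50 = tuple(float(c) for c in self.ce50)
        if len(ce50) != N_THRESHOLDS:
            raise ValueError(f"ce50 must have {N_THRESHOLDS} entries, got {len(ce50)}")
        if any(not math.isfinite(c) or c <= 0.0 for c in ce50):
            raise ValueError(f"all ce50 must be finite and > 0, got {ce50}")
        if any(a >= b for a, b in zip(ce50, ce50[1:])):
            raise ValueError(f"ce50 must be strictly increasing, got {ce50}")
        gamma = float(self.gamma)
        if not math.isfinite(gamma) or gamma <= 0.0:
            raise ValueError(f"gamma must be finite and > 0, got {gamma}")
        object.__setattr__(self, "ce50", ce50)
        object.__setattr__(self, "gamma", gamma)

    def as_dict(self) -> dict:
        return {"ce50": list(self.ce50), "gamma": self.gamma}

    @classmethod
    def from_dict(cls, d: dict) -> "PDParams":
        return cls(ce50=tuple(d["ce50"]), gamma=float(d["gamma"]))


def _validate_ce(ce: np.ndarray) -> None:
    if np.any(~np.isfinite(ce)) or np.any(ce < 0.0):
        raise ValueError("ce must be finite and >= 0")


def prob_response(ce, ce50: float, gamma: float):
    """P(score >= n) for one threshold: ``ce^gamma / (ce50^gamma + ce^gamma)``.

    Evaluated in log space as ``expit(gamma * (log ce - log ce50))`` so that
    large ``gamma`` cannot overflow.  ``ce`` may be a scalar or array;
    ``ce == 0`` maps exactly to probability 0.
    """
    ce50 = float(ce50)
    gamma = float(gamma)
    if not math.isfinite(ce50) or ce50 <= 0.0:
        raise ValueError(f"ce50 must be > 0, got {ce50}")
    if not math.isfinite(gamma) or gamma <= 0.0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    ce_arr = np.asarray(ce, dtype=float)
    _validate_ce(ce_arr)
    scalar = ce_arr.ndim == 0
    ce_arr = np.atleast_1d(ce_arr)
    p = np.zeros_like(ce_arr)
    pos = ce_arr > 0.0
    z = gamma * (np.log(ce_arr[pos]) - math.log(ce50))
    p[pos] = expit(z)
    return float(p[0]) if scalar else p


def threshold_probs(ce, params: PDParams) -> np.ndarray:
    """The four threshold probabilities P(score >= n), n = 1..4.

    Returns shape ``(4,)`` for scalar ``ce`` and ``(m, 4)`` for an array.
    """
    ce_arr = np.asarray(ce, dtype=float)
    scalar = ce_arr.ndim == 0
    ce_arr = np.atleast_1d(ce_arr)
    _validate_ce(ce_arr)
    out = np.zeros((ce_arr.size, N_THRESHOLDS))
    pos = ce_arr > 0.0
    log_ce = np.log(ce_arr[pos])[:, None]
    log_c50 = np.log(np.asarray(params.ce50))[None, :]
    out[pos] = expit(params.gamma * (log_ce - log_c50))
    return out[0] if scalar else out


def category_probs(ce, params: PDParams, normalize: bool = True) -> np.ndarray:
    """Probability of each exact score 0..4 at ``ce``.

    Entry ``n`` is the product ``prod_{k<=n} P(>=k) * prod_{k>n} (1 - P(>=k))``
    with ``P(>=0) = 1`` fixed.  The raw products do not form a normalized
    distribution; by default the vector is rescaled to sum to one, which
    leaves the argmax (and hence every most-probable-score quantity)
    unchanged.  Pass ``normalize=False`` for the raw products, whose entry
    at the observed score equals the product of the four per-threshold
    binary likelihood terms.

    Returns shape ``(5,)`` for scalar ``ce`` and ``(m, 5)`` for an array.
    """
    p = np.atleast_2d(threshold_probs(ce, params))  # (m, 4)
    m = p.shape[0]
    resp = np.concatenate([np.ones((m, 1)), p], axis=1)  # P(>=k), k=0..4
    nonresp = 1.0 - resp
    # cumulative products of responses below each score / non-responses above
    cum_resp = np.cumprod(resp, axis=1)  # prod_{k<=n} P(>=k)
    rev_nonresp = np.concatenate(
        [np.cumprod(nonresp[:, ::-1], axis=1)[:, ::-1][:, 1:], np.ones((m, 1))],
        axis=1,
    )  # prod_{k>n} (1 - P(>=k))
    cat = cum_resp * rev_nonresp
    if normalize:
        cat = cat / cat.sum(axis=1, keepdims=True)
    return cat[0] if np.asarray(ce).ndim == 0 else cat


def predicted_score(ce, params: PDParams):
    """Most probable score at ``ce``; ties resolve to the lower score.

    Non-decreasing in ``ce`` for valid (ordered) parameters.
    """
    cat = category_probs(ce, params, normalize=False)
    if cat.ndim == 1:
        return int(np.argmax(cat))  # argmax takes the first (lower) on ties
    return np.argmax(cat, axis=1).astype(int)


def score_breakpoints(
    params: PDParams,
    grid_step: float = 0.1,
    ce_max: float | None = None,
) -> Dict[int, Tuple[float, float]]:
    """Half-open Ce intervals on a grid where each score is the most probable.

    The grid runs from 0 to ``ce_max`` (default: comfortably above the top
    ``ce50``) in multiples of ``grid_step``.  Score ``n``'s interval starts
    at the smallest grid multiple strictly greater than the exact crossover,
    which for this model sits at ``ce50[n]`` whenever the argmax transitions
    are sequential.  Non-sequential transitions (pathological parameters)
    emit :class:`NonSequentialTransitionWarning` carrying the raw crossover
    grid values.

    Returns a map from score to ``(lower, upper)`` with ``upper`` exclusive;
    score 0 starts at 0.0 and score 4 ends at ``math.inf``.
    """
    grid_step = float(grid_step)
    if not math.isfinite(grid_step) or grid_step <= 0.0:
        raise ValueError(f"grid_step must be > 0, got {grid_step}")
    if ce_max is None:
        ce_max = 2.0 * params.ce50[-1]
    n_pts = int(round(ce_max / grid_step)) + 1
    # build from integer multiples to avoid cumulative float drift
    ks = np.arange(n_pts)
    grid = np.round(ks * grid_step, 12)
    scores = predicted_score(grid, params)

    transitions = []  # (grid value, from_score, to_score)
    for i in range(1, n_pts):
        if scores[i] != scores[i - 1]:
            transitions.append((float(grid[i]), int(scores[i - 1]), int(scores[i])))
    sequential = all(b == a + 1 for _, a, b in transitions) and [
        t[2] for t in transitions
    ] == sorted({t[2] for t in transitions})
    if not sequential:
        warnings.warn(
            f"non-sequential most-probable-score transitions: {transitions}",
            NonSequentialTransitionWarning,
        )

    intervals: Dict[int, Tuple[float, float]] = {}
    present = sorted(set(int(s) for s in scores))
    for s in present:
        where = np.nonzero(scores == s)[0]
        lo = 0.0 if s == present[0] else float(grid[where[0]])
        hi = math.inf if s == present[-1] else float(grid[where[-1] + 1])
        intervals[s] = (lo, hi)
    return intervals
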