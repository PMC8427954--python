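"""Naive-pooled maximum-likelihood estimation of the ordinal model.

All subjects' threshold-expanded binary responses are pooled (inter-
individual variability fixed to zero) and the per-record likelihood

    L = R * P(score >= n) + (1 - R) * (1 - P(score >= n))

is maximized over the five parameters.  Optimization runs on an
unconstrained scale (log of the first ce50, log successive increments,
log gamma) which enforces positivity and ordering smoothly; results are
reported on the natural scale with Wald standard errors (cluster-robust
sandwich by default — see :func:`fit_binary_arrays`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .core_model import PDParams
from .dataset_io import (
    BinaryRecord,
    SedationDataset,
    THRESHOLDS,
    binary_from_observations,
)

__all__ = [
    "FitResult",
    "IdentifiabilityError",
    "neg_log_likelihood",
    "fit_mle",
    "fit_binary_arrays",
    "wald_ci",
]

P_CLAMP = 1e-12
Z_95 = 1.96


class IdentifiabilityError(ValueError):
    """The dataset cannot identify the model parameters."""


@dataclass
class FitResult:
    """Pooled-ML estimates with Wald uncertainty.

    ``se``, ``rse_percent`` and ``ci95`` are ordered
    (ce50[1], ce50[2], ce50[3], ce50[4], gamma).
    """

    params_hat: PDParams
    se: np.ndarray
    rse_percent: np.ndarray
    ci95: np.ndarray  # (5, 2)
    neg_log_lik: float
    converged: bool
    n_obs: int
    n_subjects: int
    n_clamped: int = 0
    message: str = ""
    options: dict = field(default_factory=dict)

    @property
    def estimates(self) -> np.ndarray:
        return np.array(list(self.params_hat.ce50) + [self.params_hat.gamma])

    def as_dict(self) -> dict:
        return {
            "params": self.params_hat.as_dict(),
            "se": [None if not np.isfinite(s) else float(s) for s in self.se],
            "rse_percent": [
                None if not np.isfinite(r) else float(r) for r in self.rse_percent
            ],
            "ci95": [
                [None if not np.isfinite(v) else float(v) for v in row]
                for row in np.asarray(self.ci95)
            ],
            "neg_log_lik": float(self.neg_log_lik),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_subjects": int(self.n_subjects),
            "n_clamped": int(self.n_clamped),
            "message": self.message,
            "options": self.options,
        }


# ---------------------------------------------------------------------------
# likelihood


def _as_arrays(binary) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(binary, tuple) and len(binary) == 3:
        thr, ce, resp = binary
        return (
            np.asarray(thr, dtype=int),
            np.asarray(ce, dtype=float),
            np.asarray(resp, dtype=float),
        )
    records: Sequence[BinaryRecord] = list(binary)
    thr = np.array([r.threshold for r in records], dtype=int)
    ce = np.array([r.ce for r in records], dtype=float)
    resp = np.array([r.response for r in records], dtype=float)
    return thr, ce, resp


def _threshold_p(thr, ce, ce50_arr, gamma):
    """P(score >= thr) per record, stable in log space; ce == 0 -> 0."""
    p = np.zeros_like(ce)
    pos = ce > 0.0
    z = gamma * (np.log(ce[pos]) - np.log(ce50_arr[thr[pos] - 1]))
    p[pos] = expit(z)
    return p


def neg_log_likelihood(params: PDParams, binary) -> float:
    """Negative pooled log-likelihood of binary threshold records.

    ``binary`` is either an iterable of :class:`BinaryRecord` or a tuple of
    arrays ``(threshold, ce, response)``.  Probabilities are clamped to
    ``[1e-12, 1 - 1e-12]`` inside the logarithm only.  Empty input gives 0.
    """
    thr, ce, resp = _as_arrays(binary)
    if thr.size == 0:
        return 0.0
    ce50_arr = np.asarray(params.ce50)
    p = _threshold_p(thr, ce, ce50_arr, params.gamma)
    lik = resp * p + (1.0 - resp) * (1.0 - p)
    return float(-np.sum(np.log(np.clip(lik, P_CLAMP, 1.0))))


def _count_clamped(params: PDParams, thr, ce, resp) -> int:
    p = _threshold_p(thr, ce, np.asarray(params.ce50), params.gamma)
    lik = resp * p + (1.0 - resp) * (1.0 - p)
    return int(np.sum(lik < P_CLAMP))


# unconstrained parameterization: theta = (log c1, log d2, log d3, log d4, log g)
def _theta_to_natural(theta: np.ndarray) -> Tuple[np.ndarray, float]:
    ce50 = np.cumsum(np.exp(theta[:4]))
    return ce50, float(np.exp(theta[4]))


def _natural_to_theta(ce50: Sequence[float], gamma: float) -> np.ndarray:
    ce50 = np.asarray(ce50, dtype=float)
    incr = np.diff(np.concatenate([[0.0], ce50]))
    return np.concatenate([np.log(incr), [math.log(gamma)]])


def _nll_grad_theta(theta, thr, ce, resp):
    """Objective and analytic gradient on the unconstrained scale."""
    ce50, gamma = _theta_to_natural(theta)
    p = _threshold_p(thr, ce, ce50, gamma)
    lik = resp * p + (1.0 - resp) * (1.0 - p)
    nll = float(-np.sum(np.log(np.clip(lik, P_CLAMP, 1.0))))

    pos = ce > 0.0
    z = np.zeros_like(ce)
    z[pos] = gamma * (np.log(ce[pos]) - np.log(ce50[thr[pos] - 1]))
    # d(-log lik)/dz = p - R for both R = 0 and R = 1
    dz = p - resp
    dz[~pos] = 0.0
    grad = np.zeros(5)
    # dz/dtheta_m = -gamma * exp(theta_m) / ce50[thr-1] for m <= thr-1
    e = np.exp(theta[:4])
    inv_c = np.zeros_like(ce)
    inv_c[pos] = 1.0 / ce50[thr[pos] - 1]
    for m in range(4):
        mask = thr - 1 >= m
        grad[m] = -gamma * e[m] * np.sum(dz[mask] * inv_c[mask])
    grad[4] = np.sum(dz * z)  # z = dz/dlog(gamma) * ... (z itself)
    return nll, grad


# ---------------------------------------------------------------------------
# initialization


def _auto_init(thr, ce, resp) -> Tuple[np.ndarray, float]:
    """Per-threshold ce50 from the empirical 50% crossing; gamma = 5."""
    ce50 = np.empty(4)
    for n in THRESHOLDS:
        mask = thr == n
        ce_n, r_n = ce[mask], resp[mask]
        hi = ce_n[(r_n == 1) & (ce_n > 0)]
        lo = ce_n[(r_n == 0) & (ce_n > 0)]
        if hi.size and lo.size:
            ce50[n - 1] = math.sqrt(np.median(hi) * np.median(lo))
        elif hi.size:
            ce50[n - 1] = np.median(hi)
        else:
            ce50[n - 1] = np.median(lo) if lo.size else 1.0
    # enforce strict ordering for the increment parameterization
    for i in range(1, 4):
        if ce50[i] <= ce50[i - 1]:
            ce50[i] = ce50[i - 1] * 1.05
    return ce50, 5.0


def _check_identifiable(thr, ce, resp) -> None:
    if np.unique(ce).size < 2:
        raise IdentifiabilityError(
            "all observations share a single ce value; gamma is not identifiable"
        )
    for n in THRESHOLDS:
        r_n = resp[thr == n]
        if r_n.size == 0 or np.all(r_n == r_n[0]):
            state = "responses" if (r_n.size and r_n[0] == 1) else "non-responses"
            raise IdentifiabilityError(
                f"threshold {n}: all records are {state}; ce50[{n}] is not identifiable"
            )


# ---------------------------------------------------------------------------
# fitting


def _natural_score_rows(params: PDParams, thr, ce, resp) -> np.ndarray:
    """Per-record gradient of the NLL w.r.t. (ce50_1..4, gamma)."""
    ce50 = np.asarray(params.ce50)
    gamma = params.gamma
    p = _threshold_p(thr, ce, ce50, gamma)
    pos = ce > 0.0
    z = np.zeros_like(ce)
    z[pos] = gamma * (np.log(ce[pos]) - np.log(ce50[thr[pos] - 1]))
    dz = p - resp
    dz[~pos] = 0.0
    rows = np.zeros((len(ce), 5))
    for n in (1, 2, 3, 4):
        mask = thr == n
        rows[mask, n - 1] = dz[mask] * (-gamma / ce50[n - 1])
    rows[:, 4] = dz * z / gamma
    return rows


def fit_mle(
    dataset: SedationDataset,
    init: PDParams | str = "auto",
    options: Optional[dict] = None,
) -> FitResult:
    """Fit the five model parameters to a dataset by pooled ML.

    Parameters
    ----------
    dataset
        Observations; internally expanded to binary threshold records.
    init
        ``"auto"`` (empirical 50% crossings, gamma = 5) or explicit
        :class:`~umsspd.core_model.PDParams`.
    options
        ``n_starts`` (default 5) multi-starts from jittered inits,
        ``seed`` (default 0) for the jitter, ``tol`` (default 1e-8)
        objective tolerance, ``hessian_step`` (default 1e-4) relative
        finite-difference step for standard errors.

    Raises
    ------
    IdentifiabilityError
        If some threshold has all-equal responses or only one distinct
        ce value is present.
    """
    thr, ce, resp = binary_from_observations(dataset)
    sid_codes = {sid: i for i, sid in enumerate(dataset.subject_ids)}
    groups = np.repeat(np.array([sid_codes[r.subject_id] for r in dataset]), 4)
    return fit_binary_arrays(
        (thr, ce, resp),
        n_obs=len(dataset),
        n_subjects=dataset.n_subjects,
        init=init,
        options=options,
        groups=groups,
    )


def fit_binary_arrays(
    binary,
    n_obs: int,
    n_subjects: int,
    init: PDParams | str = "auto",
    options: Optional[dict] = None,
    groups: Optional[np.ndarray] = None,
) -> FitResult:
    """Array-level pooled-ML fit; the workhorse behind :func:`fit_mle`.

    ``binary`` is ``(threshold, ce, response)`` arrays.  Set option
    ``compute_se=False`` to skip the Hessian (bootstrap replicates only
    need point estimates).  ``groups`` assigns each binary record to a
    cluster (subject) for the robust sandwich covariance; without it the
    plain inverse-Hessian SE is used.

    Option ``se_method`` is ``"sandwich"`` (default; cluster-robust — the
    four threshold records expanded from one observation are correlated,
    so the composite-likelihood Hessian alone understates uncertainty) or
    ``"hessian"`` for the naive inverse observed information.
    """
    opts = {
        "n_starts": 5,
        "seed": 0,
        "tol": 1e-8,
        "hessian_step": 1e-4,
        "compute_se": True,
        "se_method": "sandwich",
    }
    opts.update(options or {})

    thr, ce, resp = _as_arrays(binary)
    _check_identifiable(thr, ce, resp)

    if isinstance(init, str):
        if init != "auto":
            raise ValueError(f"unknown init {init!r}")
        ce50_0, gamma_0 = _auto_init(thr, ce, resp)
    else:
        ce50_0, gamma_0 = np.asarray(init.ce50), init.gamma
    theta0 = _natural_to_theta(ce50_0, gamma_0)

    rng = np.random.default_rng(opts["seed"])
    starts = [theta0]
    for _ in range(int(opts["n_starts"]) - 1):
        starts.append(theta0 + rng.normal(scale=0.2, size=5))

    # generous bounds on the unconstrained scale prevent overflow excursions
    bounds = [(-12.0, 12.0)] * 5
    best = None
    for th_start in starts:
        res = minimize(
            _nll_grad_theta,
            np.clip(th_start, -11.0, 11.0),
            args=(thr, ce, resp),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": opts["tol"], "gtol": 1e-10},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("optimization failed from every start")

    ce50_hat, gamma_hat = _theta_to_natural(best.x)
    params_hat = PDParams(ce50=tuple(ce50_hat), gamma=gamma_hat)
    nll_hat = float(best.fun)

    est = np.array(list(ce50_hat) + [gamma_hat])
    if opts["compute_se"]:
        se = _wald_se(
            params_hat,
            (thr, ce, resp),
            rel_step=opts["hessian_step"],
            groups=groups if opts["se_method"] == "sandwich" else None,
        )
    else:
        se = np.full(5, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rse = 100.0 * se / est
    ci = np.column_stack([est - Z_95 * se, est + Z_95 * se])

    return FitResult(
        params_hat=params_hat,
        se=se,
        rse_percent=rse,
        ci95=ci,
        neg_log_lik=nll_hat,
        converged=bool(best.success),
        n_obs=int(n_obs),
        n_subjects=int(n_subjects),
        n_clamped=_count_clamped(params_hat, thr, ce, resp),
        message=str(best.message),
        options=dict(opts),
    )


def _wald_se(
    params: PDParams,
    binary,
    rel_step: float = 1e-4,
    groups: Optional[np.ndarray] = None,
) -> np.ndarray:
    """SEs on the natural scale from the finite-difference Hessian.

    With ``groups``, returns cluster-robust sandwich SEs
    ``sqrt(diag(H^-1 J H^-1))`` where ``J`` sums outer products of
    per-cluster score vectors; otherwise plain ``sqrt(diag(H^-1))``.
    """
    thr, ce, resp = _as_arrays(binary)
    x0 = np.array(list(params.ce50) + [params.gamma])

    def f(x):
        try:
            p = PDParams(ce50=tuple(x[:4]), gamma=x[4])
        except ValueError:
            return np.inf
        return neg_log_likelihood(p, (thr, ce, resp))

    n = 5
    h = rel_step * np.abs(x0)
    hess = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x0.copy(), x0.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                hess[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                hess[i, j] = hess[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4.0 * h[i] * h[j]
                )
    try:
        hinv = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)
    if groups is not None:
        rows = _natural_score_rows(params, thr, ce, resp)
        codes = np.asarray(groups)
        order = np.argsort(codes, kind="stable")
        sums = np.add.reduceat(
            rows[order], np.searchsorted(codes[order], np.unique(codes))
        )
        j_mat = sums.T @ sums
        cov = hinv @ j_mat @ hinv
    else:
        cov = hinv
    var = np.diag(cov)
    se = np.sqrt(np.where(var > 0, var, np.nan))
    return se


def wald_ci(estimate: float, rse_percent: float) -> Tuple[float, float]:
    """95% Wald interval from an estimate and its relative standard error.

    Reproduces the display arithmetic ``estimate * (1 +/- 1.96 * RSE/100)``,
    rounded to two decimals.
    """
    estimate = float(estimate)
    rse_percent = float(rse_percent)
    if estimate <= 0:
        raise ValueError(f"estimate must be > 0, got {estimate}")
    if rse_percent < 0:
        raise ValueError(f"rse_percent must be >= 0, got {rse_percent}")
    half = Z_95 * rse_percent / 100.0
    return (round(estimate * (1.0 - half), 2), round(estimate * (1.0 + half), 2))
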