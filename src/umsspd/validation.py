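"""Internal validation and agreement metrics.

* subject-resampling (nonparametric) bootstrap percentile intervals,
* prediction probability Pk = (Somers' d + 1) / 2 with jackknife or
  bootstrap confidence intervals,
* percent-scale Bland-Altman agreement between two concentration series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dataset_io import SedationDataset, binary_from_observations
from .estimation import IdentifiabilityError, fit_binary_arrays, fit_mle

__all__ = [
    "BootstrapResult",
    "AgreementResult",
    "bootstrap_ci",
    "prediction_probability",
    "pk_confidence_interval",
    "bland_altman_percent",
]

#: Default seed used when callers do not supply one.
DEFAULT_SEED = 20210909

PARAM_NAMES = ("ce50_1", "ce50_2", "ce50_3", "ce50_4", "gamma")


@dataclass
class BootstrapResult:
    """Subject-resampling bootstrap distribution of the five estimates."""

    replicates: np.ndarray  # (n_converged, 5), converged replicates only
    median: np.ndarray  # (5,)
    percentiles: np.ndarray  # (5, 2): 2.5th and 97.5th
    n_requested: int
    n_converged: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "param_names": list(PARAM_NAMES),
            "median": [float(v) for v in self.median],
            "percentile_2_5": [float(v) for v in self.percentiles[:, 0]],
            "percentile_97_5": [float(v) for v in self.percentiles[:, 1]],
            "n_requested": int(self.n_requested),
            "n_converged": int(self.n_converged),
            "seed": int(self.seed),
        }


@dataclass
class AgreementResult:
    """Percent-scale Bland-Altman summary of two paired series."""

    bias_percent: float
    loa_lower: float
    loa_upper: float
    bias_ci95: Tuple[float, float]
    n_pairs: int
    n_excluded: int = 0

    def as_dict(self) -> dict:
        return {
            "bias_percent": self.bias_percent,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "bias_ci95": list(self.bias_ci95),
            "n_pairs": self.n_pairs,
            "n_excluded": self.n_excluded,
        }


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(
    dataset: SedationDataset,
    n_reps: int,
    seed: int = DEFAULT_SEED,
    fit_options: Optional[dict] = None,
    init: "PDParams | str" = "auto",
) -> BootstrapResult:
    """Percentile bootstrap by resampling subjects with replacement.

    Each replicate draws ``n_subjects`` subject IDs with replacement;
    duplicated subjects receive distinct synthetic IDs so refitting treats
    them as independent individuals.  Replicates whose fit fails or does
    not converge are excluded and counted; more than 20% failures emits a
    warning.  ``fit_options`` is forwarded to :func:`~umsspd.estimation.fit_mle`
    (bootstrap refits default to a single start for speed).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if dataset.n_subjects < 2:
        warnings.warn("bootstrap over fewer than 2 subjects is degenerate", UserWarning)
    opts = {"n_starts": 1, "compute_se": False}
    opts.update(fit_options or {})

    rng = np.random.default_rng(seed)
    ids = dataset.subject_ids
    # pre-expand each subject's binary arrays once; resampling with
    # replacement then just concatenates blocks (duplicated subjects act
    # as distinct individuals, which pooled ML treats identically anyway)
    blocks = {
        sid: binary_from_observations(SedationDataset(dataset.for_subject(sid)))
        for sid in ids
    }
    n_obs_by_id = {sid: len(dataset.for_subject(sid)) for sid in ids}

    estimates: List[np.ndarray] = []
    n_failed = 0
    for _ in range(int(n_reps)):
        chosen = rng.choice(len(ids), size=len(ids), replace=True)
        thr = np.concatenate([blocks[ids[i]][0] for i in chosen])
        ce = np.concatenate([blocks[ids[i]][1] for i in chosen])
        resp = np.concatenate([blocks[ids[i]][2] for i in chosen])
        n_obs = sum(n_obs_by_id[ids[i]] for i in chosen)
        try:
            fit = fit_binary_arrays(
                (thr, ce, resp),
                n_obs=n_obs,
                n_subjects=len(ids),
                init=init,
                options=opts,
            )
        except IdentifiabilityError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        estimates.append(fit.estimates)

    if n_failed > 0.2 * n_reps:
        warnings.warn(
            f"{n_failed}/{n_reps} bootstrap replicates failed to converge",
            UserWarning,
        )
    if not estimates:
        raise RuntimeError("no bootstrap replicate converged")
    reps = np.vstack(estimates)
    return BootstrapResult(
        replicates=reps,
        median=np.median(reps, axis=0),
        percentiles=np.percentile(reps, [2.5, 97.5], axis=0).T,
        n_requested=int(n_reps),
        n_converged=len(estimates),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# prediction probability (Pk)


def _pk_counts(observed: np.ndarray, predictor: np.ndarray):
    """Pairwise concordant / discordant / predictor-tied counts.

    Only pairs with distinct observed scores count; pairs tied on the
    predictor contribute to ``T``.  Returns per-observation row sums as
    well, for jackknifing.
    """
    o = observed[:, None] - observed[None, :]
    p = predictor[:, None] - predictor[None, :]
    informative = o != 0
    so = np.sign(o)
    sp = np.sign(p)
    conc = informative & (so * sp > 0)
    disc = informative & (so * sp < 0)
    tied = informative & (sp == 0)
    # each unordered pair appears twice in the full matrices
    c_rows = conc.sum(axis=1)
    d_rows = disc.sum(axis=1)
    t_rows = tied.sum(axis=1)
    return (
        c_rows.sum() / 2.0,
        d_rows.sum() / 2.0,
        t_rows.sum() / 2.0,
        c_rows,
        d_rows,
        t_rows,
    )


def _pk_from_counts(c: float, d: float, t: float) -> float:
    tot = c + d + t
    if tot == 0:
        raise ValueError("all observed scores are identical; Pk is undefined")
    return (c + 0.5 * t) / tot


def prediction_probability(observed: Sequence[int], predictor: Sequence[float]) -> float:
    """Pk = (Somers' d + 1)/2 of a real-valued index against ordinal scores.

    Over all pairs with distinct observed scores, counts concordant (C),
    discordant (D) and predictor-tied (T) pairs and returns
    ``(C + T/2) / (C + D + T)``: 1 for perfect agreement, 0.5 for a random
    relationship, 0 for complete reversal.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predictor, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predictor must be equal-length 1-D sequences")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    c, d, t, *_ = _pk_counts(obs, pred)
    return _pk_from_counts(c, d, t)


def pk_confidence_interval(
    observed: Sequence[int],
    predictor: Sequence[float],
    method: str = "jackknife",
    seed: int = DEFAULT_SEED,
    n_boot: int = 2000,
) -> Tuple[float, float]:
    """95% CI for Pk by delete-1 jackknife (default) or bootstrap percentile."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predictor, dtype=float)
    n = obs.size
    if n < 3:
        raise ValueError("need at least 3 observations for a Pk interval")
    pk = prediction_probability(obs, pred)

    if method == "jackknife":
        c, d, t, c_rows, d_rows, t_rows = _pk_counts(obs, pred)
        pk_i = np.empty(n)
        for i in range(n):
            pk_i[i] = _pk_from_counts(c - c_rows[i], d - d_rows[i], t - t_rows[i])
        mean_i = pk_i.mean()
        var = (n - 1) / n * np.sum((pk_i - mean_i) ** 2)
        half = 1.96 * np.sqrt(var)
        return (max(0.0, pk - half), min(1.0, pk + half))

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(int(n_boot)):
            idx = rng.integers(0, n, size=n)
            try:
                vals.append(prediction_probability(obs[idx], pred[idx]))
            except ValueError:  # degenerate resample
                continue
        if not vals:
            raise RuntimeError("all bootstrap resamples were degenerate")
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return (float(lo), float(hi))

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Bland-Altman


def bland_altman_percent(
    reference: Sequence[float], comparator: Sequence[float]
) -> AgreementResult:
    """Percent-scale Bland-Altman agreement between paired series.

    Per-pair difference is ``100 * (reference - comparator) / pairwise mean``
    (reference higher => positive bias).  Pairs whose mean is 0 are excluded
    and counted.  Limits of agreement are ``bias +/- 1.96 SD``; the bias CI
    is ``bias +/- 1.96 SD / sqrt(n)``.
    """
    ref = np.asarray(reference, dtype=float)
    comp = np.asarray(comparator, dtype=float)
    if ref.shape != comp.shape or ref.ndim != 1:
        raise ValueError("series must be equal-length 1-D sequences")
    if ref.size < 2:
        raise ValueError("need at least 2 pairs")
    mean = 0.5 * (ref + comp)
    keep = mean != 0.0
    n_excluded = int(np.sum(~keep))
    diff = 100.0 * (ref[keep] - comp[keep]) / mean[keep]
    n = diff.size
    if n < 2:
        raise ValueError("fewer than 2 usable pairs after excluding zero-mean pairs")
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    half_loa = 1.96 * sd
    half_ci = 1.96 * sd / np.sqrt(n)
    return AgreementResult(
        bias_percent=bias,
        loa_lower=bias - half_loa,
        loa_upper=bias + half_loa,
        bias_ci95=(bias - half_ci, bias + half_ci),
        n_pairs=n,
        n_excluded=n_excluded,
    )
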