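"""Data model and text I/O for sedation observations and infusion logs.

Observation files are plain CSV with NONMEM-style headers ``ID,TIME,CE,DV``
(DV = UMSS score; an optional ``MDV`` column marks rows to skip when 1).
Infusion logs are CSV with ``ID,TIME,RATE`` defining piecewise-constant
rates.  Configuration files are YAML or JSON with a ``model`` section
(``ce50`` list + ``gamma``), optional ``pk``, ``protocol``, ``fit`` and
``seed`` entries.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core_model import PDParams

__all__ = [
    "ObservationRecord",
    "BinaryRecord",
    "SedationDataset",
    "InfusionLog",
    "DatasetParseError",
    "NonMonotoneScoreWarning",
    "expand_to_binary",
    "binary_from_observations",
    "select_modeling_points",
    "read_dataset",
    "write_dataset",
    "read_infusion_log",
    "write_infusion_log",
    "load_config",
    "pd_params_from_config",
]

THRESHOLDS = (1, 2, 3, 4)


class DatasetParseError(ValueError):
    """Malformed dataset file; message carries the offending line number."""


class NonMonotoneScoreWarning(UserWarning):
    """Observed scores decrease over time within a subject."""


@dataclass(frozen=True)
class ObservationRecord:
    """One (Ce, UMSS) pair for a subject at a given time (seconds)."""

    subject_id: str
    time: float
    ce: float
    umss: int

    def __post_init__(self) -> None:
        if not (self.time >= 0.0 and np.isfinite(self.time)):
            raise ValueError(f"time must be finite and >= 0, got {self.time}")
        if not (self.ce >= 0.0 and np.isfinite(self.ce)):
            raise ValueError(f"ce must be finite and >= 0, got {self.ce}")
        if self.umss not in (0, 1, 2, 3, 4):
            raise ValueError(f"umss must be in 0..4, got {self.umss}")


@dataclass(frozen=True)
class BinaryRecord:
    """Threshold-expanded binary response: R = 1 iff umss >= threshold."""

    subject_id: str
    threshold: int
    ce: float
    response: int

    def __post_init__(self) -> None:
        if self.threshold not in THRESHOLDS:
            raise ValueError(f"threshold must be in 1..4, got {self.threshold}")
        if self.response not in (0, 1):
            raise ValueError(f"response must be 0 or 1, got {self.response}")


class SedationDataset:
    """Ordered collection of observations with by-subject access."""

    def __init__(self, records: Iterable[ObservationRecord]):
        self.records: List[ObservationRecord] = list(records)
        if not self.records:
            raise ValueError("dataset must contain at least one record")
        seen = set()
        index: Dict[str, List[int]] = {}
        for i, rec in enumerate(self.records):
            key = (rec.subject_id, rec.time)
            if key in seen:
                raise ValueError(f"duplicate (subject_id, time) pair: {key}")
            seen.add(key)
            index.setdefault(rec.subject_id, []).append(i)
        self._index = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, SedationDataset) and self.records == other.records

    @property
    def subject_ids(self) -> List[str]:
        return list(self._index)

    @property
    def n_subjects(self) -> int:
        return len(self._index)

    def for_subject(self, subject_id: str) -> List[ObservationRecord]:
        return [self.records[i] for i in self._index[subject_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ID": [r.subject_id for r in self.records],
                "TIME": [r.time for r in self.records],
                "CE": [r.ce for r in self.records],
                "DV": [r.umss for r in self.records],
            }
        )


@dataclass
class InfusionLog:
    """Piecewise-constant infusion for one subject.

    ``events`` is an ordered list of ``(time_seconds, rate)`` pairs; each
    rate holds from its time until the next event (the final rate holds
    indefinitely).  Rates are in mass/min, matching the PK rate constants.
    """

    subject_id: str
    events: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(r < 0 for _, r in self.events):
            raise ValueError("rates must be >= 0")

    def rate_at(self, t: float) -> float:
        rate = 0.0
        for et, er in self.events:
            if et <= t:
                rate = er
            else:
                break
        return rate


# ---------------------------------------------------------------------------
# binary expansion


def expand_to_binary(dataset: SedationDataset) -> List[BinaryRecord]:
    """Expand each observation into 4 binary records (thresholds 1..4)."""
    out: List[BinaryRecord] = []
    for rec in dataset:
        for n in THRESHOLDS:
            out.append(
                BinaryRecord(
                    subject_id=rec.subject_id,
                    threshold=n,
                    ce=rec.ce,
                    response=int(rec.umss >= n),
                )
            )
    return out


def binary_from_observations(dataset: SedationDataset):
    """Vectorized expansion: arrays (threshold, ce, response), length 4*n_obs."""
    umss = np.array([r.umss for r in dataset])
    ce = np.array([r.ce for r in dataset])
    thr = np.tile(np.array(THRESHOLDS), len(umss))
    ce4 = np.repeat(ce, 4)
    resp = (np.repeat(umss, 4) >= thr).astype(float)
    return thr, ce4, resp


# ---------------------------------------------------------------------------
# modeling-point selection


def select_modeling_points(
    trajectory: Sequence[ObservationRecord], eval_step: float = 20.0
) -> List[ObservationRecord]:
    """Select the modeling points from one subject's observation series.

    Selected points are: (a) the start of infusion; (b) the first
    observation at which each score 1..4 is attained; (c) for each
    maintained score 0..3, the observation at the midpoint of its
    maintenance period, snapped to the latest observation at or before the
    midpoint; (d) the observation ``eval_step`` seconds after score 4 is
    attained (omitted with a warning when unavailable).  At most 10 points
    result.  A decreasing score sequence triggers
    :class:`NonMonotoneScoreWarning`; selection then runs on the running
    maximum of the scores.
    """
    records = list(trajectory)
    if not records:
        raise ValueError("trajectory must be non-empty")
    times = [r.time for r in records]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("trajectory times must be strictly increasing")
    raw = np.array([r.umss for r in records])
    scores = np.maximum.accumulate(raw)
    if np.any(raw != scores):
        warnings.warn(
            f"non-monotone score sequence for subject "
            f"{records[0].subject_id}; using running maximum for selection",
            NonMonotoneScoreWarning,
        )

    selected_idx = {0}  # start of infusion

    # first attainment index of each level present
    attain: Dict[int, int] = {}
    for level in range(int(scores[0]), -1, -1):
        attain[level] = 0
    for i in range(1, len(records)):
        if scores[i] > scores[i - 1]:
            for level in range(int(scores[i - 1]) + 1, int(scores[i]) + 1):
                attain[level] = i
    for level in (1, 2, 3, 4):
        if level in attain:
            selected_idx.add(attain[level])

    t_arr = np.array(times)
    max_level = int(scores[-1])
    # midpoint of each maintained period, scores 0..3
    for level in range(0, min(max_level, 3) + 1):
        if level not in attain:
            continue
        start_t = times[attain[level]]
        if level + 1 <= max_level:
            nxt = min(l for l in attain if l > level)
            end_t = times[attain[nxt]]
        else:
            end_t = times[-1]
        mid = 0.5 * (start_t + end_t)
        # latest observation at or before the midpoint, within the period
        cand = np.nonzero((t_arr >= start_t) & (t_arr <= mid))[0]
        if cand.size:
            selected_idx.add(int(cand[-1]))

    # point eval_step seconds after score 4 is attained
    if 4 in attain:
        t4 = times[attain[4]]
        after = np.nonzero(t_arr >= t4 + eval_step)[0]
        if after.size:
            selected_idx.add(int(after[0]))
        else:
            warnings.warn(
                f"subject {records[0].subject_id}: no observation "
                f"{eval_step:g} s after reaching score 4; point omitted",
                UserWarning,
            )

    return [records[i] for i in sorted(selected_idx)]


# ---------------------------------------------------------------------------
# readers / writers


def _fmt(x: float) -> str:
    return repr(float(x)) if not float(x).is_integer() else str(int(x))


def read_dataset(path) -> SedationDataset:
    """Read a CSV observation file with columns ID,TIME,CE,DV (+optional MDV)."""
    path = Path(path)
    records: List[ObservationRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetParseError(f"{path}: empty file") from None
        header = [h.strip().upper() for h in header]
        for col in ("ID", "TIME", "CE", "DV"):
            if col not in header:
                raise DatasetParseError(f"{path}: missing column {col!r}")
        idx = {c: header.index(c) for c in header}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if "MDV" in idx and row[idx["MDV"]].strip() == "1":
                continue
            try:
                time = float(row[idx["TIME"]])
                ce = float(row[idx["CE"]])
                dv = float(row[idx["DV"]])
            except (ValueError, IndexError) as exc:
                raise DatasetParseError(f"{path}: line {lineno}: {exc}") from None
            if dv != int(dv) or not 0 <= dv <= 4:
                raise DatasetParseError(
                    f"{path}: line {lineno}: DV must be an integer in 0..4, got {row[idx['DV']]}"
                )
            try:
                records.append(
                    ObservationRecord(row[idx["ID"]].strip(), time, ce, int(dv))
                )
            except ValueError as exc:
                raise DatasetParseError(f"{path}: line {lineno}: {exc}") from None
    if not records:
        raise DatasetParseError(f"{path}: no data rows")
    return SedationDataset(records)


def write_dataset(dataset: SedationDataset, path) -> None:
    """Write observations as CSV ID,TIME,CE,DV; round-trips exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ID", "TIME", "CE", "DV"])
        for r in dataset:
            writer.writerow([r.subject_id, _fmt(r.time), _fmt(r.ce), r.umss])


def read_infusion_log(path) -> List[InfusionLog]:
    """Read CSV ID,TIME,RATE into one InfusionLog per subject."""
    path = Path(path)
    events: Dict[str, List[Tuple[float, float]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = [h.strip().upper() for h in next(reader)]
        for col in ("ID", "TIME", "RATE"):
            if col not in header:
                raise DatasetParseError(f"{path}: missing column {col!r}")
        idx = {c: header.index(c) for c in header}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                t = float(row[idx["TIME"]])
                rate = float(row[idx["RATE"]])
            except (ValueError, IndexError) as exc:
                raise DatasetParseError(f"{path}: line {lineno}: {exc}") from None
            events.setdefault(row[idx["ID"]].strip(), []).append((t, rate))
    return [InfusionLog(sid, evts) for sid, evts in events.items()]


def write_infusion_log(logs: Iterable[InfusionLog], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ID", "TIME", "RATE"])
        for log in logs:
            for t, rate in log.events:
                writer.writerow([log.subject_id, _fmt(t), _fmt(rate)])


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return cfg


def pd_params_from_config(cfg: dict) -> PDParams:
    """Extract model parameters from a config mapping."""
    try:
        model = cfg["model"]
        return PDParams(ce50=tuple(model["ce50"]), gamma=float(model["gamma"]))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"config missing model.ce50/model.gamma: {exc}") from None
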