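import numpy as np
import pytest

from umsspd.core_model import PDParams
from umsspd.dataset_io import ObservationRecord, SedationDataset
from umsspd.simulation import DEFAULT_PK, StudyDesign, effect_site_step_protocol


#: Published point estimates used throughout as reference/ground truth.
REF_CE50 = (1.84, 2.64, 3.98, 4.78)
REF_GAMMA = 5.76
REF_ESTIMATES = np.array([*REF_CE50, REF_GAMMA])


@pytest.fixture(scope="session")
def ref_params() -> PDParams:
    return PDParams(ce50=REF_CE50, gamma=REF_GAMMA)


@pytest.fixture(scope="session")
def protocol():
    """The default step-up TCI protocol, computed once per session."""
    return effect_site_step_protocol(DEFAULT_PK, StudyDesign())


@pytest.fixture
def tiny_dataset() -> SedationDataset:
    return SedationDataset(
        [
            ObservationRecord("A", 0.0, 0.0, 0),
            ObservationRecord("A", 60.0, 1.5, 1),
            ObservationRecord("A", 120.0, 3.0, 2),
            ObservationRecord("B", 0.0, 0.0, 0),
            ObservationRecord("B", 60.0, 2.5, 2),
            ObservationRecord("B", 120.0, 5.0, 4),
        ]
    )


def staircase_trajectory(
    subject_id: str,
    increments: dict,
    t_end: float,
    eval_step: float = 20.0,
    ce_of_t=None,
):
    """Build a monotone observation series with scores stepping at given times."""
    if ce_of_t is None:
        ce_of_t = lambda t: t / 100.0
    times = np.arange(0.0, t_end + 1e-9, eval_step)
    records = []
    for t in times:
        score = 0
        for s, ts in increments.items():
            if t >= ts:
                score = max(score, s)
        records.append(ObservationRecord(subject_id, float(t), float(ce_of_t(t)), score))
    return records
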