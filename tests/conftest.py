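import numpy as np
import pytest

from spaclust.records import TIMESERIES_PARAMS, TimeSeriesRecord
from spaclust.synthetic import ProtocolSpec

#: the designated best feature combination used across fixtures
BEST_COMBO = ("HHb-PFC", "O2Hb-VC", "PETCO2", "SC", "SpO2")


@pytest.fixture
def four_point_instance():
    """1-D points (0, 1, 10, 11) with labels (A, A, B, B): every index is
    hand-computable (mean silhouette ~0.8997, CH = 200, DB = 0.1)."""
    points = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = np.array([0, 0, 1, 1])
    return points, labels


def make_blobs_tight(n_per=10, k=3, spread=0.1, gap=10.0, d=2, seed=0):
    """Well-separated tight Gaussian blobs on a line of centers."""
    rng = np.random.default_rng(seed)
    centers = np.zeros((k, d))
    centers[:, 0] = np.arange(k) * gap
    pts = np.concatenate([
        rng.normal(centers[j], spread, size=(n_per, d)) for j in range(k)
    ])
    labels = np.repeat(np.arange(k), n_per)
    return pts, labels


@pytest.fixture
def blobs3():
    return make_blobs_tight(k=3, seed=1)


def make_record(samples, parameter="SC", sampling_rate=1.0,
                phase_bounds=(0.0, 480.0, 1020.0, 1920.0),
                subject_id="s01", condition="blue"):
    return TimeSeriesRecord(
        subject_id=subject_id, condition=condition, parameter=parameter,
        sampling_rate=sampling_rate, samples=np.asarray(samples, float),
        phase_bounds=phase_bounds,
    )


def constant_record(value=5.0, **kw):
    protocol = ProtocolSpec()
    n = int(protocol.total_duration) + 1
    return make_record(np.full(n, value), **kw)
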