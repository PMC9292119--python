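import numpy as np
import pandas as pd
import pytest

from gcomprisk import AnalysisSpec, build_cohort


def two_group_binary_frame() -> pd.DataFrame:
    """30/100 events exposed vs 20/100 unexposed."""
    rows = []
    for a, events, n in ((1, 30, 100), (0, 20, 100)):
        rows += [(a, 1)] * events + [(a, 0)] * (n - events)
    return pd.DataFrame(rows, columns=["exposed", "event"])


@pytest.fixture
def two_group_binary():
    return build_cohort(two_group_binary_frame())


@pytest.fixture
def two_group_rate():
    """15 events/500 person-days exposed vs 10 events/800 unexposed.

    One row per group carrying the aggregate count and person-time: a
    two-group Poisson model with offset fits crude rates exactly, so the
    group structure is all that matters.
    """
    df = pd.DataFrame(
        {
            "exposed": [1, 1, 0, 0],
            "events": [8, 7, 6, 4],
            "persondays": [250.0, 250.0, 400.0, 400.0],
        }
    )
    return build_cohort(df, {"events": "numeric"})


#: binary A, binary W, both outcomes present in every (A, W) cell, so the
#: additive logistic MLE is finite (no separation)
LOGISTIC_ROWS = [
    (0, 0, 0), (0, 0, 0), (0, 0, 1),
    (0, 1, 0), (0, 1, 1),
    (1, 0, 0), (1, 0, 1),
    (1, 1, 0), (1, 1, 1), (1, 1, 1),
]


@pytest.fixture
def small_logistic():
    df = pd.DataFrame(LOGISTIC_ROWS, columns=["a", "w", "y"])
    return build_cohort(df)


@pytest.fixture
def binary_spec():
    return AnalysisSpec(
        outcome_name="event",
        exposure_name="exposed",
        outcome_type="binary",
        n_boot=20,
        seed=0,
    )


def newton_logistic(X: np.ndarray, y: np.ndarray, maxiter: int = 60) -> np.ndarray:
    """Independent ML oracle: Newton-Raphson on the logistic log-likelihood."""
    b = np.zeros(X.shape[1])
    for _ in range(maxiter):
        p = 1.0 / (1.0 + np.exp(-(X @ b)))
        step = np.linalg.solve(X.T @ (X * (p * (1 - p))[:, None]), X.T @ (y - p))
        b = b + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return b
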