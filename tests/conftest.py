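import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glycotrial import AnalysisConfig, GlucoseSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def series_factory():
    """Build a capillary GlucoseSeries from (times, values)."""

    def make(times, values, patient_id="P001"):
        return GlucoseSeries(patient_id, times, values, "capillary")

    return make


def naive_gli(times_h, values_mgdl, max_pair_gap_h=12.0, mgdl_per_mmol=18.0182):
    """Independent pairwise-loop oracle for the daily lability index.

    Mirrors the printed construction term by term: convert to mmol/L, walk
    consecutive pairs, drop pairs whose gap exceeds the cutoff, count the
    readings left participating, divide each squared difference by
    (N-1) * gap.  Deliberately scalar/loop-based.
    """
    mmol = [v / mgdl_per_mmol for v in values_mgdl]
    pairs = []
    participating = set()
    for i in range(len(mmol) - 1):
        gap = times_h[i + 1] - times_h[i]
        if gap <= max_pair_gap_h:
            pairs.append((mmol[i] - mmol[i + 1], gap))
            participating.update((i, i + 1))
    n = len(participating)
    if n < 2:
        return 0.0
    return sum(d * d / ((n - 1) * g) for d, g in pairs)


@pytest.fixture
def gli_oracle():
    return naive_gli


def random_irregular_series(rng: np.random.Generator, n_max=40, day_span_h=24.0):
    """One day's worth of irregularly spaced readings."""
    n = int(rng.integers(2, n_max))
    gaps = rng.uniform(0.1, 5.0, size=n - 1)
    t = np.concatenate([[float(rng.uniform(0, 1))], gaps]).cumsum()
    t = t[t < day_span_h]
    if t.size < 2:
        t = np.array([0.5, 2.5])
    v = rng.uniform(45.0, 380.0, size=t.size)
    return t, v
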