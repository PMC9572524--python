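import numpy as np
import pytest
from hypothesis import settings

from prrx import Segment, build_grid

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

DELTA_128 = 1000.0 / 128.0


@pytest.fixture(scope="session")
def grid128():
    return build_grid(128, 25)


def make_segment(rr_ms, fs=128.0, label="SR", gap_after=None,
                 quantize=False, record_id="toy", start_time_ms=0.0):
    """Build a Segment from raw RR values (optionally snapped to the
    sampling grid)."""
    rr = np.asarray(rr_ms, dtype=float)
    if quantize:
        delta = 1000.0 / fs
        rr = np.maximum(np.rint(rr / delta), 1.0) * delta
    return Segment(record_id=record_id, start_time_ms=start_time_ms,
                   label=label, fs=fs, rr_ms=rr, gap_after=gap_after)


def random_segment(rng, fs=128.0, n_min=5, n_max=120, label=None):
    """A random quantized segment: heterogeneous length, scale and
    variability, occasional gaps."""
    n = int(rng.integers(n_min, n_max + 1))
    mean = rng.uniform(400, 1200)
    sd = rng.uniform(5, 250)
    rr = np.clip(rng.normal(mean, sd, size=n), 250, 2900)
    gaps = rng.random(n) < rng.uniform(0, 0.2)
    gaps[-1] = False
    if gaps[:-1].all():  # keep at least one valid pair
        gaps[int(rng.integers(0, n - 1))] = False
    return make_segment(rr, fs=fs, label=label or rng.choice(["SR", "AF"]),
                        gap_after=gaps, quantize=True)


@pytest.fixture(scope="session")
def small_cohort_table(grid128):
    """Feature table from a small heterogeneous synthetic cohort."""
    from prrx import feature_matrix, generate_cohort, segment_series

    cohort = generate_cohort(n_sr=25, n_af=25, duration_s=60.0, seed=1234)
    segments, _ = segment_series(cohort)
    return feature_matrix(segments, grid128)
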