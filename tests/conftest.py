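import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from evquant import FieldSpec, simulate_field


@pytest.fixture
def rng():
    return np.random.default_rng(20250927)


@pytest.fixture
def quiet_spec():
    """Small noise-free field: 12 well-separated spots, exact identities hold."""
    return FieldSpec(
        width=192,
        height=192,
        n_evs=12,
        shot_noise=False,
        read_noise_sigma=0.0,
        min_separation=14.0,
        seed=11,
    )


@pytest.fixture
def quiet_field(quiet_spec):
    return simulate_field(quiet_spec)


@pytest.fixture
def noisy_field():
    """Default camera model at reduced size, for statistical checks."""
    return simulate_field(FieldSpec(width=256, height=256, n_evs=60, seed=3))


def triangle_oracle_bin(counts) -> int:
    """Brute-force triangle threshold: exhaustive point-to-chord distance scan.

    Integer arithmetic on the unnormalized cross product, so comparisons
    are exact; ties resolved toward the bin nearest the peak, then lower.
    """
    counts = np.asarray(counts)
    nz = np.flatnonzero(counts)
    assert len(nz) >= 2
    b_p = int(np.argmax(counts))
    left, right = int(nz[0]), int(nz[-1])
    b_e = right if (right - b_p) >= (b_p - left) else left
    lo, hi = min(b_p, b_e), max(b_p, b_e)
    dx = b_e - b_p
    dy = int(counts[b_e]) - int(counts[b_p])
    best = None
    for b in range(lo + 1, hi):
        num = abs(dx * (int(counts[b]) - int(counts[b_p])) - dy * (b - b_p))
        key = (-num, abs(b - b_p), b)
        if best is None or key < best[0]:
            best = (key, b)
    assert best is not None
    return best[1]
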