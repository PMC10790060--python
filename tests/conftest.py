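import numpy as np
import pytest

from csecnn import SimulationConfig, make_toy_atlas, simulate_cohort
from csecnn.entropy import CrossSampleEntropy


def cse_bruteforce(x, y, m, r):
    """O(T^2) reference enumeration of template match counts.

    Uses the shared N - m start-position range for both template lengths,
    strict Chebyshev tolerance.  Returns (b_total, a_total, n_templates).
    """
    n = min(len(x), len(y))
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(nt):
            if max(abs(x[i + k] - y[j + k]) for k in range(m)) < r:
                b += 1
                if abs(x[i + m] - y[j + m]) < r:
                    a += 1
    return b, a, nt


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 subjects, 5 ROIs, strong coupling contrast — for CV plumbing."""
    config = SimulationConfig(
        n_rois=5,
        group_sizes=(6, 3, 3),
        effect_rois=(1, 3),
        coupling_ns=0.0,
        coupling_s=0.8,
        seed=7,
    )
    manifest, data = simulate_cohort(config)
    atlas = make_toy_atlas((24, 24, 24), 5, seed=7)
    matrices = {
        sid: CrossSampleEntropy().fit_transform(ts) for sid, ts in data.items()
    }
    return manifest, data, atlas, matrices


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240115)
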