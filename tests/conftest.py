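import numpy as np
import pandas as pd
import pytest

from epiqc import synthetic
from epiqc.types import LABELS, RatingsTable


@pytest.fixture(scope="session")
def small_phantom():
    """A small clean phantom: series, mask, zero trace (plateau 500, sigma 5)."""
    return synthetic.generate_phantom(shape=(24, 24, 14, 50), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_ratings(rng, n_subjects, n_raters, missing_rate=0.0):
    """A uniformly random ratings table, optionally with missing cells."""
    frame = pd.DataFrame(
        rng.choice(LABELS, size=(n_subjects, n_raters)).astype(object),
        index=[f"s{i:03d}" for i in range(n_subjects)],
        columns=[f"r{j}" for j in range(n_raters)],
    )
    if missing_rate:
        drop = rng.random(frame.shape) < missing_rate
        # never empty an entire row
        for i in range(n_subjects):
            if drop[i].all():
                drop[i, rng.integers(n_raters)] = False
        frame = frame.mask(drop)
    return RatingsTable(frame)
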