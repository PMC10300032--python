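import numpy as np
import pandas as pd
import pytest

from mthetqtl.mt_io import PileupTable
from mthetqtl.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample cohort with amplicon pileups, fixed seed."""
    return simulate_cohort(SimConfig(n_samples=60, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """A 400-sample cohort without pileups (truth tables only)."""
    return simulate_cohort(SimConfig(n_samples=400, seed=11, with_pileups=False))


def make_pileup(rows, sample_id="S1", mt_length=16571):
    """rows: list of (position, ref, counts-dict)."""
    return PileupTable(
        sample_id,
        pd.DataFrame(rows, columns=["position", "ref", "counts"]),
        mt_length=mt_length,
    )


def random_pileup(rng, n_sites=40, mt_length=16571, sample_id="S1"):
    """A fuzzed pileup spanning the whole circle, varied fractions/depths."""
    positions = rng.choice(np.arange(1, mt_length + 1), size=n_sites, replace=False)
    rows = []
    for p in sorted(positions):
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        depth = int(rng.integers(0, 400))
        if depth == 0:
            counts = {ref: 0}
        else:
            n_alt = int(rng.binomial(depth, rng.uniform(0, 1)))
            counts = {ref: depth - n_alt}
            if n_alt:
                counts[alt] = n_alt
        rows.append((int(p), ref, counts))
    return make_pileup(rows, sample_id=sample_id, mt_length=mt_length)
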