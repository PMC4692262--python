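import numpy as np
import pandas as pd
import pytest

from nipt21 import (
    CHROMS,
    CohortConfig,
    CountMatrix,
    build_genome_model,
    FragmentLengthModel,
)
from nipt21.cohort import simulate_cohort_counts
from nipt21.genome import HG19_SIZES


def scaled_hg19_table(factor: int = 250) -> dict[str, int]:
    """hg19 chromosome proportions shrunk by an integer factor."""
    return {c: max(HG19_SIZES[c] // factor, 100_000) for c in CHROMS}


@pytest.fixture(scope="session")
def small_genome():
    """All 24 chromosomes at 1/250 scale, 10 kb bins (~6200 bins)."""
    return build_genome_model(scaled_hg19_table(250), bin_size=10_000, gc_seed=0)


@pytest.fixture(scope="session")
def default_lengths():
    return FragmentLengthModel.from_modes()


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    """12 euploid + 4 trisomic samples, 120k raw reads each.

    Depth is scaled for fast unit tests; z-scale assertions that need the
    full-depth regime live in the acceptance tests.
    """
    cfg = CohortConfig(n_euploid=12, n_trisomic=4, n_reads=120_000)
    return simulate_cohort_counts(cfg, small_genome, seed=2024)


def counts_matrix_from_rows(rows: dict[str, np.ndarray]) -> CountMatrix:
    """Build a 24-column count matrix from per-sample 24-vectors."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CHROMS))
    return CountMatrix(data=df, corrected=True)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
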