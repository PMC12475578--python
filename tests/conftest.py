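import numpy as np
import pytest

from epistage import CohortConfig, simulate_cohort


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=200):
    """Random valid interval list for oracle comparisons."""
    from epistage import GenomicInterval
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by the slower integration tests."""
    cfg = CohortConfig(
        n_per_stage={"CTL": 8, "AIS": 8, "MIA": 8, "IAC": 8},
        n_cpgs=2000,
        n_peaks=400,
        n_genes=400,
        planted_effects=__import__("epistage").standard_effects(n_per_category=5),
        n_tfs=8, n_tf_clusters=2, sites_per_tf_dar=7,
        sites_per_tf_background=20,
    )
    return simulate_cohort(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
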