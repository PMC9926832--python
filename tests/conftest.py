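import numpy as np
import pytest

from ulcgwas.impute import HmmParams
from ulcgwas.synthetic_cohort import generate_panel, sample_cohort, simulate_pileups


@pytest.fixture(scope="session")
def small_panel():
    """100 haplotypes, 200 sites over 1 Mbp, 5 founders, near-zero recomb."""
    return generate_panel(100, 200, 1_000_000, 1e-8, seed=42, n_founders=5)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    return sample_cohort(small_panel, 300, sibs_per_family=3, seed=43)


@pytest.fixture(scope="session")
def small_pileup(small_panel, small_cohort):
    return simulate_pileups(small_cohort, small_panel, 0.1, seed=44)


@pytest.fixture(scope="session")
def fast_params():
    return HmmParams(K=5, n_em_iters=8, recomb_rate_bp=1e-10, seed=0)
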