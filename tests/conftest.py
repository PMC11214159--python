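import numpy as np
import pytest

from sweepfoot.coalescent import NullModel, simulate_sfs
from sweepfoot.popgen import DerivedSFS, HaplotypeWindow

# Fixed study-condition seed for the expensive shared simulation.
STUDY_SEED = 20260924

PAPER_NULL = NullModel(n=22, theta_site=7.6e-3, rho_site=2.5e-1,
                       L=2000, reps=10000, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def paper_null_reps():
    """10,000 neutral SFS replicates at the study's null configuration
    (n = 22, theta = 7.6e-3/site, rho = 2.5e-1/site, L = 2000)."""
    return simulate_sfs(PAPER_NULL)


@pytest.fixture()
def rng():
    return np.random.default_rng(STUDY_SEED)


def window_from_locus(locus) -> HaplotypeWindow:
    return HaplotypeWindow(locus.sequences, locus.ancestral)


def random_sfs(rng, n_max=8, s_max=6) -> DerivedSFS:
    n = int(rng.integers(2, n_max + 1))
    counts = rng.multinomial(int(rng.integers(0, s_max + 1)),
                             np.ones(n - 1) / (n - 1))
    return DerivedSFS.from_counts(n, counts)
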