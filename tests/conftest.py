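import numpy as np
import pytest

from shapesig import fit_binning
from shapesig import simulate as sim


@pytest.fixture(scope="session")
def genome():
    """20 kb single-contig random genome (dict chrom -> sequence)."""
    return sim.make_genome(20_000, gc=0.5, seed=101)


@pytest.fixture(scope="session")
def shape_table():
    """Complete synthetic pentamer shape table honoring forbidden bins."""
    return sim.make_shape_table(seed=102, honor_forbidden=True)


@pytest.fixture(scope="session")
def free_shape_table():
    """Shape table without the forbidden-bin adjustment."""
    return sim.make_shape_table(seed=103, honor_forbidden=False)


@pytest.fixture(scope="session")
def binning(shape_table):
    return fit_binning(shape_table)


@pytest.fixture(scope="session")
def small_catalog(genome):
    """3-signature, 6-sample catalog of 400 mutations each."""
    sigs = sim.make_signatures(3, seed=104)
    expo = sim.make_exposures(6, 3, seed=105)
    records = sim.simulate_catalog(genome, sigs, expo, 400, seed=106)
    return sigs, expo, records


@pytest.fixture
def rng():
    return np.random.default_rng(0)
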