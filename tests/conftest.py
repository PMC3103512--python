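import numpy as np
import pytest

from crmscan import fixtures
from crmscan.conservation import conserve_hits
from crmscan.crm import call_crms
from crmscan.scan import scan_all


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic multi-species dataset (seed 0)."""
    return fixtures.generate()


@pytest.fixture(scope="session")
def fixture_hits(bundle):
    return scan_all(bundle.ref_records.values(), bundle.pwms)


@pytest.fixture(scope="session")
def fixture_conserved(bundle, fixture_hits):
    pwms = {p.matrix_id: p for p in bundle.pwms}
    return conserve_hits(fixture_hits, pwms, bundle.blocks,
                         bundle.species_records)


@pytest.fixture(scope="session")
def fixture_crms(fixture_conserved):
    return call_crms(fixture_conserved)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
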