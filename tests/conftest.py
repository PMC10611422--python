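import numpy as np
import pytest

from methindex.amplicon import (
    DEFAULT_TEMPLATE,
    AmpliconTemplate,
    build_site_map,
)


@pytest.fixture(scope="session")
def template():
    return DEFAULT_TEMPLATE


@pytest.fixture(scope="session")
def site_map(template):
    return template.site_map


@pytest.fixture(scope="session")
def toy_template():
    """Tiny primerless template: 5 CpG sites, 3 controls, easy to enumerate."""
    seq = "ATACGTTCATACGTACGATCATTACGTTACGATCT"
    t = AmpliconTemplate(name="toy", sequence=seq)
    sm = build_site_map(seq)
    assert sm.n_cpg == 5 and sm.n_controls == 3
    return t


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_917)
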