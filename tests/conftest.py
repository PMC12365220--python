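import warnings

import pytest

from abcdiv.codon_core import allowed_codons
from abcdiv.io import packaged_mouse_usage, packaged_restriction_sites


@pytest.fixture(scope="session")
def usage():
    return packaged_mouse_usage()


@pytest.fixture(scope="session")
def motifs():
    return packaged_restriction_sites()


@pytest.fixture(scope="session")
def greedy_map(usage):
    # bias 1.0 collapses every family to its most abundant codon
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return allowed_codons(usage, 1.0)


@pytest.fixture(autouse=True)
def _quiet_fallback_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
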