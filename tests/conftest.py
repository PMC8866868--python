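import numpy as np
import pytest

from snpsnp import default_panel
from snpsnp.panel import HaplotypeGenotype


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def G(text: str) -> HaplotypeGenotype:
    """Shorthand genotype constructor for tests."""
    return HaplotypeGenotype.from_string(text)


# Minor/major genotypes of the published seven-locus informative multiplex
# mixture (minor heterozygous or opposite-homozygous at SNP1).
FIG4_MINOR = {
    "MH8": G("AA-CG"),
    "MH3": G("TC-TC"),
    "MH11": G("CA-TG"),
    "MH13": G("CG-TG"),
    "MH9": G("CA-TG"),
    "MH10": G("CT-GT"),
    "MH12": G("CG-TG"),
}
FIG4_MAJOR = {
    "MH8": G("CG-CG"),
    "MH3": G("CC-CC"),
    "MH11": G("TG-TG"),
    "MH13": G("TG-TG"),
    "MH9": G("CA-CA"),
    "MH10": G("CT-CT"),
    "MH12": G("CG-CA"),
}
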