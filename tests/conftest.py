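import pytest

from starcall.haplotypes import builtin_table
from starcall.observations import Category, SiteGenotype
from starcall.sites import Gene


@pytest.fixture(scope="session")
def d6_table():
    return builtin_table(Gene.CYP2D6)


@pytest.fixture(scope="session")
def c19_table():
    return builtin_table(Gene.CYP2C19)


def genotypes(mapping):
    """Build SiteGenotype lists from {site_label: 'WT'|'HET'|...} dicts."""
    return [SiteGenotype(site, Category(cat)) for site, cat in mapping.items()]
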