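import pytest

from paraspec import datasets, dupfinder, synthetic


@pytest.fixture(scope="session")
def default_truth():
    """The default synthetic inverted-duplication fixture (96% identity,
    1 kb blocks, 6 shared + 3 unique SNPs)."""
    return synthetic.simulate_inverted_duplication(seed=11)


@pytest.fixture(scope="session")
def default_blocks(default_truth):
    return dupfinder.find_inverted_duplications(default_truth.sequence)


@pytest.fixture(scope="session")
def taqman_locus():
    """Synthetic locus carrying the published TaqMan primer footprints."""
    return datasets.synthetic_taqman_locus()


@pytest.fixture(scope="session")
def rs_study():
    """Synthetic 48-sample rs12979860 validation panel."""
    return datasets.synthetic_rs12979860_panel()
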