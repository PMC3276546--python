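import numpy as np
import pytest

from famlr import codis_like_fixture, generate_equifrequent_panel
from famlr.popdata import FrequencyPanel


@pytest.fixture(scope="session")
def str_panel():
    """13 equi-frequent 10-allele loci, n = 200 — the standard STR-like panel."""
    return generate_equifrequent_panel(13, 10, 200)


@pytest.fixture(scope="session")
def fixture_panel():
    """The deterministic built-in 5-population panel."""
    return codis_like_fixture()


@pytest.fixture()
def two_pop_biallelic():
    """Two biallelic populations p = 0.2 vs 0.8, n = 100 each."""
    return FrequencyPanel(
        populations=["A", "B"],
        loci=["L"],
        alleles={"L": ["x", "y"]},
        freqs={
            ("A", "L"): np.array([0.2, 0.8]),
            ("B", "L"): np.array([0.8, 0.2]),
        },
        sizes={"A": 100, "B": 100},
    )


def make_single_locus_panel(freq_map, n=100, pop="X", locus="L"):
    labels = list(freq_map)
    return FrequencyPanel(
        populations=[pop],
        loci=[locus],
        alleles={locus: labels},
        freqs={(pop, locus): np.array([freq_map[a] for a in labels], dtype=float)},
        sizes={pop: n},
    )
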