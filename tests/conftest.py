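import numpy as np
import pytest

from cnavhmm.fixtures import make_scenario, scenario_matrix
from cnavhmm.graph_model import build_canonical


@pytest.fixture(scope="session")
def hwe_graph():
    return build_canonical("hwe_biallelic", alleles=("H131", "R131"))


@pytest.fixture(scope="session")
def cnav_graph():
    return build_canonical("cnav_multiallele", alleles=("A", "B"))


@pytest.fixture(scope="session")
def hwe_scenario():
    """Hardy-Weinberg data at allele frequency 0.3 (387 individuals)."""
    return make_scenario(
        "hwe_biallelic", {"alleles": ("H131", "R131"), "p": 0.3}, N=387, seed=7
    )


@pytest.fixture(scope="session")
def cnav_scenario():
    """Biallelic copy-number scenario with loss and gain loops."""
    return make_scenario(
        "cnav_multiallele",
        {"alleles": ("A", "B"), "loss": 0.2, "gain": 0.1,
         "allele_probs": [0.6, 0.4]},
        N=150,
        seed=11,
    )


def hwe_matrix(g, p):
    return scenario_matrix(
        "hwe_biallelic", g, {"alleles": g.alphabet, "p": p}
    )
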