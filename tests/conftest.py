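import numpy as np
import pytest

from inteinscan.alnio import Alignment
from inteinscan.phylocore import build_model
from inteinscan.simgen import ElementSpec, ScenarioConfig, simulate_scenario


@pytest.fixture(scope="session")
def wag():
    return build_model("WAG")


@pytest.fixture(scope="session")
def wag_g4():
    return build_model("WAG", heterogeneity="G4", gamma_alpha=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230121)


@pytest.fixture()
def toy_alignment():
    rows = {
        "alpha": "MKV-LT",
        "bravo": "MKVALT",
        "casey": "M-VALT",
    }
    return Alignment(ids=list(rows), rows=rows)


@pytest.fixture(scope="session")
def two_element_scenario():
    """16 taxa, one vertically inherited element and one with HGT + homing."""
    cfg = ScenarioConfig(
        n_taxa=16, cluster_sizes=[8, 8], extein_length=300,
        element_specs=[
            ElementSpec("vertical", 60, 100, min_carriers=5, max_carrier_fraction=0.5),
            ElementSpec("mobile", 60, 200, hgt_rate=0.8, min_carriers=5,
                        max_carrier_fraction=0.5,
                        homing_groups=[["T01", "T06", "T11", "T16"]]),
        ],
        seed=11)
    return simulate_scenario(cfg)
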