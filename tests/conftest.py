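import warnings

import numpy as np
import pytest

from vtepanel import SimulationConfig, bundled_panel, generate_cohort
from vtepanel.panel import Panel, VariantDef


@pytest.fixture(scope="session")
def panel38():
    return bundled_panel()


@pytest.fixture(scope="session")
def small_panel():
    """Five-variant panel covering common, rare and deletion alleles."""
    return Panel(
        (
            VariantDef("FGG", "rs2066865", "A", "G", 1.56),
            VariantDef("PROC", "rs146922325", "T", "C", 6.91),
            VariantDef("F5", "rs4524", "C", "T", 0.88),
            VariantDef("ABO", "rs8176719", "C", "-", 1.85),
            VariantDef("TGFB2", "rs57615042", "A", "G", 0.89),
        ),
        name="mini",
    )


@pytest.fixture(scope="session")
def small_config(small_panel):
    return SimulationConfig(
        n_case=30,
        n_control=25,
        panel=small_panel,
        control_eafs={"rs2066865": 0.36, "rs146922325": 0.09, "rs4524": 0.22,
                      "rs8176719": 0.40, "rs57615042": 0.78},
        case_eafs={"rs2066865": 0.52, "rs146922325": 0.16, "rs4524": 0.09,
                   "rs8176719": 0.46, "rs57615042": 0.69},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = generate_cohort(small_config)
    return cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-shaped synthetic cohort: 122 cases / 87 controls, full panel."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, truth = generate_cohort(SimulationConfig(seed=3))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
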