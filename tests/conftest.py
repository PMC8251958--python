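import numpy as np
import pytest

from transglyq import (
    EquilibriumConstants,
    ReactionMix,
    TransglySystem,
    infer_K_donor,
)
from transglyq.synthetic import make_references

# analytical transglycosylation rows: (label, 5-fold conversion, K_product,
# printed 10-fold prediction %)
ANALYTICAL_ROWS = [
    ("1a", 0.305, 9.37, 39.0),
    ("1b", 0.300, 6.07, 40.0),
    ("2a", 0.350, 6.75, 44.0),
    ("2b", 0.330, 4.85, 44.0),
]

FIVEFOLD_MIX = ReactionMix(
    donor_nucleoside_0=5.0, acceptor_base_0=1.0, phosphate_0=0.09
)


@pytest.fixture(scope="session")
def refs():
    """Gaussian-band protonated/deprotonated reference pair on 250-350 nm."""
    return make_references()


@pytest.fixture(scope="session")
def calibrated_1a():
    """Constants of the 2-Se-uridine system with the donor constant
    calibrated from the fivefold-excess equilibrium conversion."""
    kd = infer_K_donor(FIVEFOLD_MIX, K_product=9.37, observed_conversion=0.305)
    return EquilibriumConstants(K_donor=kd, K_product=9.37)


def random_system(rng, loading_range=(0.01, 100.0), k_range=(0.01, 100.0)):
    def loguni(lo, hi):
        return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))

    mix = ReactionMix(
        donor_nucleoside_0=loguni(*loading_range),
        acceptor_base_0=loguni(*loading_range),
        phosphate_0=loguni(*loading_range),
    )
    constants = EquilibriumConstants(
        K_donor=loguni(*k_range), K_product=loguni(*k_range)
    )
    return TransglySystem(mix, constants)
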