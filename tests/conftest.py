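import numpy as np
import pandas as pd
import pytest

from rrnasip import default_config
from rrnasip.simulate import DensityModel, GradientTable, SimTaxon, SimulationConfig


@pytest.fixture
def density():
    return DensityModel()


@pytest.fixture
def config():
    return default_config(seed=42)


@pytest.fixture
def calibration_config():
    """20 equally abundant, unlabeled taxa: the symmetric null community."""
    taxa = tuple(SimTaxon(f"taxon_{i:02d}", "bacteria", 0.05) for i in range(20))
    return SimulationConfig(taxa=taxa, depth=10_000, seed=0)


def make_gradient(counts: dict[str, list[int]], substrate="glucose", isotope="13C",
                  timepoint="8d", fractions=(3, 8)) -> GradientTable:
    """Minimal gradient table holding only the sequenced fractions."""
    df = pd.DataFrame(counts, index=list(fractions)).T
    df.index.name = "taxon"
    return GradientTable(
        counts=df,
        densities=np.array([1.82625, 1.78875][: len(fractions)]),
        substrate=substrate,
        isotope=isotope,
        timepoint=timepoint,
    )


@pytest.fixture
def make_table():
    return make_gradient
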