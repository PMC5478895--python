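import numpy as np
import pandas as pd
import pytest

from factoromics import FactorialDE
from factoromics.synthetic import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study (600 genes, triplicate 2x2, seed 7)."""
    return generate_study(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def rna_model(bundle):
    return FactorialDE.from_counts(bundle.counts, bundle.design)


@pytest.fixture(scope="session")
def rna_fits(rna_model):
    return rna_model.fit()


@pytest.fixture()
def tiny_design():
    """Minimal 2x2 triplicate design."""
    rows = []
    for dga1, nlim in ((0, 0), (0, 1), (1, 0), (1, 1)):
        for rep in (1, 2, 3):
            rows.append(
                {
                    "sample_id": f"s{dga1}{nlim}{rep}",
                    "nlim": nlim,
                    "dga1": dga1,
                    "replicate": rep,
                }
            )
    from factoromics.io import StudyDesign

    return StudyDesign(pd.DataFrame(rows))


def null_config() -> SimulationConfig:
    """Global-null study: no planted coefficients anywhere."""
    return SimulationConfig(coef_values=(0.0, 0.0, 0.0), coef_jitter=0.0, plant_pathway=False)
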