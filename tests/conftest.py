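import numpy as np
import pandas as pd
import pytest

from crossconcord import synthgen
from crossconcord.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def small_pair():
    """A small paired cohort with one planted gain module and mixed DE classes."""
    design = synthgen.SyntheticDesign(
        n_genes=400,
        groups=("control", "withdrawal"),
        n_per_group=8,
        frac_concordant_up=0.1,
        frac_concordant_down=0.1,
        frac_discordant=0.05,
        frac_unique_a=0.05,
        frac_unique_b=0.05,
        modules=(synthgen.ModuleSpec(size=40, r_control=0.2, r_treatment=0.6,
                                     group="withdrawal"),),
        ortholog_coverage=0.9,
    )
    return synthgen.generate_pair(design, design, seed=11)


@pytest.fixture()
def toy_matrix():
    """Four genes, two groups of three samples, hand-readable values."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0, 0.0],
            "s2": [1.0, 5.5, 2.5, 0.1],
            "s3": [1.0, 4.5, 1.5, -0.1],
            "s4": [2.0, 5.0, 4.0, 0.0],
            "s5": [2.0, 5.2, 4.5, 0.2],
            "s6": [2.0, 4.8, 3.5, -0.2],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    samples = pd.DataFrame(
        {
            "group": ["control"] * 3 + ["case"] * 3,
            "sex": ["F", "F", "M", "F", "F", "M"],
            "cohort": ["a"] * 6,
        },
        index=values.columns,
    )
    genes = pd.DataFrame(
        {
            "symbol": values.index,
            "biotype": ["protein_coding", "protein_coding", "lncRNA", "pseudogene"],
        },
        index=values.index,
    )
    return ExpressionMatrix(values, samples, genes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(202409)
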