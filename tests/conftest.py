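import numpy as np
import pandas as pd
import pytest

from stemchrom import SimulationPlan, simulate
from stemchrom.expression import CountMatrix

SMALL_CLASSES = {"brain": 20, "epidermis": 20, "intestine": 20,
                 "neoblast": 20, "constitutive": 30, "unclassified": 30}


@pytest.fixture(scope="session")
def small_plan():
    return SimulationPlan(seed=11, n_genes_per_class=dict(SMALL_CLASSES),
                          fragment_depth=50_000)


@pytest.fixture(scope="session")
def small_genome(small_plan):
    return simulate.generate_genome(small_plan)


@pytest.fixture(scope="session")
def small_atac(small_plan, small_genome):
    genome, truth = small_genome
    return simulate.generate_fragments(small_plan, genome, truth, "ATAC")


def make_counts(counts: dict, lengths=None, isolations=None) -> CountMatrix:
    """Build a CountMatrix from {sample: [counts per gene]} columns."""
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    if lengths is None:
        lengths = pd.Series(1000, index=df.index)
    else:
        lengths = pd.Series(lengths, index=df.index)
    rows = []
    for name in df.columns:
        iso, rep = name.rsplit("_r", 1) if "_r" in name else (name, 1)
        if isolations is not None:
            iso = isolations[name]
        rows.append({"sample": name, "isolation": iso, "replicate": int(rep)})
    return CountMatrix(counts=df, lengths=lengths, samples=pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
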