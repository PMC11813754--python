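import numpy as np
import pandas as pd
import pytest

from isnkit.containers import CountMatrix
from isnkit.simulate import SimulationConfig, generate_cohort


PLANTED = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]


def planted_config(n_taxa=30, n_per_group=40, delta=0.4, seed=1, **kw):
    """Two-group cohort whose planted edges differ in partial correlation by delta."""
    return SimulationConfig(
        n_taxa=n_taxa,
        n_samples_per_group=n_per_group,
        planted_edges=[(i, j, delta) for i, j in PLANTED],
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """30 taxa x 80 samples, 5 planted differential edges, seed 1."""
    return generate_cohort(planted_config())


@pytest.fixture()
def toy_counts():
    """Hand-written 4-sample x 3-taxon table with full metadata."""
    counts = pd.DataFrame(
        [[10, 0, 5], [0, 20, 5], [8, 2, 0], [1, 1, 1]],
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
        columns=["tA", "tB", "tC"],
    )
    taxonomy = pd.DataFrame(
        {"family": ["F1", "F1", "F2"], "genus": ["g1", "g2", "g3"],
         "copy_number": [1.0, 2.0, 1.0]},
        index=pd.Index(["tA", "tB", "tC"], name="taxon"),
    )
    metadata = pd.DataFrame(
        {"outcome": ["remission", "no-remission", "remission", "no-remission"],
         "timepoint": ["w0"] * 4, "cohort": ["CD"] * 4,
         "microbial_load": [1e11, 2e11, 1e11, 1e11],
         "individual_id": ["i1", "i2", "i3", "i4"]},
        index=counts.index,
    )
    return CountMatrix(counts, taxonomy, metadata)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
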