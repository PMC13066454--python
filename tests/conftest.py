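import numpy as np
import pandas as pd
import pytest

from phenocurate import PhenotypeDataset, TRAIT_PRESETS


def make_dataset(rows, trait="PH", traits=None):
    """Build a small dataset from (accession, year, value) triples."""
    df = pd.DataFrame(rows, columns=["accession_number", "year", "value"])
    df["institute_code"] = "XXX001"
    df["genus"] = "Triticum"
    df["trait"] = trait
    return PhenotypeDataset(df, traits=traits or {trait: TRAIT_PRESETS[trait]})


def balanced_frame(I, J, mu=100.0, sg=2.0, sa=1.5, se=1.0, seed=0,
                   first_year=2000):
    """Balanced I x J additive simulation as a long-format DataFrame."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, sg, I)
    a = rng.normal(0, sa, J)
    y = mu + g[:, None] + a[None, :] + rng.normal(0, se, (I, J))
    return pd.DataFrame({
        "accession_id": np.repeat([f"A{i:03d}" for i in range(I)], J),
        "year": np.tile(first_year + np.arange(J), I),
        "value": y.ravel(),
    }), g, a


@pytest.fixture
def small_ph_dataset():
    return make_dataset(
        [("A", 2001, 80.0), ("A", 2002, 85.0),
         ("B", 2001, 90.0), ("B", 2002, 95.0),
         ("C", 2001, 100.0), ("C", 2002, 105.0)],
    )
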