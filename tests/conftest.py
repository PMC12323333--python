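import pandas as pd
import pytest

from rhizonet.synth import SyntheticSpec, generate_study
from rhizonet.tables_io import CountTable


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared by read-only tests."""
    return generate_study(SyntheticSpec(seed=7))


@pytest.fixture()
def tiny_counts():
    counts = pd.DataFrame(
        {"s1": [5, 3, 2], "s2": [1, 0, 9], "s3": [4, 4, 2]},
        index=["t1", "t2", "t3"],
    )
    lineages = pd.Series({
        "t1": "p__Ascomycota;c__Sordariomycetes;o__Hypocreales;"
              "f__Cordycipitaceae;g__Beauveria",
        "t2": "p__Ascomycota;c__Sordariomycetes;o__Hypocreales;"
              "f__Clavicipitaceae;g__Metarhizium",
        "t3": "p__Basidiomycota;c__Agaricomycetes;o__Agaricales;"
              "f__Tricholomataceae;g__Tricholoma",
    })
    return CountTable(counts, lineages)
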