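import numpy as np
import pandas as pd
import pytest

from ceconet import AbundanceTable, Lineage


@pytest.fixture
def small_table():
    """3 samples x 4 taxa of relative abundances with lineages and groups."""
    data = pd.DataFrame(
        [
            [0.5, 0.2, 0.2, 0.1],
            [0.4, 0.3, 0.2, 0.1],
            [0.25, 0.25, 0.25, 0.25],
        ],
        index=["s1", "s2", "s3"],
        columns=["tA", "tB", "tC", "tD"],
    )
    lineages = {
        "tA": Lineage.parse("d__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;"
                            "f__Lactobacillaceae;g__Lactobacillus;s__La"),
        "tB": Lineage.parse("d__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;"
                            "f__Lactobacillaceae;g__Lactobacillus;s__Lb"),
        "tC": Lineage.parse("d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;"
                            "o__Enterobacterales;f__Enterobacteriaceae;g__Escherichia;s__Ec"),
        "tD": Lineage.parse("d__Bacteria;p__Firmicutes_A;c__Clostridia;o__Oscillospirales;"
                            "f__;g__;s__"),
    }
    groups = pd.Series(["CON", "CON", "AOS"], index=data.index, name="group")
    return AbundanceTable(data, lineages=lineages, groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20230703)
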