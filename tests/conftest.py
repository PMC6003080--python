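import numpy as np
import pandas as pd
import pytest

from hfe.io import AbundanceTable, LabelVector
from hfe.taxonomy import Lineage, build_tree


@pytest.fixture
def three_otu_tree():
    """Two complete OTUs under one genus plus one OTU stopping at the family."""
    lineages = {
        "OTU1": Lineage(("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                         "Lachnospiraceae", "Coprococcus", "comes")),
        "OTU2": Lineage(("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                         "Lachnospiraceae", "Coprococcus", "comes")),
        "OTU3": Lineage(("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                         "Lachnospiraceae")),
    }
    return build_tree(["OTU1", "OTU2", "OTU3"], lineages)


@pytest.fixture
def three_otu_table():
    data = pd.DataFrame(
        [[0.2, 0.3, 0.5],
         [0.1, 0.6, 0.3],
         [0.4, 0.4, 0.2],
         [0.25, 0.25, 0.5]],
        index=["S1", "S2", "S3", "S4"],
        columns=["OTU1", "OTU2", "OTU3"],
    )
    return AbundanceTable(data, normalized=True)


@pytest.fixture
def four_sample_labels():
    return LabelVector({"S1": "case", "S2": "case", "S3": "control", "S4": "control"})
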