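import numpy as np
import pandas as pd
import pytest

from coinflam import (
    ExpressionMatrix,
    GeneSetPartition,
    OtuCountTable,
    SubjectVisitPair,
)


@pytest.fixture
def tiny_matrix():
    """Two inflammatory + three regulatory probes, two subjects (pre/post)."""
    values = pd.DataFrame(
        {
            "A_pre": [8.0, 10.0, 4.0, 5.0, 9.0],
            "A_post": [7.0, 9.0, 4.0, 5.0, 9.0],
            "B_pre": [6.0, 6.0, 6.0, 6.0, 6.0],
            "B_post": [6.0, 6.0, 6.0, 6.0, 6.0],
        },
        index=["i1", "i2", "r1", "r2", "r3"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def tiny_partition():
    return GeneSetPartition(
        inflammatory=frozenset({"i1", "i2"}),
        regulatory=frozenset({"r1", "r2", "r3"}),
    )


@pytest.fixture
def tiny_pairs():
    return [
        SubjectVisitPair("A", "A_pre", "A_post"),
        SubjectVisitPair("B", "B_pre", "B_post"),
    ]


@pytest.fixture
def small_otu_table():
    """Four OTUs across two families, one OTU unassigned at family."""
    counts = pd.DataFrame(
        {
            "OTU_1": [10, 20, 30, 5],
            "OTU_2": [5, 5, 0, 10],
            "OTU_3": [0, 3, 7, 2],
            "OTU_4": [1, 0, 2, 3],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    lineages = pd.Series(
        {
            "OTU_1": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                     "f__Lachnospiraceae;g__Blautia;s__",
            "OTU_2": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                     "f__Lachnospiraceae;g__Roseburia;s__",
            "OTU_3": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;"
                     "o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides;s__",
            "OTU_4": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales",
        }
    )
    return OtuCountTable(counts, lineages)


def make_pairs(n, prefix="P"):
    return [
        SubjectVisitPair(f"{prefix}{i:02d}", f"{prefix}{i:02d}_pre",
                         f"{prefix}{i:02d}_post")
        for i in range(1, n + 1)
    ]
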