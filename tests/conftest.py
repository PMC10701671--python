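import networkx as nx
import numpy as np
import pandas as pd
import pytest

from taxonet.preprocess import BatchMap


@pytest.fixture
def toy_table() -> pd.DataFrame:
    """3 features x 4 samples with varied totals."""
    return pd.DataFrame(
        [[5, 0, 2, 1], [0, 3, 3, 0], [10, 7, 0, 4]],
        index=pd.Index(["f1", "f2", "f3"], name="feature-id"),
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def decontam_batch() -> tuple[pd.DataFrame, BatchMap]:
    """One batch: 4 environmental samples + 1 control, three features
    exercising each branch of the decontamination rule."""
    table = pd.DataFrame(
        {
            "e1": [5, 8, 300],
            "e2": [5, 8, 300],
            "e3": [5, 8, 300],
            "e4": [5, 8, 300],
            "ctrl": [2, 0, 2],
        },
        index=pd.Index(["low_contam", "clean_absent", "abundant"], name="feature-id"),
    )
    batches = BatchMap(
        batch_of={s: "b1" for s in table.columns},
        environmental={"b1": frozenset(["e1", "e2", "e3", "e4"])},
        controls={"b1": frozenset(["ctrl"])},
    )
    return table, batches


@pytest.fixture
def two_triangles_bridge() -> nx.Graph:
    """Triangles {A,B,C} and {D,E,F} joined by the bridge C-D."""
    g = nx.Graph()
    g.add_edges_from(
        [("A", "B"), ("A", "C"), ("B", "C"), ("D", "E"), ("D", "F"), ("E", "F"), ("C", "D")]
    )
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230942)
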