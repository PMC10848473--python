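import io as _io

import pandas as pd
import pytest
from skbio import TreeNode

from wildgut.io import OtuTable, PedigreeRecord, TaxonomyMap
from wildgut.kinship import PedigreeGraph
from wildgut.simulate import SimulationConfig, simulate_study


@pytest.fixture
def three_leaf_tree() -> TreeNode:
    """((A:1,B:1):1,C:2); — total branch length 5."""
    return TreeNode.read(_io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def small_table() -> OtuTable:
    return OtuTable(
        pd.DataFrame({"s1": [2, 0, 1], "s2": [0, 3, 1]}, index=["A", "B", "C"])
    )


@pytest.fixture
def small_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        {
            "A": ("Bacteria", "Firmicutes", "", "", "", "GenA", ""),
            "B": ("Bacteria", "Firmicutes", "", "", "", "GenB", ""),
            "C": ("Bacteria", "Bacteroidetes", "", "", "", "GenC", ""),
        }
    )


@pytest.fixture
def family_pedigree() -> PedigreeGraph:
    """Two founders, two full-sib children, one grandchild via an outside mate."""
    return PedigreeGraph(
        [
            PedigreeRecord("sire"),
            PedigreeRecord("dam"),
            PedigreeRecord("kid1", "sire", "dam"),
            PedigreeRecord("kid2", "sire", "dam"),
            PedigreeRecord("mate"),
            PedigreeRecord("grandkid", "kid1", "mate"),
        ]
    )


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seeded)."""
    return simulate_study(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced design for fast pipeline-level tests."""
    return SimulationConfig(
        populations=(
            ("wild", 6, "wild"),
            ("zooA", 8, "captive"),
            ("zooB", 7, "captive"),
        ),
        taxa_per_phylum=8,
        n_planted_genera=4,
        n_age_genera=3,
        n_heritable_taxa=10,
        depth_range=(4000, 8000),
    )
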