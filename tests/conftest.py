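import numpy as np
import pytest

from pathdc import (
    PathwayHierarchy,
    PathwayNode,
    reference_fixture,
)

# subcategories of the "Metabolism" category used as a realistic
# 3-level hierarchy stub throughout the suite
METABOLISM_SUBCATEGORIES = [
    ("1.1", "Carbohydrate Metabolism"),
    ("1.2", "Energy Metabolism"),
    ("1.3", "Lipid Metabolism"),
    ("1.4", "Nucleotide Metabolism"),
    ("1.5", "Amino Acid Metabolism"),
    ("1.6", "Metabolism of Other Amino Acids"),
    ("1.7", "Glycan Biosynthesis and Metabolism"),
    ("1.8", "Metabolism of Cofactors and Vitamins"),
    ("1.11", "Xenobiotics Biodegradation and Metabolism"),
]


@pytest.fixture(scope="session")
def ref4():
    """Frozen four-child reference analysis (printed to 3 decimals)."""
    return reference_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture()
def metabolism_hierarchy():
    nodes = [PathwayNode("1", "Metabolism", "category")]
    nodes += [
        PathwayNode(nid, name, "subcategory", "1")
        for nid, name in METABOLISM_SUBCATEGORIES
    ]
    return PathwayHierarchy(nodes)


@pytest.fixture()
def metabolism_hierarchy_tsv(tmp_path):
    lines = ["level\tid\tname\tparent_id", "category\t1\tMetabolism\t"]
    lines += [
        f"subcategory\t{nid}\t{name}\t1" for nid, name in METABOLISM_SUBCATEGORIES
    ]
    path = tmp_path / "hierarchy.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def chain_hierarchy():
    """Minimal category -> subcategory -> secondary chain."""
    return PathwayHierarchy(
        [
            PathwayNode("C", "Category", "category"),
            PathwayNode("S", "Subcategory", "subcategory", "C"),
            PathwayNode("P", "Secondary pathway", "secondary", "S"),
        ]
    )
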