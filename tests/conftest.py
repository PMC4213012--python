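import numpy as np
import pytest

from contamlens.taxonomy import TaxonNode, TaxonomyTree


@pytest.fixture
def small_tree() -> TaxonomyTree:
    """Hand-built taxonomy: two phylum-level clades, one unclassifiable branch.

    Depths: root(1) -> superkingdom(2) -> phylum(3) -> class(4) -> family(5)
    -> genus(6) -> species(7), plus an 'uncultured organism' node and a
    shallow 'environmental samples' clade.
    """
    nodes = {}

    def add(tax_id, parent, rank, name):
        nodes[tax_id] = TaxonNode(tax_id, parent, rank, name)

    add(1, 1, "no rank", "root")
    add(2, 1, "superkingdom", "Eukaryota")
    # clade A: plants
    add(3, 2, "phylum", "Streptophyta")
    add(4, 3, "class", "Magnoliopsida")
    add(5, 4, "family", "Solanaceae")
    add(6, 5, "genus", "Solanum")
    add(7, 6, "species", "Solanum lycopersicum")
    # clade B: animals
    add(8, 2, "phylum", "Chordata")
    add(9, 8, "class", "Mammalia")
    add(10, 9, "family", "Hominidae")
    add(11, 10, "genus", "Homo")
    add(12, 11, "species", "Homo sapiens")
    add(13, 10, "genus", "Pan")
    add(14, 13, "species", "Pan troglodytes")
    # unclassifiable material
    add(20, 1, "no rank", "unclassified sequences")
    add(21, 20, "species", "uncultured organism")
    add(22, 1, "no rank", "environmental samples")
    add(23, 22, "species", "taxon 23")
    return TaxonomyTree(nodes=nodes, root_id=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
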