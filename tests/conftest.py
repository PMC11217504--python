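import numpy as np
import pytest

import phenotrip as pt


@pytest.fixture(scope="session")
def small_dataset():
    """4 species x 2 sexes x 2 surfaces x 3 images, 32 px, fixed seed."""
    scenario = pt.SimScenario(
        n_species=4, images_per_species_sex_surface=3, seed=11,
        n_gene_trees=20,
    )
    return pt.generate_dataset(scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns
    (dendropy tree, labels, additive distance matrix as DataFrame)."""
    import dendropy
    import pandas as pd

    labels = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.require_taxon(label=lab))
             for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for idx in (i, j):
            parent.add_child(nodes[idx])
            nodes[idx].edge.length = float(rng.uniform(0.1, 2.0))
        nodes[i] = parent
        del nodes[j]
    center = dendropy.Node()
    for node in nodes:
        center.add_child(node)
        node.edge.length = float(rng.uniform(0.1, 2.0))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tns}
    n = len(labels)
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = pdm.patristic_distance(
                taxa[labels[a]], taxa[labels[b]]
            )
    return tree, labels, pd.DataFrame(m, index=labels, columns=labels)


def patristic_df(tree):
    import pandas as pd
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = pdm.patristic_distance(
                taxa[labels[a]], taxa[labels[b]]
            )
    return pd.DataFrame(m, index=labels, columns=labels)
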