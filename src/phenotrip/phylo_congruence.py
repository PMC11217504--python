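"""Phenotypic phylogenies and their congruence with gene-tree samples.

Neighbour joining turns an inter-species centroid-distance matrix into an
unrooted phylogeny; branch-score (Euclidean branch-length) distance compares
it against a sample of gene trees and against random-tree nulls.  Because an
embedding-space tree carries arbitrary units while gene trees are on a
time/substitution scale, congruence analysis normalises every tree to unit
total branch length by default so the comparison is shape-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.stats import kruskal

from .disparity_stats import SubsetDistanceMatrix
from .errors import FormatError, InvalidArgumentError

__all__ = [
    "nj_tree", "root_tree", "branch_score_distance", "prune_to_taxa",
    "rescale_matrix", "clade_depth", "random_trees", "congruence_analysis",
    "normalize_tree_length", "CongruenceReport",
]


def _as_matrix(m) -> tuple[list[str], np.ndarray]:
    if isinstance(m, SubsetDistanceMatrix):
        labels, values = m.labels, m.values
    else:  # labelled DataFrame
        labels, values = list(map(str, m.index)), m.to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape != (len(labels), len(labels)) or not np.allclose(values, values.T):
        raise FormatError("distance matrix must be square and symmetric")
    # canonical label sort fixes tie-breaking and output determinism
    order = np.argsort(labels)
    labels = [labels[i] for i in order]
    return labels, values[np.ix_(order, order)]


def nj_tree(m) -> dendropy.Tree:
    """Saitou-Nei neighbour joining; exact on additive matrices.

    Ties in the Q criterion break at the smallest (row, column) index pair
    under canonical (sorted-label) order.  A negative branch-length estimate
    is clamped to zero with the deficit moved to the co-joined branch, so the
    joined pair's distance is preserved.
    """
    labels, d = _as_matrix(m)
    n = len(labels)
    if n < 3:
        raise InvalidArgumentError("neighbour joining needs >= 3 taxa")

    tns = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.require_taxon(label=lab))
        nodes.append(node)
    d = d.copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        q = (k - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))          # first minimum = smallest (i, j)
        i, j = divmod(flat, k)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        lj = d[i, j] - li
        if li < 0:
            li, lj = 0.0, d[i, j]
        elif lj < 0:
            li, lj = d[i, j], 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(lj)

        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d[i, :] = du
        d[:, i] = du
        d[i, i] = 0.0
        keep = [t for t in range(k) if t != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    center = dendropy.Node()
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, ln in ((a, la), (b, lb), (c, lc)):
        center.add_child(node)
        node.edge.length = float(max(ln, 0.0))

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def root_tree(t: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the midpoint of the outgroup's pendant edge.

    Leaf-pair path lengths are unchanged; rooting twice on the same taxon is
    a no-op after the first call.
    """
    leaf = next((lf for lf in t.leaf_node_iter()
                 if lf.taxon and lf.taxon.label == outgroup), None)
    if leaf is None:
        raise InvalidArgumentError(f"outgroup {outgroup!r} not among leaves")
    tree = t.clone(depth=1)
    leaf = next(lf for lf in tree.leaf_node_iter()
                if lf.taxon.label == outgroup)
    root = tree.seed_node
    if len(root.child_nodes()) == 2 and leaf in root.child_nodes():
        tree.is_rooted = True
        return tree
    half = (leaf.edge.length or 0.0) / 2.0
    tree.reroot_at_edge(leaf.edge, length1=half, length2=half,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def _bipartition_lengths(t: dendropy.Tree, bit_of: dict[str, int]) -> dict[int, float]:
    """Map each non-trivial-agnostic split (as a normalised leaf bitmask) to
    its total branch length; the two edges either side of a root merge."""
    full = (1 << len(bit_of)) - 1
    out: dict[int, float] = {}
    masks = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            masks[id(node)] = 1 << bit_of[node.taxon.label]
        else:
            masks[id(node)] = 0
            for ch in node.child_nodes():
                masks[id(node)] |= masks[id(ch)]
        if node.parent_node is None:
            continue
        mask = masks[id(node)]
        if mask == 0 or mask == full:
            continue
        if mask & 1:                      # normalise: exclude reference leaf
            mask ^= full
        out[mask] = out.get(mask, 0.0) + float(node.edge.length or 0.0)
    return out


def branch_score_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Euclidean branch-length (branch-score) distance between two trees.

    The norm runs over the union of the trees' bipartitions, a bipartition
    absent from one tree contributing length zero there.  Leaf sets must be
    identical (prune first if not).
    """
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise InvalidArgumentError(
            f"leaf sets differ: {sorted(l1 ^ l2)} — prune to a common set first"
        )
    bit_of = {lab: i for i, lab in enumerate(sorted(l1))}
    b1 = _bipartition_lengths(t1, bit_of)
    b2 = _bipartition_lengths(t2, bit_of)
    total = 0.0
    for key in set(b1) | set(b2):
        diff = b1.get(key, 0.0) - b2.get(key, 0.0)
        total += diff * diff
    return float(np.sqrt(total))


def prune_to_taxa(t: dendropy.Tree, taxa) -> dendropy.Tree:
    """Induced subtree on ``taxa``; retained leaf-pair path lengths are
    preserved (unary nodes collapsed with summed branch lengths)."""
    taxa = set(taxa)
    leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
    if not taxa <= leaves:
        raise InvalidArgumentError(f"taxa not in tree: {sorted(taxa - leaves)}")
    if len(taxa) < 3:
        raise InvalidArgumentError("prune target needs >= 3 taxa")
    if taxa == leaves:
        return t.clone(depth=1)
    tree = t.clone(depth=1)
    tree.retain_taxa_with_labels(sorted(taxa))
    return tree


def rescale_matrix(m: SubsetDistanceMatrix) -> SubsetDistanceMatrix:
    """Divide every entry by the matrix maximum (new maximum = 1)."""
    peak = float(m.values.max())
    if peak <= 0:
        raise InvalidArgumentError("all-zero distance matrix cannot be rescaled")
    return SubsetDistanceMatrix(keys=list(m.keys), values=m.values / peak)


def clade_depth(t: dendropy.Tree, clade_taxa) -> float:
    """Path length from the MRCA of ``clade_taxa`` to its furthest member."""
    clade_taxa = list(clade_taxa)
    if not clade_taxa:
        raise InvalidArgumentError("clade must be nonempty")
    leaves = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
    missing = set(clade_taxa) - set(leaves)
    if missing:
        raise InvalidArgumentError(f"taxa not in tree: {sorted(missing)}")
    if len(clade_taxa) == 1:
        return 0.0
    mrca = t.mrca(taxon_labels=clade_taxa)
    depth = 0.0
    for lab in clade_taxa:
        node, dist = leaves[lab], 0.0
        while node is not mrca:
            dist += node.edge.length or 0.0
            node = node.parent_node
        depth = max(depth, dist)
    return float(depth)


def random_trees(taxa, n: int, branch_length_pool, seed: int
                 ) -> list[dendropy.Tree]:
    """Uniform random coalescent-style topologies on ``taxa``.

    Topologies are built by repeatedly joining two uniformly chosen lineages;
    every branch length is resampled from ``branch_length_pool`` (typically
    the pooled gene-tree branch lengths).
    """
    taxa = sorted(taxa)
    pool = np.asarray(list(branch_length_pool), dtype=float)
    if len(taxa) < 3 or n < 1:
        raise InvalidArgumentError("need >= 3 taxa and n >= 1")
    if pool.size == 0:
        raise InvalidArgumentError("empty branch-length pool")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        tns = dendropy.TaxonNamespace()
        lineages = []
        for lab in taxa:
            node = dendropy.Node(taxon=tns.require_taxon(label=lab))
            lineages.append(node)
        while len(lineages) > 1:
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
            parent = dendropy.Node()
            for idx in (i, j):
                child = lineages[idx]
                parent.add_child(child)
                child.edge.length = float(rng.choice(pool))
            lineages[i] = parent
            del lineages[j]
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=lineages[0])
        tree.is_rooted = True
        out.append(tree)
    return out


def normalize_tree_length(t: dendropy.Tree) -> dendropy.Tree:
    """Copy of the tree scaled to unit total branch length."""
    tree = t.clone(depth=1)
    total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    if total <= 0:
        raise InvalidArgumentError("tree has zero total branch length")
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= total
    return tree


@dataclass
class CongruenceReport:
    """Distance distributions and tests from :func:`congruence_analysis`."""

    pheno_vs_gene: np.ndarray
    gene_vs_gene: np.ndarray
    pheno_vs_random: np.ndarray
    kruskal_h: float
    kruskal_p: float
    median_pheno_gene: float
    gene_range: tuple[float, float]
    median_within_gene_range: bool
    n_gene_trees: int
    n_random_trees: int

    def summary(self) -> dict:
        return {
            "n_gene_trees": self.n_gene_trees,
            "n_random_trees": self.n_random_trees,
            "median_pheno_gene": self.median_pheno_gene,
            "median_pheno_random": float(np.median(self.pheno_vs_random)),
            "gene_gene_min": self.gene_range[0],
            "gene_gene_max": self.gene_range[1],
            "median_within_gene_range": self.median_within_gene_range,
            "kruskal_h": self.kruskal_h,
            "kruskal_p": self.kruskal_p,
        }


_MAX_GENE_PAIRS_EXHAUSTIVE = 2000
_GENE_PAIR_SUBSAMPLE = 10_000


def congruence_analysis(pheno_tree: dendropy.Tree, gene_trees, n_random: int,
                        seed: int, normalize: str | None = "tree_length"
                        ) -> CongruenceReport:
    """Quantify congruence of a phenotypic tree with a gene-tree sample.

    Computes branch-score distances (i) phenotypic tree vs each gene tree,
    (ii) among gene trees (all pairs, or a seeded subsample when the pair
    count exceeds 2000), and (iii) phenotypic tree vs ``n_random`` random
    trees whose branch lengths are resampled from the gene trees.  Reports a
    Kruskal-Wallis location test between (i) and (iii) and whether the median
    of (i) falls inside the range of (ii).  With ``normalize="tree_length"``
    (default) every tree is first scaled to unit total branch length.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise InvalidArgumentError("gene tree sample is empty")
    leaf_sets = [{lf.taxon.label for lf in t.leaf_node_iter()}
                 for t in [pheno_tree, *gene_trees]]
    common = set.intersection(*leaf_sets)
    if len(common) < 3:
        raise InvalidArgumentError("fewer than 3 taxa shared across trees")

    def prep(t):
        leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
        tt = prune_to_taxa(t, common) if leaves != common else t
        return normalize_tree_length(tt) if normalize == "tree_length" else tt

    pheno = prep(pheno_tree)
    genes = [prep(t) for t in gene_trees]

    rng = np.random.default_rng(seed)
    pool = [e.length for g in genes for e in g.preorder_edge_iter()
            if e.length]
    randoms = random_trees(sorted(common), n_random, pool,
                           seed=int(rng.integers(2**31)))
    if normalize == "tree_length":
        randoms = [normalize_tree_length(t) for t in randoms]

    # vectorise: stack every tree's bipartition-length profile over the
    # union of observed splits, then take row-wise Euclidean distances
    bit_of = {lab: i for i, lab in enumerate(sorted(common))}
    profiles = [_bipartition_lengths(t, bit_of)
                for t in [pheno, *genes, *randoms]]
    keys = sorted(set().union(*profiles))
    kidx = {k: i for i, k in enumerate(keys)}
    mat = np.zeros((len(profiles), len(keys)))
    for r, prof in enumerate(profiles):
        for k, v in prof.items():
            mat[r, kidx[k]] = v
    p_row = mat[0]
    g_rows = mat[1:1 + len(genes)]
    r_rows = mat[1 + len(genes):]
    pheno_gene = np.linalg.norm(g_rows - p_row, axis=1)
    pheno_random = np.linalg.norm(r_rows - p_row, axis=1)

    from scipy.spatial.distance import pdist
    gene_gene = pdist(g_rows) if len(genes) > 1 else np.array([0.0])
    if len(gene_gene) > _MAX_GENE_PAIRS_EXHAUSTIVE:
        take = min(_GENE_PAIR_SUBSAMPLE, len(gene_gene))
        gene_gene = rng.choice(gene_gene, size=take, replace=False)

    if np.ptp(np.concatenate([pheno_gene, pheno_random])) == 0:
        h, p = 0.0, 1.0
    else:
        stat = kruskal(pheno_gene, pheno_random)
        h, p = float(stat.statistic), float(stat.pvalue)
    med = float(np.median(pheno_gene))
    lo, hi = float(gene_gene.min()), float(gene_gene.max())
    return CongruenceReport(
        pheno_vs_gene=pheno_gene,
        gene_vs_gene=gene_gene,
        pheno_vs_random=pheno_random,
        kruskal_h=h,
        kruskal_p=p,
        median_pheno_gene=med,
        gene_range=(lo, hi),
        median_within_gene_range=bool(lo <= med <= hi),
        n_gene_trees=len(genes),
        n_random_trees=n_random,
    )
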