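"""Tree handling helpers on top of dendropy.

Trees are dendropy.Tree objects throughout the package. Two length scales
occur: substitution branch lengths (expected substitutions/site, the
``edge.length`` of inference trees) and node ages in Myr (stored as the
``age`` annotation of chronograms, with tips at age 0).
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np


def parse_newick(source: str | Path, rooted: bool = True) -> dendropy.Tree:
    """Read a Newick tree from a string or a file path."""
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if not text.lstrip().startswith("("):
        text = Path(text).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick",
                             rooting="force-rooted" if rooted else "force-unrooted")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None,
                 ages: bool = False) -> str:
    """Serialise to Newick; with ``ages=True`` node ages ride along as
    ``[&age=...]`` comments."""
    if ages:
        for nd in tree:
            if getattr(nd, "age", None) is not None:
                nd.annotations.drop(name="age")
                nd.annotations.add_new("age", round(float(nd.age), 6))
    s = tree.as_string(schema="newick", suppress_annotations=not ages,
                       suppress_rooting=True)
    if path is not None:
        Path(path).write_text(s)
    return s


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def annotate_ages_from_lengths(tree: dendropy.Tree, tol: float = 1e-6) -> None:
    """Set ``node.age`` from edge lengths, requiring ultrametricity.

    Edge lengths are interpreted as durations; tips sit at age 0.
    """
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd.age = 0.0
        else:
            ages = [c.age + (c.edge.length or 0.0) for c in nd.child_nodes()]
            if max(ages) - min(ages) > tol * max(1.0, max(ages)):
                raise ValueError("tree is not ultrametric in edge-length space")
            nd.age = float(np.mean(ages))


def set_lengths_from_ages(tree: dendropy.Tree) -> None:
    """Edge length := parent age - child age (duration in Myr)."""
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(nd.parent_node.age - nd.age)


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    try:
        annotate_ages_from_lengths(tree, tol=tol)
    except ValueError:
        return False
    return True


class TreeIndex:
    """Flat array view of a rooted tree for likelihood recursions.

    Nodes are numbered in postorder (root last). ``children[i]`` lists child
    indices, ``parent[i]`` the parent index (-1 for the root), ``lengths[i]``
    the edge length above node i, and ``tip_row[i]`` the row of a leaf's
    taxon in the supplied taxa ordering (-1 for internal nodes).
    """

    def __init__(self, tree: dendropy.Tree, taxa: list[str]):
        row_of = {name: i for i, name in enumerate(taxa)}
        self.nodes = list(tree.postorder_node_iter())
        self.index_of = {id(nd): i for i, nd in enumerate(self.nodes)}
        n = len(self.nodes)
        self.n_nodes = n
        self.parent = np.full(n, -1, dtype=int)
        self.lengths = np.zeros(n)
        self.tip_row = np.full(n, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, nd in enumerate(self.nodes):
            if nd.parent_node is not None:
                self.parent[i] = self.index_of[id(nd.parent_node)]
                self.children[self.parent[i]].append(i)
                self.lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label not in row_of:
                    raise ValueError(f"leaf {nd.taxon} not among supplied taxa")
                self.tip_row[i] = row_of[nd.taxon.label]
        self.root = n - 1
        self.internal = [i for i in range(n) if self.children[i]]
        self.tips = [i for i in range(n) if not self.children[i]]

    def set_lengths_on_tree(self, lengths: np.ndarray) -> None:
        for i, nd in enumerate(self.nodes):
            if nd.parent_node is not None:
                nd.edge.length = float(lengths[i])


def jc_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Jukes-Cantor distances from a '<U1' symbol matrix.

    Cells that are not plain A/C/G/T in both rows are ignored; saturated
    pairs (p >= 0.749) are capped at an arbitrary large distance.
    """
    n = matrix.shape[0]
    plain = np.isin(matrix, list("ACGT"))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = plain[i] & plain[j]
            if ok.sum() == 0:
                dist = 5.0
            else:
                p = (matrix[i, ok] != matrix[j, ok]).mean()
                dist = 5.0 if p >= 0.749 else -0.75 * np.log(1 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return d


def canonicalize(tree: dendropy.Tree) -> dendropy.Tree:
    """Deterministic form: root on the first taxon's pendant edge (split in
    half) and order children by their smallest descendant label."""
    first = min(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if tree.seed_node not in (first, first.parent_node):
        half = (first.edge.length or 0.0) / 2.0
        tree.reroot_at_edge(first.edge, length1=half, length2=half,
                            update_bipartitions=False)

    def min_label(nd):
        return min(lf.taxon.label for lf in nd.leaf_iter())

    for nd in tree.preorder_node_iter():
        children = nd.child_nodes()
        if len(children) > 1:
            nd.set_child_nodes(sorted(children, key=min_label))
    return tree


def nj_tree(taxa: list[str], dist: np.ndarray) -> dendropy.Tree:
    """Neighbour-joining (Saitou-Nei) tree from a distance matrix.

    Deterministic: joins are selected by the standard Q criterion with
    index-ordered tie-breaking, so identical inputs give byte-identical
    trees. Negative branch-length estimates are clamped to zero. The result
    is returned in canonical rooted form (see :func:`canonicalize`).
    """
    n = len(taxa)
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match the taxon list")
    namespace = dendropy.TaxonNamespace(taxa)
    nodes = []
    for label in taxa:
        nd = dendropy.Node()
        nd.taxon = namespace.get_taxon(label)
        nodes.append(nd)
    active = list(range(n))
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n)}
    next_id = n
    while len(active) > 2:
        m = len(active)
        totals = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best, best_q = None, np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i, j] - totals[i] - totals[j]
                if q < best_q - 1e-12:
                    best, best_q = (i, j), q
        i, j = best
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            parent.add_child(child)
            child.edge.length = max(length, 0.0)
        nodes.append(parent)
        k = next_id
        next_id += 1
        for x in active:
            if x not in (i, j):
                d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        active = [x for x in active if x not in (i, j)] + [k]
        d[k, k] = 0.0
    i, j = active
    root = dendropy.Node()
    half = max(d[i, j], 0.0) / 2.0
    for child in (nodes[i], nodes[j]):
        root.add_child(child)
        child.edge.length = half
    tree = dendropy.Tree(taxon_namespace=namespace, seed_node=root)
    return canonicalize(tree)
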