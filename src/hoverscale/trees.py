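"""Phylogenetic tree utilities: Yule simulation, Brownian motion, covariance matrices.

Trees are :class:`dendropy.Tree` objects throughout.  The only quantity the
downstream statistics need from a tree is the Brownian-motion trait covariance
``C`` (``C[i, j]`` = shared root-to-MRCA path length of tips *i* and *j*), so
helpers here revolve around producing and consuming that matrix.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidParameterError, TreeDegeneracyError

__all__ = [
    "simulate_yule_tree",
    "simulate_bm_trait",
    "star_tree",
    "vcv_matrix",
    "tree_from_newick",
    "tip_labels",
]


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def star_tree(labels: list[str], depth: float = 1.0) -> dendropy.Tree:
    """A rooted star phylogeny: every tip attached to the root at ``depth``."""
    newick = "(" + ",".join(f"{lab}:{depth!r}" for lab in labels) + ");"
    return tree_from_newick(newick)


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float,
    rng: np.random.Generator,
    prefix: str = "sp",
) -> dendropy.Tree:
    """Sample a pure-birth (Yule) tree and rescale it to unit root-to-tip depth.

    Lineages split at exponential waiting times with total rate
    ``k * birth_rate`` for ``k`` extant lineages; after the n-th lineage
    appears the clade grows for one further (censored) waiting time so all
    pendant edges have positive length.  The result is ultrametric.
    """
    if n_tips < 3:
        raise InvalidParameterError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise InvalidParameterError("birth_rate must be > 0")

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    root.birth_time = 0.0
    active = []
    t = 0.0
    # root splits immediately into the first two lineages
    for _ in range(2):
        child = dendropy.Node()
        child.birth_time = 0.0
        root.add_child(child)
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        parent = active.pop(int(i))
        parent.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            parent.add_child(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))

    width = len(str(n_tips))
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxon_ns.new_taxon(f"{prefix}{k:0{width}d}")
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        end = getattr(node, "split_time", t_end) if not node.is_leaf() else t_end
        node.edge.length = end - node.birth_time
    # rescale to unit depth
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= t_end
    return tree


def simulate_bm_trait(
    tree: dendropy.Tree,
    sigma2: float,
    root_value: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Evolve a trait along the tree under Brownian motion; returns tip values."""
    if sigma2 < 0:
        raise InvalidParameterError("sigma2 must be >= 0")
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            bl = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(sigma2 * bl)) if sigma2 > 0 and bl > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def vcv_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion covariance matrix of the tips.

    ``C[i, j]`` is the root-to-MRCA distance of tips *i* and *j*; the diagonal
    holds root-to-tip depths.
    """
    labels = tip_labels(tree)
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depth: dict[int, float] = {}
    tipsets: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[id(parent)] + (node.edge.length or 0.0)
        depth[id(node)] = d
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = index[node.taxon.label]
            tipsets[id(node)] = [k]
            C[k, k] = depth[id(node)]
        else:
            child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            C[i, j] = C[j, i] = d
            tipsets[id(node)] = [i for s in child_sets for i in s]
    return pd.DataFrame(C, index=labels, columns=labels)


def cholesky_or_raise(C: np.ndarray) -> np.ndarray:
    """Cholesky factor of a tree covariance; singular trees raise."""
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise TreeDegeneracyError(
            "phylogenetic covariance matrix is singular "
            "(identical tips at zero distance, or zero-depth tree)"
        ) from exc
    if not np.all(np.isfinite(L)):
        raise TreeDegeneracyError("non-finite covariance matrix")
    return L
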