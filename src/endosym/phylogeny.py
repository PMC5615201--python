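"""Neighbor-joining tree construction with column-bootstrap support.

Saitou-Nei neighbor joining with the Studier-Keppler Q criterion: at each
step the pair (i, j) minimizing

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

is joined; ties are broken by the lowest (row, column) index pair so the
result is platform-deterministic. On an additive distance matrix the
algorithm recovers the unique generating topology with exact branch
lengths. Negative branch lengths (possible on noisy matrices) are clamped
to zero on the final tree and logged.

Bootstrap support for each internal edge is the percentage of
column-resampled replicates whose NJ tree contains the same bipartition.
Trees are dendropy ``Tree`` objects (unrooted, trifurcating at the seed
node), so the full dendropy toolkit applies downstream.
"""

from __future__ import annotations

import logging
import warnings
from io import StringIO

import dendropy
import numpy as np

from .distances import Alignment, DistanceMatrix, SaturationError, SiteFilterPolicy, distance_matrix

__all__ = [
    "neighbor_joining",
    "bootstrap_nj",
    "write_newick",
    "read_newick",
    "bipartitions",
]

logger = logging.getLogger(__name__)


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree from a distance matrix.

    Requires at least 3 taxa. Returns a dendropy tree whose seed node is
    the final trifurcation; leaf taxa carry the matrix labels.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    ns = dendropy.TaxonNamespace(list(D.labels))
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: list[dendropy.Node] = []
    for label in D.labels:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(node)
    d = D.d.astype(np.float64).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # Row-major argmin == lowest (row, column) tie-break.
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # Distances from the new node to the remaining ones.
        dk = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.empty((m - 1, m - 1))
        new_d[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        new_d[m - 2, : m - 2] = new_d[: m - 2, m - 2] = dk[keep]
        new_d[m - 2, m - 2] = 0.0
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    # Final trifurcation via the three-point formulas.
    center = dendropy.Node()
    lens = (
        0.5 * (d[0, 1] + d[0, 2] - d[1, 2]),
        0.5 * (d[0, 1] + d[1, 2] - d[0, 2]),
        0.5 * (d[0, 2] + d[1, 2] - d[0, 1]),
    )
    for node, length in zip(nodes, lens):
        center.add_child(node)
        node.edge.length = length

    tree.seed_node = center
    tree.is_rooted = False
    n_clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("clamped %d negative NJ branch lengths to 0", n_clamped)
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Internal-edge bipartitions as frozensets of leaf labels (smaller side)."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = frozenset(leaves - side)
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_nj(
    aln: Alignment,
    model: str = "k2p",
    n_reps: int = 1000,
    seed: int | None = None,
    policy: SiteFilterPolicy | None = None,
) -> dendropy.Tree:
    """NJ tree from an alignment, internal edges annotated with bootstrap %.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    tree votes for the bipartitions it contains. Replicates with saturated
    distances are skipped (a warning is issued if more than 1% are).
    Supports are stored as internal-node labels (integer percent).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    from .distances import filter_sites

    filtered = filter_sites(aln, policy or SiteFilterPolicy())
    if np.all(filtered.codes == filtered.codes[0], axis=None):
        raise ValueError("all sequences identical; no phylogenetic signal")
    full = neighbor_joining(distance_matrix(filtered, model=model))
    target = bipartitions(full)

    rng = np.random.default_rng(seed)
    votes: dict[frozenset[str], int] = {bp: 0 for bp in target}
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, filtered.n_sites, size=filtered.n_sites)
        rep = Alignment(labels=filtered.labels, codes=filtered.codes[:, cols])
        try:
            rep_tree = neighbor_joining(distance_matrix(rep, model=model))
        except (SaturationError, ValueError):
            skipped += 1
            continue
        for bp in bipartitions(rep_tree):
            if bp in votes:
                votes[bp] += 1
    counted = n_reps - skipped
    if counted == 0:
        raise SaturationError("every bootstrap replicate saturated")
    if skipped > 0.01 * n_reps:
        warnings.warn(
            f"{skipped}/{n_reps} bootstrap replicates skipped (saturated distances)",
            RuntimeWarning,
        )

    for node in full.preorder_node_iter():
        if node.is_leaf() or node is full.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        leaves = {lf.taxon.label for lf in full.leaf_node_iter()}
        key = min(side, frozenset(leaves - side), key=lambda s: (len(s), sorted(s)))
        if key in votes:
            node.label = str(round(100.0 * votes[key] / counted))
    return full


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize to Newick; supports appear as internal-node labels, lengths to 6 dp."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    ).strip() + "\n"


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; rejects empty input and duplicate leaf labels."""
    if not text.strip():
        raise ValueError("empty Newick string")
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
    )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in Newick input")
    return tree
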