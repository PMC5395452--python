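"""Phylogenetic primitives: Newick ingestion, cophenetic distances, Brownian
simulation, and Felsenstein-weighted nodal estimation.

Trees are represented as :class:`dendropy.Tree` objects throughout the public
API (branch lengths in Myr).  The heavy lifting for the D statistic — nodal
estimation and sister-clade differences over thousands of permuted traits — is
done by :class:`TreeIndex`, a flattened array view of a binary tree in which
the Felsenstein branch-length adjustment is precomputed once (it depends only
on the tree, never on the trait), so whole matrices of traits are processed in
one post-order sweep.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import NewickParseError, ValidationError

logger = logging.getLogger(__name__)

#: Stand-in for a zero branch length inside weight computations only; patristic
#: distances are never touched by this guard.
ZERO_BRANCH_EPS = 1e-9


# ---------------------------------------------------------------------------
# Ingestion and validation
# ---------------------------------------------------------------------------

def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not (leaf.taxon.label or "").strip():
            raise ValidationError("tree contains an unlabeled or empty-labeled tip")
        labels.append(leaf.taxon.label)
    seen, dups = set(), []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen.add(lab)
    if dups:
        raise ValidationError(f"duplicate tip labels: {sorted(set(dups))}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            where = node.taxon.label if node.taxon else "an internal node"
            raise ValidationError(f"missing branch length above {where}")
        if node.edge.length < 0:
            raise ValidationError("negative branch length in tree")
    return tree


def _get_tree(source: dict, what: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, **source,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate tip labels in {what}: {exc}") from exc
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise NewickParseError(f"malformed Newick in {what}: {exc}") from exc
    return _validate_tree(tree)


def read_newick(path: str) -> dendropy.Tree:
    """Read and validate a rooted Newick tree with branch lengths.

    Raises :class:`NewickParseError` on malformed input (the message carries
    dendropy's line/column diagnosis) and :class:`ValidationError` on duplicate
    or empty tip labels and missing branch lengths.
    """
    return _get_tree({"path": path}, path)


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    return _get_tree({"data": newick}, "string")


def is_binary(tree: dendropy.Tree) -> bool:
    return all(
        len(nd.child_nodes()) == 2
        for nd in tree.preorder_internal_node_iter()
    )


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Return a fully binary copy of *tree*.

    Each polytomy is broken by seeded random pairing with inserted zero-length
    branches, so every pairwise tip (patristic) distance is unchanged.  A tree
    that is already binary comes back topologically identical.
    """
    out = tree.clone(depth=1)
    out.resolve_polytomies(limit=2, rng=random.Random(seed))
    for node in out.preorder_node_iter():
        if node is not out.seed_node and node.edge.length is None:
            node.edge.length = 0.0
    return out


def prune_to_labels(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Copy of *tree* restricted to the given tip labels.

    Tips absent from *labels* are pruned with a logged warning; path lengths
    among retained tips are preserved (collapsed unifurcations merge edges).
    """
    keep = set(labels)
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = keep - tip_labels
    if missing:
        raise ValidationError(f"labels not in tree: {sorted(missing)[:5]} ...")
    dropped = tip_labels - keep
    if dropped:
        logger.warning(
            "pruning %d tree tips absent from data tables (e.g. %s)",
            len(dropped), sorted(dropped)[:3],
        )
    return tree.extract_tree_with_taxa_labels(keep)


# ---------------------------------------------------------------------------
# Cophenetic (patristic) distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric patristic distance matrix in Myr."""

    labels: list
    values: np.ndarray  # (n, n)

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix_min(self, focal: str, others) -> float:
        i = self._index[focal]
        js = [self._index[o] for o in others]
        return float(self.values[i, js].min())


def cophenetic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """All-pairs sums of branch lengths along tip-to-tip paths."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((lf.taxon for lf in tree.leaf_node_iter()),
                  key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix([t.label for t in taxa], d)


# ---------------------------------------------------------------------------
# Flattened binary-tree index (vectorized nodal machinery)
# ---------------------------------------------------------------------------

class TreeIndex:
    """Array view of a rooted binary tree.

    Node ids: tips ``0..n_tips-1`` (order of ``labels``), internal nodes
    ``n_tips + j`` with ``j`` in post-order, so children always precede their
    parent.  ``weights[j]`` holds the Felsenstein weights ``1/b'`` of the two
    children of internal node ``j``, where ``b' = b + b_L' b_R'/(b_L'+b_R')``
    is the standard contrasts branch-length adjustment and zero lengths are
    replaced by ``ZERO_BRANCH_EPS`` inside the weights only.
    """

    def __init__(self, tree: dendropy.Tree):
        if not is_binary(tree):
            raise ValidationError(
                "TreeIndex requires a binary tree; run resolve_polytomies first")
        tips = list(tree.leaf_node_iter())
        self.labels = [t.taxon.label for t in tips]
        self.n_tips = len(tips)
        node_id = {id(nd): i for i, nd in enumerate(tips)}
        internals = [nd for nd in tree.postorder_internal_node_iter()]
        self.n_internal = len(internals)
        for j, nd in enumerate(internals):
            node_id[id(nd)] = self.n_tips + j
        n_nodes = self.n_tips + self.n_internal
        self.n_nodes = n_nodes
        self.children = np.empty((self.n_internal, 2), dtype=np.int64)
        self.edge_len = np.zeros(n_nodes)
        for nd in tree.preorder_node_iter():
            if nd is not tree.seed_node:
                self.edge_len[node_id[id(nd)]] = float(nd.edge.length)
        for j, nd in enumerate(internals):
            kids = nd.child_nodes()
            self.children[j] = [node_id[id(kids[0])], node_id[id(kids[1])]]
        self.node_refs = tips + internals

        # Felsenstein adjusted lengths -> per-node weights (trait independent)
        adj = np.where(self.edge_len > 0, self.edge_len, ZERO_BRANCH_EPS)
        self.weights = np.empty((self.n_internal, 2))
        for j in range(self.n_internal):
            left, right = self.children[j]
            b_l, b_r = adj[left], adj[right]
            self.weights[j] = (1.0 / b_l, 1.0 / b_r)
            own = self.edge_len[self.n_tips + j]
            own = own if own > 0 else ZERO_BRANCH_EPS
            adj[self.n_tips + j] = own + b_l * b_r / (b_l + b_r)

    # -- nodal estimation ---------------------------------------------------

    def nodal_values(self, tip_matrix: np.ndarray) -> np.ndarray:
        """Post-order weighted-average estimates for every node.

        ``tip_matrix`` is ``(n_tips,)`` or ``(n_tips, m)``; returns values for
        all ``n_nodes`` nodes (tips echo their inputs).
        """
        x = np.asarray(tip_matrix, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[:, None]
        v = np.empty((self.n_nodes, x.shape[1]))
        v[: self.n_tips] = x
        for j in range(self.n_internal):
            left, right = self.children[j]
            w_l, w_r = self.weights[j]
            v[self.n_tips + j] = (w_l * v[left] + w_r * v[right]) / (w_l + w_r)
        return v[:, 0] if squeeze else v

    def sum_sister_diffs(self, tip_matrix: np.ndarray) -> np.ndarray:
        """Sum over internal nodes of |left − right| child estimates (Σd)."""
        x = np.asarray(tip_matrix, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[:, None]
        v = np.empty((self.n_nodes, x.shape[1]))
        v[: self.n_tips] = x
        total = np.zeros(x.shape[1])
        for j in range(self.n_internal):
            left, right = self.children[j]
            w_l, w_r = self.weights[j]
            total += np.abs(v[left] - v[right])
            v[self.n_tips + j] = (w_l * v[left] + w_r * v[right]) / (w_l + w_r)
        return total[0] if squeeze else total

    # -- Brownian simulation ------------------------------------------------

    def brownian_tips(self, n_reps: int, sigma2: float,
                      rng: np.random.Generator) -> np.ndarray:
        """Simulate Brownian motion down the tree; ``(n_tips, n_reps)`` values.

        Root value 0; each node adds a Normal(0, sigma2 × branch length)
        increment to its parent's value.
        """
        if sigma2 < 0:
            raise ValidationError("sigma2 must be non-negative")
        v = np.zeros((self.n_nodes, n_reps))
        sd = np.sqrt(sigma2 * self.edge_len)
        # parents in reverse post-order = pre-order: parents before children
        for j in range(self.n_internal - 1, -1, -1):
            parent = self.n_tips + j
            for child in self.children[j]:
                v[child] = v[parent]
                if sd[child] > 0:
                    v[child] += rng.normal(0.0, sd[child], size=n_reps)
        return v[: self.n_tips]


# ---------------------------------------------------------------------------
# Per-trait convenience wrappers
# ---------------------------------------------------------------------------

def simulate_brownian(tree: dendropy.Tree, sigma2: float, seed: int) -> dict:
    """One Brownian realization on *tree*; map tip label → value.

    Deterministic given *seed*; the root starts at 0 and every branch adds an
    independent Normal(0, sigma2 × length) increment.
    """
    if sigma2 < 0:
        raise ValidationError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            values[id(node)] = 0.0
        else:
            b = float(node.edge.length or 0.0)
            incr = rng.normal(0.0, np.sqrt(sigma2 * b)) if sigma2 * b > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + incr
    return {lf.taxon.label: values[id(lf)] for lf in tree.leaf_node_iter()}


def estimate_nodal_values(tree: dendropy.Tree, tip_values: dict) -> dict:
    """Felsenstein-weighted ancestral estimates; map node → value.

    Tips map to their own values.  Requires a binary tree and a value for
    every tip (a missing tip raises :class:`ValidationError` naming it).
    """
    idx = TreeIndex(tree)
    missing = [lab for lab in idx.labels if lab not in tip_values]
    if missing:
        raise ValidationError(f"no trait value for tip(s): {missing[:5]}")
    x = np.array([float(tip_values[lab]) for lab in idx.labels])
    v = idx.nodal_values(x)
    return {idx.node_refs[i]: float(v[i]) for i in range(idx.n_nodes)}
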