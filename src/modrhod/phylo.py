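"""Distance-based phylogeny: p-distance, neighbor joining, bootstrap.

Neighbor joining follows the Saitou–Nei agglomeration: at each step the pair
minimising the Q-criterion

    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)

is joined, with the standard branch-length formulas.  Ties are broken toward
the lowest index pair so the output is deterministic; a negative branch
length is clamped to zero with the excess transferred to its sister branch
(the tree's path-length metric is unchanged by the transfer).  The result is
an unrooted tree held in a dendropy container, rooted arbitrarily at the
final trifurcation.

Bootstrap support resamples alignment columns with replacement, rebuilds the
NJ tree per replicate, and annotates each internal bipartition of the
full-data tree with its replicate frequency (0–100).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .records import GAP, ValidationError


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between named taxa."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate taxon ids")
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match taxa")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite distances")
        if np.any(self.values < 0):
            raise ValidationError("negative distances")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("non-zero diagonal")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("asymmetric distance matrix")


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Fraction of mismatched columns, columns gapped in either sequence
    excluded pairwise."""
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned sequences differ in length")
    compared = 0
    mismatches = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValidationError("no comparable columns")
    return mismatches / compared


def poisson_distance(aligned_a: str, aligned_b: str) -> float:
    """Poisson-corrected distance −ln(1−p); saturated pairs (p ≥ 1) are an
    error rather than infinity."""
    p = p_distance(aligned_a, aligned_b)
    if p >= 1.0:
        raise ValidationError("saturated pair: p-distance >= 1")
    return -float(np.log1p(-p))


def distance_matrix(
    alignment: dict[str, str] | list[tuple[str, str]], model: str = "p"
) -> DistanceMatrix:
    """All-pairs distances from a rectangular alignment (id → aligned seq)."""
    items = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    ids = tuple(i for i, _ in items)
    seqs = [s for _, s in items]
    if len({len(s) for s in seqs}) > 1:
        raise ValidationError("alignment is not rectangular")
    dist = p_distance if model == "p" else poisson_distance
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dist(seqs[i], seqs[j])
    return DistanceMatrix(ids=ids, values=values)


def _clamped(left: float, right: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the excess to its sister."""
    if left < 0:
        right += left
        left = 0.0
    if right < 0:
        left += right
        right = 0.0
    return max(left, 0.0), max(right, 0.0)


def nj_tree(dm: DistanceMatrix, taxon_namespace=None) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix (≥ 3 taxa)."""
    n = len(dm.ids)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(list(dm.ids))
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)

    nodes: list[dendropy.Node] = []
    for label in dm.ids:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(label))
        nodes.append(node)
    D = dm.values.astype(float).copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int) -> None:
        """Join the active nodes at list positions i_pos < j_pos."""
        nonlocal D, active, nodes
        m = len(active)
        i, j = active[i_pos], active[j_pos]
        r = D[np.ix_(active, active)].sum(axis=1)
        dij = D[i, j]
        li = 0.5 * dij + (r[i_pos] - r[j_pos]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamped(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        new_row = np.zeros(D.shape[0] + 1)
        for k_pos, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = (np.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] < best[0]:  # strict: first (lowest index) pair wins ties
                    best = (Q[a, b], a, b)
        join(best[1], best[2])

    # resolve the final three nodes around a central trifurcation
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj = _clamped(li, lj)
    lk = max(lk, 0.0)
    center = dendropy.Node()
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        center.add_child(node)
        node.edge.length = length
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def path_length_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree, as a DistanceMatrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = tuple(t.label for t in taxa)
    n = len(ids)
    values = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            values[a, b] = values[b, a] = pdm.patristic_distance(taxa[a], taxa[b])
    return DistanceMatrix(ids=ids, values=values)


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unweighted Robinson–Foulds distance; trees with distinct taxon
    namespaces are re-read onto a common one by label."""
    if tree_a.taxon_namespace is not tree_b.taxon_namespace:
        namespace = dendropy.TaxonNamespace()
        tree_a = dendropy.Tree.get(
            data=tree_a.as_string(schema="newick"), schema="newick",
            taxon_namespace=namespace,
        )
        tree_b = dendropy.Tree.get(
            data=tree_b.as_string(schema="newick"), schema="newick",
            taxon_namespace=namespace,
        )
    tree_a.encode_bipartitions()
    tree_b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(tree_a, tree_b)


def bootstrap_support(
    alignment: dict[str, str],
    n_replicates: int,
    seed: int,
    model: str = "p",
) -> dendropy.Tree:
    """Full-data NJ tree with bootstrap supports on internal bipartitions.

    Columns are resampled with replacement ``n_replicates`` times; each
    internal edge of the full-data tree is labelled with the percentage of
    replicate trees containing the same bipartition.  Reproducible for a
    fixed seed.
    """
    if len(alignment) < 3:
        raise ValidationError("bootstrap needs at least 3 sequences")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    ids = list(alignment)
    seqs = [alignment[i] for i in ids]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValidationError("alignment is not rectangular")

    namespace = dendropy.TaxonNamespace(ids)
    full_tree = nj_tree(distance_matrix(alignment, model), taxon_namespace=namespace)
    full_tree.encode_bipartitions()

    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}
    arr = np.array([list(s) for s in seqs])
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {
            ids[r]: "".join(arr[r, cols]) for r in range(len(ids))
        }
        rep = nj_tree(distance_matrix(resampled, model), taxon_namespace=namespace)
        rep.encode_bipartitions()
        for bp in rep.bipartition_encoding:
            key = bp.split_bitmask
            counts[key] = counts.get(key, 0) + 1

    for edge in full_tree.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or edge.tail_node is None:
            continue
        support = 100.0 * counts.get(edge.bipartition.split_bitmask, 0) / n_replicates
        head.label = str(int(round(support)))
    return full_tree
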