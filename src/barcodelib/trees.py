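"""Neighbor-joining tree construction, Newick I/O and reciprocal-monophyly
screening.

Trees are handled as :class:`dendropy.Tree` objects with leaf labels equal to
record ids.  Monophyly is defined on unrooted bipartitions: a species with
k >= 2 leaves is monophyletic iff some edge of the tree separates exactly its
leaf set from the rest, which makes verdicts independent of rooting.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)


class NewickError(Exception):
    pass


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion are broken by the lowest (i, j) index pair in
    the current agglomeration order.  Negative branch lengths are clamped to
    zero with a warning; masked distances are imputed by the maximum
    observed distance with a warning.  On an additive input matrix the
    output tree's path-length matrix reproduces the input exactly (to
    numerical precision).
    """
    n = matrix.n
    if n < 3:
        raise ValueError("neighbor joining requires >=3 taxa")
    d = matrix.d.astype(float).copy()
    if np.isnan(d).any():
        fill = np.nanmax(d)
        logger.warning("imputing %d masked cells with max distance %.4f",
                       int(np.isnan(d).sum()) // 2, fill)
        d = np.where(np.isnan(d), fill, d)
        np.fill_diagonal(d, 0.0)

    taxon_namespace = dendropy.TaxonNamespace(matrix.ids)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes: list[dendropy.Node] = []
    for label in matrix.ids:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(label))
        nodes.append(node)
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    def clamp(value: float) -> float:
        if value < 0:
            if value < -1e-9:
                logger.warning("negative NJ branch length %.6f clamped to 0", value)
            return 0.0
        return value

    next_index = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for a_pos, i in enumerate(active):
            for j in active[a_pos + 1 :]:
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = get(i, j)
        vi = clamp(0.5 * dij + (r[i] - r[j]) / (2 * (m - 2)))
        vj = clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))))
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = vi
        nj.edge.length = vj
        nodes.append(parent)
        new = next_index
        next_index += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(k, new) if k < new else (new, k)] = 0.5 * (
                get(i, k) + get(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [new]

    # Final three nodes join at an unrooted central node of degree 3.
    a, b, c = active
    va = clamp(0.5 * (get(a, b) + get(a, c) - get(b, c)))
    vb = clamp(0.5 * (get(a, b) + get(b, c) - get(a, c)))
    vc = clamp(0.5 * (get(a, c) + get(b, c) - get(a, b)))
    center = dendropy.Node()
    for node, length in ((nodes[a], va), (nodes[b], vb), (nodes[c], vc)):
        center.add_child(node)
        node.edge.length = length
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            key = tuple(sorted((t1.label, t2.label)))
            out[key] = pdm.distance(t1, t2)
    return out


def read_newick(path) -> dendropy.Tree:
    """Read one Newick tree; internal node labels are parsed as support
    values (stored on ``node.label``); quoted labels are preserved."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises a zoo of parse errors
        raise NewickError(f"failed to parse Newick file {path}: {exc}") from exc
    for node in tree.internal_nodes():
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                node.support = None
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                unquoted_underscores=True,
                suppress_rooting=True,
                real_value_format_specifier=".6f",
            )
        )


def _leaf_bipartitions(tree: dendropy.Tree) -> list[frozenset[str]]:
    """One side of every edge's bipartition, as leaf-label sets.

    Computed by postorder accumulation from an arbitrary rooting; each
    internal edge contributes its subtree leaf set (the complement is the
    other side, so both orientations are implicitly covered).
    """
    sides: list[frozenset[str]] = []
    subtree: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            subtree[id(node)] = frozenset({node.taxon.label})
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= subtree[id(child)]
            subtree[id(node)] = frozenset(acc)
        if node.parent_node is not None:
            sides.append(subtree[id(node)])
    return sides


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def is_monophyletic(tree: dendropy.Tree, leaf_set: set[str]) -> bool:
    """True iff some edge bipartition isolates exactly *leaf_set*."""
    all_leaves = frozenset(leaf_labels(tree))
    target = frozenset(leaf_set)
    if not target <= all_leaves:
        raise ValueError("leaf set contains labels not in tree")
    if len(target) <= 1 or target == all_leaves:
        return True
    for side in _leaf_bipartitions(tree):
        if side == target or (all_leaves - side) == target:
            return True
    return False


def monophyly_report(
    tree: dendropy.Tree, species_map: dict[str, str]
) -> dict[str, dict]:
    """Per species: monophyly verdict and, for failures, the minimal set of
    intruding species.

    Every leaf must be mapped.  Singletons are reported trivially
    monophyletic and never listed as failures.  For a failing species the
    smallest bipartition side containing all its leaves is located and the
    other species with leaves inside it are reported as intruders.
    """
    labels = leaf_labels(tree)
    unmapped = [l for l in labels if l not in species_map]
    if unmapped:
        raise ValueError(f"unmapped leaves: {unmapped[:5]}")
    all_leaves = frozenset(labels)
    by_species: dict[str, frozenset[str]] = {}
    for label in labels:
        sp = species_map[label]
        by_species[sp] = by_species.get(sp, frozenset()) | {label}
    sides = _leaf_bipartitions(tree)
    both_orientations = sides + [all_leaves - s for s in sides]

    report: dict[str, dict] = {}
    for species, leaves in sorted(by_species.items()):
        if len(leaves) == 1:
            report[species] = {
                "monophyletic": True,
                "trivial": True,
                "n_leaves": 1,
                "intruders": [],
            }
            continue
        mono = leaves == all_leaves or any(
            side == leaves for side in both_orientations
        )
        intruders: list[str] = []
        if not mono:
            containing = [s for s in both_orientations if leaves <= s]
            smallest = min(containing, key=len)  # root side always qualifies
            intruders = sorted(
                {species_map[l] for l in smallest - leaves}
            )
        report[species] = {
            "monophyletic": mono,
            "trivial": False,
            "n_leaves": len(leaves),
            "intruders": intruders,
        }
    return report
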