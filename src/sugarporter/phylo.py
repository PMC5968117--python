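"""Distance-based phylogeny with bootstrap supports and clade extraction.

The tree stage trims gap-rich alignment columns, computes Poisson-corrected
pairwise distances under pairwise deletion, builds a neighbor-joining tree,
attaches bootstrap supports by column resampling, roots the tree on a
user-supplied outgroup, and reports the maximal well-supported clades.
Substrate labels of characterized transporters are then propagated to the
clades that contain them.

Trees are :class:`dendropy.Tree` objects throughout; bootstrap supports are
stored as internal-node labels (integer percent in [0, 100]) so they
survive a Newick round-trip.  An externally computed tree (for example from
a maximum-likelihood program) can be imported with :func:`read_tree` and
used anywhere a tree is expected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .seqio import MSA, ProteinRecord

# -ln(1-p) saturates as p -> 1; p is clipped here so matrices stay finite.
SATURATION_P = 0.999


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise ValueError("distances must be finite and nonnegative")


@dataclass
class Clade:
    clade_id: str
    members: list[str]
    support: int
    substrate_labels: set[str] = field(default_factory=set)

    def candidate_members(self, candidates: set[str]) -> list[str]:
        return [m for m in self.members if m in candidates]


@dataclass
class CladeAssignment:
    clades: list[Clade]
    unplaced: list[str]

    def membership(self) -> dict[str, str]:
        """Leaf id -> clade id for every placed member."""
        out: dict[str, str] = {}
        for clade in self.clades:
            for m in clade.members:
                out[m] = clade.clade_id
        return out


def trim_gap_columns(msa: MSA, max_gap_fraction: float = 0.20) -> MSA:
    """Drop alignment columns whose gap fraction exceeds the threshold.

    A column at exactly the threshold is retained (the rule removes columns
    with *more* gaps than allowed).  Idempotent by construction.
    """
    if not 0 <= max_gap_fraction < 1:
        raise ValueError("max_gap_fraction must be in [0, 1)")
    frac = msa.gap_fraction()
    # guard the boundary against float noise from the mean
    keep = [k for k in range(msa.n_cols) if frac[k] <= max_gap_fraction + 1e-12]
    if not keep:
        raise ValueError("alignment fully trimmed: every column exceeds the gap threshold")
    return msa.select_columns(keep)


def _encode_rows(msa: MSA) -> np.ndarray:
    """(rows, cols) int8 codes; gaps -> -1."""
    arr = msa.to_array()
    codes = np.frombuffer(arr.astype("S1").tobytes(), dtype=np.int8).reshape(arr.shape).copy()
    codes[arr == "-"] = -1
    return codes


def _pdist_from_codes(codes: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    valid = codes >= 0
    shared = (valid[:, None, :] & valid[None, :, :]).sum(axis=2)
    mism = ((codes[:, None, :] != codes[None, :, :]) & valid[:, None, :] & valid[None, :, :]).sum(axis=2)
    n = codes.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(shared[off] == 0):
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValueError(
            f"rows {labels[i]!r} and {labels[j]!r} share no ungapped columns"
        )
    with np.errstate(invalid="ignore"):
        p = np.where(shared > 0, mism / np.maximum(shared, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    return p


def pairwise_distances(msa: MSA, correction: str = "poisson") -> DistanceMatrix:
    """Pairwise distances under pairwise deletion of gapped columns.

    ``p``: proportion of mismatches among columns ungapped in both rows.
    ``poisson``: -ln(1 - p), with p clipped at 0.999 so saturated pairs
    stay finite.
    """
    if correction not in {"p", "poisson"}:
        raise ValueError(f"unknown distance correction {correction!r}")
    codes = _encode_rows(msa)
    p = _pdist_from_codes(codes, msa.ids)
    if correction == "poisson":
        d = -np.log(1.0 - np.clip(p, 0.0, SATURATION_P))
    else:
        d = p
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(msa.ids), matrix=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining (Saitou-Nei Q criterion), unrooted.

    Ties in the Q minimization are broken by the lowest (row, column) index
    pair, so the topology is deterministic.  Negative limb lengths are
    clamped to zero with the deficit shifted onto the sibling limb.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)
    D = dm.matrix.astype(float).copy()
    active = list(range(n))

    def _pick_pair(Dm: np.ndarray, m: int) -> tuple[int, int]:
        r = Dm.sum(axis=1)
        Q = (m - 2) * Dm - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # argmin returns the first minimum: lowest (i, j)
        return divmod(flat, m)

    node_of = {i: nodes[i] for i in active}
    idx = list(range(n))
    while len(idx) > 3:
        m = len(idx)
        Dm = D[np.ix_(idx, idx)]
        a, b = _pick_pair(Dm, m)
        i, j = idx[a], idx[b]
        r = Dm.sum(axis=1)
        la = 0.5 * Dm[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = Dm[a, b] - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        for child, length in ((node_of[i], la), (node_of[j], lb)):
            parent.add_child(child)
            child.edge.length = float(length) + 0.0  # normalizes -0.0
        # distances from the new node to the remaining ones
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        node_of[i] = parent
        idx.remove(j)
    # join the last three around a central node (three-point formulas)
    x, y, z = idx
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    center = dendropy.Node()
    for k, length in ((x, lx), (y, ly), (z, lz)):
        center.add_child(node_of[k])
        node_of[k].edge.length = float(max(length, 0.0)) + 0.0
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def leaf_set(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Canonical nontrivial bipartitions of an (un)rooted tree.

    Each internal edge is keyed by the side of the split that does not
    contain the lexicographically smallest leaf label.
    """
    all_leaves = leaf_set(tree.seed_node)
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = leaf_set(node)
        if len(below) < 2 or len(all_leaves - below) < 2:
            continue
        splits.add(below if ref not in below else all_leaves - below)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance via symmetric split difference."""
    return len(tree_splits(t1) ^ tree_splits(t2))


def _split_key(below: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    ref = min(all_leaves)
    return below if ref not in below else all_leaves - below


def bootstrap_supports(
    msa: MSA,
    replicates: int = 500,
    seed: int = 0,
    correction: str = "poisson",
) -> dendropy.Tree:
    """NJ point-estimate tree annotated with bootstrap supports.

    Alignment columns are resampled with replacement per replicate, the NJ
    tree recomputed, and every internal edge of the point tree labeled with
    the integer percentage of replicates whose tree contains the same leaf
    bipartition.  The same seed always yields the same supports.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    codes = _encode_rows(msa)
    labels = list(msa.ids)

    def _tree_from_codes(c: np.ndarray) -> dendropy.Tree:
        p = _pdist_from_codes(c, labels)
        if correction == "poisson":
            d = -np.log(1.0 - np.clip(p, 0.0, SATURATION_P))
        else:
            d = p
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        return nj_tree(DistanceMatrix(labels=labels, matrix=d))

    point = _tree_from_codes(codes)
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    ncol = codes.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = _tree_from_codes(codes[:, cols])
        for split in tree_splits(rep):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = frozenset(labels)
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        below = leaf_set(node)
        if len(below) < 2 or len(all_leaves - below) < 2:
            continue
        key = _split_key(below, all_leaves)
        support = int(round(100.0 * counts.get(key, 0) / replicates))
        node.label = str(support)
    return point


def _support_map(tree: dendropy.Tree) -> dict[frozenset[str], str]:
    all_leaves = leaf_set(tree.seed_node)
    out: dict[frozenset[str], str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf() or node.label is None:
            continue
        below = leaf_set(node)
        if len(below) < 2 or len(all_leaves - below) < 2:
            continue
        out[_split_key(below, all_leaves)] = node.label
    return out


def root_on_outgroup(tree: dendropy.Tree, outgroup_ids: Iterable[str]) -> dendropy.Tree:
    """Root the tree on the edge separating the outgroup from the ingroup.

    The outgroup must be present and monophyletic in the unrooted tree;
    bipartition supports are preserved (they are re-attached by split
    identity after rerooting, since node labels can migrate when the tree
    is re-oriented).
    """
    outgroup = frozenset(outgroup_ids)
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    tree = tree.clone(depth=1)
    all_leaves = leaf_set(tree.seed_node)
    missing = outgroup - all_leaves
    if missing:
        raise ValueError(f"outgroup ids not in tree: {sorted(missing)}")
    if not (all_leaves - outgroup):
        raise ValueError("outgroup cannot contain every leaf")
    supports = _support_map(tree)
    # find the edge whose split is exactly outgroup vs ingroup
    target = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = leaf_set(node)
        if below == outgroup or below == all_leaves - outgroup:
            target = node
            break
    if target is None:
        if len(outgroup) == 1:
            raise ValueError("outgroup leaf not attached by a terminal edge")  # pragma: no cover
        raise ValueError(
            "outgroup is not monophyletic: no edge separates "
            f"{sorted(outgroup)} from the ingroup"
        )
    length = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    tree.suppress_unifurcations()
    # re-attach supports by split identity
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        below = leaf_set(node)
        if len(below) < 2 or len(all_leaves - below) < 2:
            node.label = None
            continue
        node.label = supports.get(_split_key(below, all_leaves))
    tree.seed_node.label = None
    return tree


def collapse_short_edges(
    tree: dendropy.Tree, min_length: float = 0.02
) -> dendropy.Tree:
    """Collapse internal edges shorter than ``min_length`` into polytomies.

    An internal edge whose estimated length is (near) zero is an arbitrary
    resolution of an effectively multifurcating node, and the bootstrap
    can lend such edges spuriously moderate support; collapsing them first
    is the standard safeguard.  Leaf edges and the root's child edges are
    never collapsed.  Returns a modified copy.
    """
    tree = tree.clone(depth=1)
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder_node_iter()):
            if node.is_leaf() or node is tree.seed_node:
                continue
            if node.parent_node is tree.seed_node and tree.is_rooted:
                continue
            if (node.edge.length or 0.0) < min_length:
                node.edge.collapse()
                changed = True
                break
    return tree


def extract_supported_clades(
    tree: dendropy.Tree,
    candidates: Iterable[str],
    references: Iterable[str],
    min_support: int = 60,
    strict: bool = False,
    min_candidates: int = 2,
    include_root_split: bool = False,
    min_branch_length: float = 0.02,
) -> CladeAssignment:
    """Maximal well-supported clades of a rooted tree, outgroup excluded.

    Walks the rooted tree from the root and reports the internal nodes
    closest to the root whose bootstrap support meets the threshold
    (inclusive by default, strict when ``strict=True``), whose subtree
    contains at least ``min_candidates`` candidates and no outgroup leaf
    (a leaf that is neither candidate nor reference).  Descendants of a
    reported clade are not reported again, so every candidate lands in at
    most one clade; the rest are returned as unplaced.

    The support on the root's child edges belongs to the bipartition the
    tree was rooted on (outgroup vs ingroup); by default it is treated as
    rooting evidence rather than clade evidence, so the search starts below
    the ingroup root.  ``include_root_split=True`` lets the full ingroup
    qualify as a single clade instead.

    Internal edges shorter than ``min_branch_length`` are collapsed into
    polytomies first (see :func:`collapse_short_edges`); pass 0 to disable.
    """
    if min_branch_length > 0:
        tree = collapse_short_edges(tree, min_branch_length)
    candidates = set(candidates)
    references = set(references)
    all_leaves = leaf_set(tree.seed_node)
    outgroup = all_leaves - candidates - references
    clades: list[Clade] = []
    placed: set[str] = set()
    root_children = set(tree.seed_node.child_nodes())

    def qualifies(node: dendropy.Node) -> bool:
        if node.is_leaf() or node.label is None:
            return False
        if node in root_children and not include_root_split:
            return False
        try:
            support = int(round(float(node.label)))
        except ValueError:
            return False
        if strict and not support > min_support:
            return False
        if not strict and not support >= min_support:
            return False
        below = leaf_set(node)
        if below & outgroup:
            return False
        return len(below & candidates) >= min_candidates

    stack = [tree.seed_node]
    while stack:
        node = stack.pop(0)
        if qualifies(node):
            below = leaf_set(node)
            clades.append(
                Clade(
                    clade_id=f"C{len(clades) + 1}",
                    members=sorted(below),
                    support=int(round(float(node.label))),
                    substrate_labels=set(),
                )
            )
            placed |= below & candidates
        else:
            stack.extend(node.child_nodes())
    unplaced = sorted(candidates - placed)
    return CladeAssignment(clades=clades, unplaced=unplaced)


def propagate_substrate_labels(
    assignment: CladeAssignment, references: Iterable[ProteinRecord]
) -> CladeAssignment:
    """Label each clade with the union of its characterized members' sugars.

    A clade containing no characterized transporter gets the single label
    ``unknown``.
    """
    by_id = {r.id: r for r in references}
    for clade in assignment.clades:
        labels: set[str] = set()
        for member in clade.members:
            rec = by_id.get(member)
            if rec is not None and rec.substrate_labels:
                labels |= set(rec.substrate_labels)
        clade.substrate_labels = labels or {"unknown"}
    return assignment


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    text = tree.as_string(
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
        real_value_format_specifier=".8g",
    )
    Path(path).write_text(text)


def read_tree(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc


def write_clades_tsv(assignment: CladeAssignment, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["clade_id", "support", "substrate_labels", "members"])
        for clade in assignment.clades:
            writer.writerow(
                [
                    clade.clade_id,
                    clade.support,
                    ";".join(sorted(clade.substrate_labels)),
                    ";".join(clade.members),
                ]
            )


def write_unplaced_tsv(assignment: CladeAssignment, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id"])
        for uid in assignment.unplaced:
            writer.writerow([uid])
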