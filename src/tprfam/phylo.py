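"""Distance-based phylogenetics and family-membership classification.

The family question here — is a TPR-containing protein a true family
member, or an unrelated TPR protein? — is answered on a neighbor-joining
tree rooted with divergent outgroup sequences (FKBP4-like TPR proteins in
the motivating analysis): candidates falling on the outgroup side of the
root are not family members.

Distances are p-distances with pairwise gap deletion
(``d = 1 - identity/100``).  Neighbor joining follows Saitou & Nei with two
determinism guarantees: Q-matrix ties are broken by the lexicographically
smallest label pair, and negative branch-length estimates are clamped to
zero with the deficit transferred to the sibling edge.  On an additive
distance matrix the algorithm recovers the generating tree exactly.

Trees are :class:`dendropy.Tree` objects (unrooted, internal nodes of
degree 3), so Newick I/O, rerooting and bipartition comparison come from
dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "AlignedSet",
    "DistanceMatrix",
    "pairwise_identity",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "classify_by_outgroup",
    "assign_subgroup",
    "read_aligned_fasta",
]

GAP = "-"


@dataclass
class AlignedSet:
    """A multiple alignment: unique labels, equal-length gapped rows, and an
    optional label -> lineage tag map (fish / amphibian / bird_reptile /
    mammal / outgroup)."""

    labels: list[str]
    rows: list[str]
    lineage_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(self.labels) < 3:
            raise ValueError("an AlignedSet needs at least 3 rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def char_matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")

    def resample_columns(self, rng: np.random.Generator) -> "AlignedSet":
        """Bootstrap pseudo-alignment: columns drawn with replacement."""
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        mat = self.char_matrix()[:, cols]
        return AlignedSet(
            labels=list(self.labels),
            rows=["".join(row) for row in mat],
            lineage_map=self.lineage_map,
        )


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if np.any(v < 0):
            raise ValueError("negative distances")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("non-zero diagonal")
        self.values = v

    @property
    def n_taxa(self) -> int:
        return len(self.labels)


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over columns where neither row has a gap.

    Returns 0 when the two gap masks leave no comparable column.
    """
    if len(a) != len(b):
        raise ValueError(f"row lengths differ: {len(a)} vs {len(b)}")
    comparable = matches = 0
    for ca, cb in zip(a, b):
        if ca == GAP or cb == GAP:
            continue
        comparable += 1
        matches += ca == cb
    if comparable == 0:
        return 0.0
    return 100.0 * matches / comparable


def distance_matrix(aln: AlignedSet) -> DistanceMatrix:
    """p-distance matrix with pairwise gap deletion: d = 1 - identity/100."""
    mat = aln.char_matrix()
    nongap = mat != GAP
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n - 1):
        both = nongap[i] & nongap[i + 1 :]
        eq = (mat[i] == mat[i + 1 :]) & both
        comparable = both.sum(axis=1)
        matches = eq.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(comparable > 0, matches / np.maximum(comparable, 1), 0.0)
        d[i, i + 1 :] = 1.0 - ident
        d[i + 1 :, i] = d[i, i + 1 :]
    return DistanceMatrix(list(aln.labels), d)


# ---------------------------------------------------------------------------
# neighbor joining

def _clamped(li: float, lj: float) -> tuple[float, float]:
    # negative estimate -> 0, deficit moved to the sibling edge
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Deterministic: Q ties go to the lexicographically smallest pair of
    cluster tags (a cluster's tag is its smallest member label).  Returns
    an unrooted dendropy tree whose seed node is the final trifurcation.
    """
    n = D.n_taxa
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    tns = dendropy.TaxonNamespace(D.labels)
    nodes: dict[int, dendropy.Node] = {
        i: dendropy.Node(taxon=tns.get_taxon(lbl)) for i, lbl in enumerate(D.labels)
    }
    tags = {i: lbl for i, lbl in enumerate(D.labels)}
    d: dict[int, dict[int, float]] = {
        i: {j: float(D.values[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    active = list(range(n))
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best_pair = None
        best_key = None
        for ai in range(m - 1):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i][j] - r[i] - r[j]
                tag_pair = tuple(sorted((tags[i], tags[j])))
                key = (q, tag_pair)
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (i, j)
        i, j = best_pair  # type: ignore[misc]
        dij = d[i][j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = dij - li
        li, lj = _clamped(li, lj)

        u = dendropy.Node()
        u.add_child(nodes[i])
        u.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        nodes[next_id] = u
        tags[next_id] = min(tags[i], tags[j])
        d[next_id] = {}
        for k in active:
            if k in (i, j):
                continue
            dk = (d[i][k] + d[j][k] - dij) / 2
            d[next_id][k] = dk
            d[k][next_id] = dk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    # three-point formulas for the final trifurcation
    la = (d[a][b] + d[a][c] - d[b][c]) / 2
    lb = (d[a][b] + d[b][c] - d[a][c]) / 2
    lc = (d[a][c] + d[b][c] - d[a][b]) / 2
    root = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap

def _nontrivial_splits(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Map each non-trivial bipartition (as the frozenset of leaf labels on
    the child side) to its subtending node."""
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_labels) - 1:
            out[side] = node
    return out


def _split_keys(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Canonical non-trivial split set: each bipartition keyed by the side
    NOT containing the lexicographically smallest leaf label."""
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(all_labels)
    keys = set()
    for side in _nontrivial_splits(tree):
        keys.add(side if anchor not in side else frozenset(all_labels - side))
    return keys


def bootstrap_support(
    aln: AlignedSet, replicates: int, seed: int
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ point tree plus bootstrap supports.

    Columns are resampled with replacement ``replicates`` times; the
    support of each bipartition in the point tree is the percentage of
    replicate trees containing it.  Supports are attached as internal-node
    labels and returned as a dict keyed by either side of each bipartition.
    Fully reproducible for a given seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = nj_tree(distance_matrix(aln))
    all_labels = set(aln.labels)
    anchor = min(all_labels)
    point_splits = _nontrivial_splits(tree)
    counts = {side: 0 for side in point_splits}

    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        rep_tree = nj_tree(distance_matrix(aln.resample_columns(rng)))
        rep_keys = _split_keys(rep_tree)
        for side in counts:
            key = side if anchor not in side else frozenset(all_labels - side)
            if key in rep_keys:
                counts[side] += 1

    supports: dict[frozenset[str], float] = {}
    for side, node in point_splits.items():
        pct = 100.0 * counts[side] / replicates
        node.label = f"{pct:g}"
        supports[side] = pct
        supports[frozenset(all_labels - side)] = pct
    return tree, supports


# ---------------------------------------------------------------------------
# outgroup-based classification

def _outgroup_clade_labels(
    tree: dendropy.Tree, target_labels: set[str], anchor_labels: set[str]
) -> tuple[set[str], bool]:
    """Root at an anchor leaf (lexicographically smallest of
    ``anchor_labels``) and return the label set of the smallest clade
    containing every target leaf, plus a target-monophyly flag."""
    work = tree.clone(depth=1)
    anchor = min(anchor_labels)
    anchor_leaf = None
    for lf in work.leaf_node_iter():
        if lf.taxon.label == anchor:
            anchor_leaf = lf
            break
    if anchor_leaf is None:
        raise ValueError(f"anchor label {anchor!r} not in tree")
    work.reroot_at_edge(anchor_leaf.edge, update_bipartitions=False)
    taxa = [t for t in work.taxon_namespace if t.label in target_labels]
    if len(taxa) != len(target_labels):
        missing = target_labels - {t.label for t in taxa}
        raise ValueError(f"labels missing from tree: {sorted(missing)}")
    mrca = work.mrca(taxa=taxa)
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade, clade == target_labels


def classify_by_outgroup(
    tree: dendropy.Tree,
    outgroup_labels: list[str],
    reference_labels: list[str],
    candidate_labels: list[str],
) -> dict[str, str]:
    """Classify candidates as ``member`` / ``non_member`` of the family.

    Rooting from the outgroup, the family is the smallest clade containing
    every reference sequence; a candidate inside it is a member, one
    falling outside — within or basal to the outgroup cluster — is not.
    A candidate sitting on the edge between family and outgroup is basal
    to the family and therefore not a member.  If the outgroup is not
    monophyletic a warning is issued (classification still proceeds by the
    same reference-clade rule, which ignores strays on the outgroup side).
    """
    if not outgroup_labels:
        raise ValueError("outgroup_labels must be non-empty")
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for lbl in list(outgroup_labels) + list(reference_labels):
        if lbl not in leaf_labels:
            raise ValueError(f"label {lbl!r} not in tree")
    _, mono = _outgroup_clade_labels(
        tree, set(outgroup_labels), set(reference_labels)
    )
    if not mono:
        warnings.warn(
            "outgroup is not monophyletic after rooting; classifying by the "
            "smallest reference-containing clade (majority-side rule)",
            stacklevel=2,
        )
    # member side: smallest clade holding all references, rooted from the
    # outgroup (the reference side of the outgroup attachment edge)
    member_side, _ = _outgroup_clade_labels(
        tree, set(reference_labels), set(outgroup_labels)
    )
    return {
        c: ("member" if c in member_side else "non_member")
        for c in candidate_labels
    }


def assign_subgroup(
    tree: dendropy.Tree, lineage_map: dict[str, str]
) -> dict[str, str]:
    """Label each non-outgroup leaf with its subgroup.

    After outgroup rooting, every maximal monophyletic group of
    same-lineage leaves is one subgroup, labelled ``<lineage>_<ordinal>``
    in tree traversal order.  Under purely lineage-specific expansion the
    subgroups coincide with the lineages; a duplication predating a
    lineage split shows up as two subgroups of the same lineage.
    """
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaf_labels if l not in lineage_map]
    if missing:
        raise ValueError(f"lineage_map missing labels: {missing[:5]}")
    outgroup = {l for l in leaf_labels if lineage_map[l] == "outgroup"}
    ingroup = [l for l in leaf_labels if l not in outgroup]

    work = tree.clone(depth=1)
    if outgroup and ingroup:
        # root from the outgroup so ingroup clades are oriented correctly
        anchor = min(outgroup)
        for lf in work.leaf_node_iter():
            if lf.taxon.label == anchor:
                work.reroot_at_edge(lf.edge, update_bipartitions=False)
                break

    assignments: dict[str, str] = {l: "outgroup" for l in outgroup}
    counters: dict[str, int] = {}

    def node_lineages(node: dendropy.Node) -> set[str]:
        return {lineage_map[lf.taxon.label] for lf in node.leaf_iter()}

    def descend(node: dendropy.Node) -> None:
        lineages = node_lineages(node)
        if lineages == {"outgroup"}:
            return
        if len(lineages) == 1:
            lineage = lineages.pop()
            counters[lineage] = counters.get(lineage, 0) + 1
            label = f"{lineage}_{counters[lineage]}"
            for lf in node.leaf_iter():
                assignments[lf.taxon.label] = label
            return
        for child in node.child_nodes():
            descend(child)

    descend(work.seed_node)
    return assignments


# ---------------------------------------------------------------------------
# I/O

def read_aligned_fasta(path) -> AlignedSet:
    """Read an aligned FASTA into an AlignedSet."""
    from Bio import SeqIO

    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq).upper())
    return AlignedSet(labels=labels, rows=rows)
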