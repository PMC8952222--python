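"""Sequence-alignment and phylogenetic-tree containers with their file formats.

The two central types are :class:`Msa` (a per-protein multiple sequence
alignment keyed by species) and :class:`PhyloTree` (a branch-length tree over
species labels, backed by :mod:`dendropy`).  Everything downstream — column
variation vectors, divergence-time correction, species trimming — is computed
from these two objects, so their invariants are enforced strictly here.

Trees are built from alignments with a Poisson-corrected p-distance followed
by neighbour joining; they can be pruned to a species subset (contracting
unary nodes so that patristic distances are preserved) and rooted at the
point that minimises tree height.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "Msa",
    "PhyloTree",
    "DistanceMatrix",
    "AlignmentShapeError",
    "DuplicateLabelError",
    "EmptyInputError",
    "IncomparablePairError",
    "TooFewTaxaError",
    "UnknownLabelError",
    "read_msa",
    "write_msa",
    "read_newick",
    "write_newick",
    "protein_distance_matrix",
    "nj_tree",
    "root_min_height",
    "prune_tree",
    "patristic_distances",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residue alphabet: the 20 amino acids, 'X' for unknown, '-' for a gap.
ALPHABET = AMINO_ACIDS + "X-"

_CODE = {ch: i for i, ch in enumerate(ALPHABET)}
GAP_CODE = _CODE["-"]
X_CODE = _CODE["X"]

# p-distances are capped here before the Poisson correction -ln(1-p) so that
# near-saturated pairs cannot produce infinite distances.
P_DISTANCE_CAP = 0.95


class AlignmentShapeError(ValueError):
    """Sequences in one alignment do not all have the same length."""


class DuplicateLabelError(ValueError):
    """A species label occurs more than once where uniqueness is required."""


class EmptyInputError(ValueError):
    """An input file or container held no records."""


class IncomparablePairError(ValueError):
    """Two sequences share no gap-free column, so no distance is defined."""


class TooFewTaxaError(ValueError):
    """An operation needs more taxa than were supplied."""


class UnknownLabelError(KeyError):
    """A requested label is not present in the tree or alignment."""


@dataclass
class Msa:
    """A multiple sequence alignment for one protein, one row per species.

    Sequences are upper-cased on construction and validated against the
    residue alphabet; all rows must have equal, non-zero length and species
    labels must be unique.
    """

    protein_id: str
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise EmptyInputError(f"{self.protein_id}: alignment has no rows")
        self.rows = [(sp, seq.upper()) for sp, seq in self.rows]
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"{self.protein_id}: ragged alignment, lengths {sorted(lengths)}"
            )
        if 0 in lengths:
            raise AlignmentShapeError(f"{self.protein_id}: zero-length sequences")
        species = [sp for sp, _ in self.rows]
        if len(set(species)) != len(species):
            dupes = sorted({s for s in species if species.count(s) > 1})
            raise DuplicateLabelError(
                f"{self.protein_id}: duplicate species labels {dupes}"
            )
        bad = {ch for _, seq in self.rows for ch in seq} - set(ALPHABET)
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal characters {sorted(bad)} "
                f"(allowed: {ALPHABET})"
            )

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def species(self) -> list[str]:
        return [sp for sp, _ in self.rows]

    def sequence(self, species: str) -> str:
        for sp, seq in self.rows:
            if sp == species:
                return seq
        raise UnknownLabelError(species)

    def column(self, index: int) -> str:
        return "".join(seq[index] for _, seq in self.rows)

    def to_codes(self) -> np.ndarray:
        """Integer-encode the alignment as an (n_rows, length) array."""
        flat = "".join(seq for _, seq in self.rows)
        codes = np.frombuffer(flat.encode("ascii"), dtype=np.uint8)
        table = np.zeros(128, dtype=np.int8)
        for ch, i in _CODE.items():
            table[ord(ch)] = i
        return table[codes].reshape(self.n_rows, self.length)

    def subset(self, keep: Iterable[str], sort: bool = True) -> "Msa":
        keep = set(keep)
        missing = keep - set(self.species)
        if missing:
            raise UnknownLabelError(f"{self.protein_id}: {sorted(missing)}")
        rows = [(sp, seq) for sp, seq in self.rows if sp in keep]
        if sort:
            rows.sort(key=lambda r: r[0])
        return Msa(self.protein_id, rows)

    def drop_columns(self, drop: Iterable[int]) -> "Msa":
        drop = set(drop)
        rows = [
            (sp, "".join(c for i, c in enumerate(seq) if i not in drop))
            for sp, seq in self.rows
        ]
        return Msa(self.protein_id, rows)


def read_msa(path: str | Path, protein_id: str | None = None) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    The species label is the first whitespace-delimited token of each header.
    Row order follows file order.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    rows = [(rec.id, str(rec.seq)) for rec in records]
    return Msa(protein_id or path.stem, rows)


def write_msa(msa: Msa, path: str | Path) -> Path:
    """Write an :class:`Msa` as FASTA, 60 characters per line, LF endings."""
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=sp, description="") for sp, seq in msa.rows
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")
    return path


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered label list."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise DuplicateLabelError("duplicate labels in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


class PhyloTree:
    """A branch-length phylogenetic tree with unique leaf labels.

    Thin wrapper around a :class:`dendropy.Tree` providing the operations the
    screening pipeline needs: Newick round-trip, pruning with patristic
    preservation, minimum-height rooting, and patristic distance matrices.
    """

    def __init__(self, dtree: dendropy.Tree):
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DuplicateLabelError(f"duplicate leaf labels {dupes}")
        for edge in dtree.preorder_edge_iter():
            if edge.length is None:
                if edge.head_node is not dtree.seed_node:
                    edge.length = 0.0
            elif edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        self._tree = dtree

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
                raise DuplicateLabelError(str(exc)) from exc
            raise ValueError(f"Newick parse error: {exc}") from exc
        return cls(dtree)

    # -- basic accessors ---------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def rooted(self) -> bool:
        return bool(self._tree.is_rooted)

    def total_length(self) -> float:
        return float(self._tree.length())

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        ).strip()
        return s if s.endswith(";") else s + ";"

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- operations --------------------------------------------------------

    def height(self) -> float:
        """Maximum root-to-leaf path length."""
        return max(
            lf.distance_from_root() for lf in self._tree.leaf_node_iter()
        )

    def patristic_distances(self) -> DistanceMatrix:
        labels = self.leaf_labels
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        values = np.zeros((n, n))
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace if t.label in index}
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
                values[i, j] = values[j, i] = d
        return DistanceMatrix(labels, values)

    def prune(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict to ``keep`` leaves; unary nodes are contracted with
        branch lengths summed, so patristic distances are preserved."""
        keep = set(keep)
        have = set(self.leaf_labels)
        unknown = keep - have
        if unknown:
            raise UnknownLabelError(sorted(unknown))
        if len(keep) < 2:
            raise TooFewTaxaError("pruning must retain at least 2 leaves")
        if keep == have:
            return self.clone()
        dtree = self._tree.clone(depth=1)
        dtree.retain_taxa_with_labels(sorted(keep))
        # Contract a possibly-unary root so no unary node survives.
        root = dtree.seed_node
        while len(root.child_nodes()) == 1:
            child = root.child_nodes()[0]
            for grand in list(child.child_nodes()):
                if grand.edge.length is None:
                    grand.edge.length = 0.0
                grand.edge.length += child.edge.length or 0.0
                child.remove_child(grand)
                root.add_child(grand)
            root.remove_child(child)
            if not root.child_nodes():
                break
        return PhyloTree(dtree)

    def root_min_height(self) -> "PhyloTree":
        """Re-root at the point minimising the tree height.

        The minimiser of the maximum root-to-leaf distance is the metric
        centre of the tree: the midpoint of the longest leaf-to-leaf path.
        The diameter pair is found exhaustively (ties broken by smallest
        label pair) and the root is placed on the edge containing the
        midpoint, splitting its length.
        """
        if self.n_leaves < 2:
            raise TooFewTaxaError("rooting needs at least 2 leaves")
        dtree = self._tree.clone(depth=1)
        leaves = sorted(dtree.leaf_node_iter(), key=lambda n: n.taxon.label)

        def ancestry(node):
            """(node, distance-from-start) pairs from a leaf up to the root."""
            chain = [(node, 0.0)]
            dist = 0.0
            while node.parent_node is not None:
                dist += node.edge.length or 0.0
                node = node.parent_node
                chain.append((node, dist))
            return chain

        chains = {lf: ancestry(lf) for lf in leaves}
        best = None  # (diameter, label_u, label_v, u, v)
        for i, u in enumerate(leaves):
            index_u = {id(n): d for n, d in chains[u]}
            for v in leaves[i + 1 :]:
                for node, dv in chains[v]:
                    if id(node) in index_u:  # lowest common ancestor
                        diam = index_u[id(node)] + dv
                        key = (-diam, u.taxon.label, v.taxon.label)
                        if best is None or key < best[0]:
                            best = (key, u, v)
                        break
        (_, u, v) = best
        # walk from u towards v and find the edge holding the midpoint
        index_u = {id(n): d for n, d in chains[u]}
        lca = next(n for n, _ in chains[v] if id(n) in index_u)
        up = []  # nodes from u to lca with cumulative distance
        for node, d in chains[u]:
            up.append((node, d))
            if node is lca:
                break
        down = []
        for node, d in chains[v]:
            if node is lca:
                break
            down.append((node, d))
        diameter = index_u[id(lca)] + (
            next(d for n, d in chains[v] if n is lca)
        )
        half = diameter / 2.0
        # path as (child_node, head_pos, tail_pos): positions from u of the
        # edge's head (child) and tail (parent) nodes
        segments = []
        for node, d in up[:-1]:
            segments.append((node, d, d + (node.edge.length or 0.0)))
        for node, d in reversed(down):
            end = diameter - d
            segments.append((node, end, end - (node.edge.length or 0.0)))
        child = head_pos = tail_pos = None
        for node, hp, tp in segments:
            if min(hp, tp) <= half <= max(hp, tp):
                child, head_pos, tail_pos = node, hp, tp
                break
        edge = child.edge
        elen = edge.length or 0.0
        length2 = min(max(abs(half - head_pos), 0.0), elen)  # head (child) side
        length1 = elen - length2
        dtree.reroot_at_edge(
            edge, length1=length1, length2=length2, update_bipartitions=False
        )
        dtree.is_rooted = True
        return PhyloTree(dtree)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PhyloTree({self.n_leaves} leaves, length={self.total_length():.4g})"


def read_newick(path: str | Path) -> PhyloTree:
    text = Path(path).read_text(encoding="utf-8").strip()
    if not text:
        raise EmptyInputError(f"empty Newick file {path}")
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    text = tree.to_newick() + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8", newline="\n")
    return text


def protein_distance_matrix(msa: Msa) -> DistanceMatrix:
    """Poisson-corrected p-distances between all alignment rows.

    For each pair the proportion of mismatches ``p`` is computed over columns
    where neither sequence has a gap, then corrected as ``d = -ln(1 - p)``.
    ``p`` is capped at :data:`P_DISTANCE_CAP` (with a warning) so the
    correction stays finite; a pair with no shared gap-free column has no
    defined distance and raises :class:`IncomparablePairError`.
    """
    if msa.n_rows < 2:
        raise TooFewTaxaError("distance matrix needs at least 2 sequences")
    codes = msa.to_codes()
    not_gap = codes != GAP_CODE
    n = msa.n_rows
    values = np.zeros((n, n))
    capped = False
    for i in range(n):
        for j in range(i + 1, n):
            both = not_gap[i] & not_gap[j]
            shared = int(both.sum())
            if shared == 0:
                raise IncomparablePairError(
                    f"{msa.protein_id}: rows {msa.species[i]!r} and "
                    f"{msa.species[j]!r} share no gap-free column"
                )
            p = float((codes[i][both] != codes[j][both]).sum()) / shared
            if p >= P_DISTANCE_CAP:
                p = P_DISTANCE_CAP
                capped = True
            values[i, j] = values[j, i] = -math.log(1.0 - p)
    if capped:
        warnings.warn(
            f"{msa.protein_id}: some p-distances reached the cap "
            f"{P_DISTANCE_CAP}; corrected distances were truncated",
            stacklevel=2,
        )
    return DistanceMatrix(list(msa.species), values)


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Neighbour joining (Saitou–Nei) on a distance matrix.

    Returns the unrooted NJ tree.  Negative branch-length estimates are
    clamped to zero with the deficit moved to the sibling branch, which keeps
    the distance between the joined pair unchanged.  On an additive matrix the
    generating topology and branch lengths are recovered exactly.
    """
    n = len(dist.labels)
    if n < 3:
        raise TooFewTaxaError("neighbour joining needs at least 3 taxa")
    d = dist.values.astype(float).copy()
    # Each active entry is a newick fragment for the subtree it roots.
    nodes: list[str] = [_quote_label(l) for l in dist.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        gi, gj = active[ai], active[aj]
        new_frag = f"({nodes[gi]}:{float(li)!r},{nodes[gj]}:{float(lj)!r})"
        # distances from the new node to every other active taxon
        rest = [g for g in active if g not in (gi, gj)]
        for g in rest:
            du = 0.5 * (d[gi, g] + d[gj, g] - dij)
            d[gi, g] = d[g, gi] = max(du, 0.0)
        nodes[gi] = new_frag
        active = [g for g in active if g != gj]
        # gi now represents the merged node

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = (
        f"({nodes[a]}:{float(la)!r},{nodes[b]}:{float(lb)!r},"
        f"{nodes[c]}:{float(lc)!r});"
    )
    tree = PhyloTree.from_newick(newick)
    tree._tree.is_rooted = False
    return tree


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "();,:[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def root_min_height(tree: PhyloTree) -> PhyloTree:
    return tree.root_min_height()


def prune_tree(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    return tree.prune(keep)


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    return tree.patristic_distances()
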