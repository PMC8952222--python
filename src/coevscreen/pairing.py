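"""Protein-pair preparation: unique pair enumeration and shared-species
trimming.

For each unordered pair of proteins, the two alignments are restricted to the
species found in both, columns that become entirely gaps are removed (a
variation vector cannot be computed for them), and the trees — when given —
are pruned to the shared species.  Original column coordinates are preserved
through an index map so that every report uses pre-trim numbering.  Pairs
sharing fewer species than the configured minimum are rejected, not errored:
rejection is a recorded outcome of the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from coevscreen.core_io import GAP_CODE, Msa, PhyloTree
from coevscreen.msa_quality import ColumnQuality

__all__ = [
    "PairInput",
    "PairRejection",
    "pair_id_of",
    "enumerate_pairs",
    "build_pair_input",
    "DEFAULT_MIN_SHARED",
]

#: Minimum number of species a protein pair must share to be analysed.
DEFAULT_MIN_SHARED = 20


@dataclass
class PairRejection:
    pair_id: str
    n_shared: int
    reason: str


@dataclass
class PairInput:
    """Trimmed inputs for one unordered protein pair.

    ``msa_a``/``msa_b`` contain exactly the shared species (rows sorted by
    species label) with all-gap columns removed; ``index_map_a``/``_b`` map
    each retained column to its original 0-based column.  ``quality_a``/``_b``
    are per-column quality records of the *original* alignments.
    """

    pair_id: str
    protein_a: str
    protein_b: str
    msa_a: Msa
    msa_b: Msa
    index_map_a: np.ndarray
    index_map_b: np.ndarray
    shared_species: list[str]
    tree_a: Optional[PhyloTree] = None
    tree_b: Optional[PhyloTree] = None
    quality_a: Optional[ColumnQuality] = None
    quality_b: Optional[ColumnQuality] = None

    def __post_init__(self) -> None:
        if self.protein_a >= self.protein_b:
            raise ValueError("pair components must be in lexicographic order")
        if self.msa_a.species != self.msa_b.species:
            raise ValueError("pair alignments must cover identical species")
        for imap, msa in ((self.index_map_a, self.msa_a), (self.index_map_b, self.msa_b)):
            imap = np.asarray(imap)
            if imap.size != msa.length or (imap.size > 1 and np.any(np.diff(imap) <= 0)):
                raise ValueError("index map must be strictly increasing, one per column")

    def swapped(self) -> "PairInput":
        """The same pair with the A/B roles exchanged (for the reverse run).

        The ``pair_id`` ordering invariant is intentionally relaxed here;
        the object is only used internally by the bidirectional protocol.
        """
        other = object.__new__(PairInput)
        other.pair_id = self.pair_id
        other.protein_a = self.protein_b
        other.protein_b = self.protein_a
        other.msa_a = self.msa_b
        other.msa_b = self.msa_a
        other.index_map_a = self.index_map_b
        other.index_map_b = self.index_map_a
        other.shared_species = self.shared_species
        other.tree_a = self.tree_b
        other.tree_b = self.tree_a
        other.quality_a = self.quality_b
        other.quality_b = self.quality_a
        return other


def pair_id_of(protein_a: str, protein_b: str) -> str:
    a, b = sorted((protein_a, protein_b))
    return f"{a}__{b}"


def enumerate_pairs(proteins: list[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered pairs, components and list both sorted."""
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    if len(set(proteins)) != len(proteins):
        dupes = sorted({p for p in proteins if proteins.count(p) > 1})
        raise ValueError(f"duplicate protein ids {dupes}")
    ordered = sorted(proteins)
    return [
        (ordered[i], ordered[j])
        for i in range(len(ordered))
        for j in range(i + 1, len(ordered))
    ]


def _trim_msa(msa: Msa, shared: list[str]) -> tuple[Msa, np.ndarray]:
    sub = msa.subset(shared, sort=True)
    codes = sub.to_codes()
    all_gap = np.flatnonzero((codes == GAP_CODE).all(axis=0))
    keep = np.setdiff1d(np.arange(sub.length), all_gap)
    if all_gap.size:
        sub = sub.drop_columns(all_gap.tolist())
    return sub, keep


def build_pair_input(
    msa_a: Msa,
    msa_b: Msa,
    tree_a: Optional[PhyloTree] = None,
    tree_b: Optional[PhyloTree] = None,
    min_shared: int = DEFAULT_MIN_SHARED,
    quality_a: Optional[ColumnQuality] = None,
    quality_b: Optional[ColumnQuality] = None,
) -> PairInput | PairRejection:
    """Trim a protein pair to its shared species, or reject it.

    Symmetric in A/B up to slot naming: the output pair is always stored
    with the lexicographically smaller protein id in the A slot.
    """
    if msa_a.protein_id == msa_b.protein_id:
        raise ValueError("a protein cannot be paired with itself")
    if msa_a.protein_id > msa_b.protein_id:
        msa_a, msa_b = msa_b, msa_a
        tree_a, tree_b = tree_b, tree_a
        quality_a, quality_b = quality_b, quality_a
    pid = pair_id_of(msa_a.protein_id, msa_b.protein_id)
    shared = sorted(set(msa_a.species) & set(msa_b.species))
    if len(shared) < min_shared:
        return PairRejection(pid, len(shared), f"shared<{min_shared}")
    trimmed_a, map_a = _trim_msa(msa_a, shared)
    trimmed_b, map_b = _trim_msa(msa_b, shared)
    return PairInput(
        pair_id=pid,
        protein_a=msa_a.protein_id,
        protein_b=msa_b.protein_id,
        msa_a=trimmed_a,
        msa_b=trimmed_b,
        index_map_a=map_a,
        index_map_b=map_b,
        shared_species=shared,
        tree_a=tree_a.prune(shared) if tree_a is not None else None,
        tree_b=tree_b.prune(shared) if tree_b is not None else None,
        quality_a=quality_a,
        quality_b=quality_b,
    )
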