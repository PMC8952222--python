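"""Orthologue curation: one sequence per species, screened for quality.

Species often contribute several candidate homologues (splice isoforms,
duplicates).  Each candidate is globally aligned to the reference sequence
(Needleman–Wunsch with affine gaps — exact, affordable at these set sizes);
per species the highest-scoring candidate is kept, and even the best hit is
dropped when its identity is too low or its gap fraction too high, so that
incomplete or spurious sequences cannot distort the downstream alignment
statistics.  A final screen removes sequences too divergent from the rest
of the set (mean pairwise identity, rescaled within the set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from coevscreen.core_io import AMINO_ACIDS

__all__ = [
    "HomologSet",
    "AlignmentStats",
    "AlphabetError",
    "global_align",
    "select_best_hit",
    "divergence_screen",
    "DEFAULT_MIN_IDENTITY",
    "DEFAULT_MAX_GAPS",
    "DEFAULT_DIVERGENCE_CUTOFF",
]

#: Minimum percent identity to the reference a best hit must reach.
DEFAULT_MIN_IDENTITY = 35.0
#: Maximum percent of gapped alignment columns a best hit may have.
DEFAULT_MAX_GAPS = 25.0
#: Rescaled mean-pairwise-identity cut-off of the divergence screen.
DEFAULT_DIVERGENCE_CUTOFF = 0.95

_ALIGN_ALPHABET = set(AMINO_ACIDS + "X")


class AlphabetError(ValueError):
    """A sequence contains characters outside the amino-acid alphabet."""


@dataclass
class HomologSet:
    """Candidate homologues of one protein, possibly several per species."""

    protein_id: str
    reference_sequence: str
    candidates: list[tuple[str, str, str]]  # (species, candidate_id, sequence)

    def __post_init__(self) -> None:
        if not self.reference_sequence:
            raise ValueError(f"{self.protein_id}: empty reference sequence")
        seen = set()
        for species, cand_id, seq in self.candidates:
            if not seq:
                raise ValueError(
                    f"{self.protein_id}: empty candidate {species}|{cand_id}"
                )
            if (species, cand_id) in seen:
                raise ValueError(
                    f"{self.protein_id}: duplicate candidate {species}|{cand_id}"
                )
            seen.add((species, cand_id))


@dataclass
class AlignmentStats:
    """Summary of one global pairwise alignment."""

    score: float
    identity_pct: float  # identical / aligned (both non-gap) positions * 100
    gap_pct: float  # gapped columns / alignment length * 100
    aligned_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0, 100]")
        if not 0.0 <= self.gap_pct <= 100.0:
            raise ValueError("gap_pct outside [0, 100]")


def _check_alphabet(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _ALIGN_ALPHABET
    if bad:
        raise AlphabetError(f"{label}: illegal characters {sorted(bad)}")
    return seq


def global_align(
    query: str,
    reference: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentStats:
    """Needleman–Wunsch global alignment with affine gap penalties.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Statistics
    are computed on the first optimal alignment of Biopython's deterministic
    traceback.  Identity is counted over aligned (both-residue) positions;
    the gap percentage over all alignment columns.
    """
    query = _check_alphabet(query, "query")
    reference = _check_alphabet(reference, "reference")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    alignment = aligner.align(query, reference)[0]
    a, b = str(alignment[0]), str(alignment[1])
    aligned = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    identical = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    gapped = sum(1 for x, y in zip(a, b) if x == "-" or y == "-")
    length = len(a)
    return AlignmentStats(
        score=float(alignment.score),
        identity_pct=100.0 * identical / aligned if aligned else 0.0,
        gap_pct=100.0 * gapped / length if length else 0.0,
        aligned_length=length,
    )


def select_best_hit(
    hs: HomologSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_gaps: float = DEFAULT_MAX_GAPS,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[dict[str, str], list[dict], list[str]]:
    """Pick one orthologue per species by alignment score to the reference.

    Returns ``(chosen, rejections, missing)``: the species→sequence table of
    retained orthologues, a log of rejected candidates (with reason and
    stats), and the species left without any accepted sequence.  Per
    species only the top-scoring candidate is eligible (ties broken by the
    lexicographically smallest candidate id); if it fails the identity or
    gap filter the species is reported missing.
    """
    by_species: dict[str, list[tuple[str, str, AlignmentStats]]] = {}
    for species, cand_id, seq in hs.candidates:
        stats = global_align(seq, hs.reference_sequence, matrix, gap_open, gap_extend)
        by_species.setdefault(species, []).append((cand_id, seq.upper(), stats))

    chosen: dict[str, str] = {}
    rejections: list[dict] = []
    missing: list[str] = []
    for species in sorted(by_species):
        entries = sorted(
            by_species[species], key=lambda e: (-e[2].score, e[0])
        )
        best_id, best_seq, best = entries[0]
        for cand_id, _, stats in entries[1:]:
            rejections.append(
                {
                    "protein": hs.protein_id,
                    "species": species,
                    "candidate": cand_id,
                    "reason": "not_best_hit",
                    "identity": round(stats.identity_pct, 3),
                    "gaps": round(stats.gap_pct, 3),
                }
            )
        reasons = []
        if best.identity_pct < min_identity:
            reasons.append(f"identity<{min_identity:g}")
        if best.gap_pct > max_gaps:
            reasons.append(f"gaps>{max_gaps:g}")
        if reasons:
            rejections.append(
                {
                    "protein": hs.protein_id,
                    "species": species,
                    "candidate": best_id,
                    "reason": ";".join(reasons),
                    "identity": round(best.identity_pct, 3),
                    "gaps": round(best.gap_pct, 3),
                }
            )
            missing.append(species)
        else:
            chosen[species] = best_seq
    return chosen, rejections, missing


def _pairwise_identity(a: str, b: str) -> float:
    """Approximate global-alignment identity from the edlib edit distance."""
    res = edlib.align(a, b, mode="NW", task="distance")
    dist = res["editDistance"]
    denom = max(len(a), len(b))
    return 1.0 - dist / denom if denom else 0.0


def divergence_screen(
    sequences: dict[str, str],
    cutoff: float = DEFAULT_DIVERGENCE_CUTOFF,
) -> tuple[dict[str, str], list[dict]]:
    """Remove sequences too divergent from the rest of the orthologue set.

    Each sequence scores the mean pairwise identity to all others
    (gap characters are ignored); scores are rescaled to [0, 1] by the set
    maximum, and sequences below ``cutoff x median(rescaled scores)`` are
    removed.  With fewer than 4 sequences the screen is skipped with a
    warning (too few to assess divergence).
    """
    if len(sequences) < 4:
        warnings.warn(
            "divergence screen skipped: fewer than 4 sequences", stacklevel=2
        )
        return dict(sequences), []
    species = sorted(sequences)
    plain = {sp: sequences[sp].replace("-", "") for sp in species}
    n = len(species)
    scores = {}
    ident = {}
    for i in range(n):
        for j in range(i + 1, n):
            ident[(i, j)] = _pairwise_identity(plain[species[i]], plain[species[j]])
    for i, sp in enumerate(species):
        vals = [ident[tuple(sorted((i, j)))] for j in range(n) if j != i]
        scores[sp] = sum(vals) / len(vals)
    top = max(scores.values())
    if top <= 0.0:
        return dict(sequences), []
    rescaled = {sp: s / top for sp, s in scores.items()}
    med = sorted(rescaled.values())[len(rescaled) // 2]
    limit = cutoff * med
    retained = {}
    removed = []
    for sp in species:
        if rescaled[sp] < limit:
            removed.append(
                {"species": sp, "score": round(rescaled[sp], 6), "cutoff": limit}
            )
        else:
            retained[sp] = sequences[sp]
    return retained, removed
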