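"""Alignment-column quality: gap fractions, conservation classes, and
reliable-block flags.

This is a deliberately reduced re-statement of the block-selection idea
behind Gblocks: columns are classed by how dominant their most frequent
residue is, columns that are mostly gaps are never trusted, and "good"
columns are those inside sufficiently long runs that are free of long
nonconserved stretches and anchored on conserved columns at both ends.
The downstream screen only consumes the per-column good/poor label and the
gap fraction; byte-level Gblocks equivalence is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from coevscreen.core_io import GAP_CODE, Msa

__all__ = [
    "ColumnQuality",
    "NONCONSERVED",
    "CONSERVED",
    "HIGHLY_CONSERVED",
    "column_stats",
    "good_blocks",
    "write_quality_tsv",
    "read_quality_tsv",
]

NONCONSERVED = 0
CONSERVED = 1
HIGHLY_CONSERVED = 2

CLASS_NAMES = {
    NONCONSERVED: "nonconserved",
    CONSERVED: "conserved",
    HIGHLY_CONSERVED: "highly_conserved",
}

#: A column whose gap fraction exceeds this is forced nonconserved
#: (the "allowed gaps: with half" setting of Gblocks, -b5=h).
MAX_GAP_FRACTION = 0.5

#: Fraction of rows the majority residue must exceed for "highly conserved".
HIGH_CONSERVATION = 0.85


@dataclass
class ColumnQuality:
    """Per-column quality record for one protein alignment."""

    protein_id: str
    gap_fraction: np.ndarray
    conservation_class: np.ndarray
    in_good_block: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gap_fraction = np.asarray(self.gap_fraction, dtype=float)
        self.conservation_class = np.asarray(self.conservation_class, dtype=np.int8)
        n = self.gap_fraction.size
        if self.conservation_class.size != n:
            raise ValueError("per-column arrays must have equal length")
        if self.in_good_block is None:
            self.in_good_block = np.zeros(n, dtype=bool)
        self.in_good_block = np.asarray(self.in_good_block, dtype=bool)
        if self.in_good_block.size != n:
            raise ValueError("per-column arrays must have equal length")

    @property
    def n_columns(self) -> int:
        return self.gap_fraction.size

    def class_names(self) -> list[str]:
        return [CLASS_NAMES[int(c)] for c in self.conservation_class]


def column_stats(msa: Msa) -> ColumnQuality:
    """Gap fraction and conservation class for every column.

    A column is ``highly_conserved`` when its most frequent residue occurs in
    more than 85% of rows, ``conserved`` when it occurs in more than half of
    the rows (strict majority), ``nonconserved`` otherwise.  Columns that are
    more than half gaps are nonconserved regardless of their residues.
    """
    codes = msa.to_codes()
    n, length = codes.shape
    gap_fraction = (codes == GAP_CODE).mean(axis=0)
    classes = np.full(length, NONCONSERVED, dtype=np.int8)
    for c in range(length):
        col = codes[:, c]
        col = col[col != GAP_CODE]
        if col.size == 0:
            continue
        top = int(np.bincount(col).max())
        if top > HIGH_CONSERVATION * n:
            classes[c] = HIGHLY_CONSERVED
        elif top > n // 2:
            classes[c] = CONSERVED
    classes[gap_fraction > MAX_GAP_FRACTION] = NONCONSERVED
    return ColumnQuality(msa.protein_id, gap_fraction, classes)


def good_blocks(
    cq: ColumnQuality,
    min_block: int = 10,
    max_nonconserved_stretch: int = 8,
) -> ColumnQuality:
    """Fill ``in_good_block``: runs free of long nonconserved stretches,
    trimmed to conserved ends, of length at least ``min_block``.

    The alignment is split at every stretch of more than
    ``max_nonconserved_stretch`` contiguous nonconserved columns (the
    stretch itself is excluded); each remaining segment is trimmed at both
    ends to start and end on a conserved-or-better column, and kept only if
    the trimmed length reaches ``min_block``.  Marking is idempotent.
    """
    classes = cq.conservation_class
    length = classes.size
    good = np.zeros(length, dtype=bool)

    # segment boundaries: long nonconserved stretches
    segments: list[tuple[int, int]] = []
    start = 0
    run_start = None
    for c in range(length + 1):
        is_nc = c < length and classes[c] == NONCONSERVED
        if is_nc:
            if run_start is None:
                run_start = c
        else:
            if run_start is not None and c - run_start > max_nonconserved_stretch:
                segments.append((start, run_start))
                start = c
            run_start = None
    segments.append((start, length))

    for seg_start, seg_end in segments:
        lo, hi = seg_start, seg_end - 1
        while lo <= hi and classes[lo] == NONCONSERVED:
            lo += 1
        while hi >= lo and classes[hi] == NONCONSERVED:
            hi -= 1
        if hi - lo + 1 >= min_block:
            good[lo : hi + 1] = True

    return ColumnQuality(cq.protein_id, cq.gap_fraction, classes, good)


def write_quality_tsv(cq: ColumnQuality, path: str | Path) -> Path:
    """Per-column TSV: column (1-based), gap fraction, class, good flag."""
    lines = ["column_1based\tgap_fraction\tclass\tgood"]
    names = cq.class_names()
    for c in range(cq.n_columns):
        lines.append(
            f"{c + 1}\t{cq.gap_fraction[c]:.6g}\t{names[c]}\t"
            f"{int(cq.in_good_block[c])}"
        )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def read_quality_tsv(path: str | Path, protein_id: str | None = None) -> ColumnQuality:
    lines = Path(path).read_text(encoding="utf-8").strip().split("\n")
    name_to_class = {v: k for k, v in CLASS_NAMES.items()}
    gaps, classes, good = [], [], []
    for line in lines[1:]:
        _, g, cls, gd = line.split("\t")
        gaps.append(float(g))
        classes.append(name_to_class[cls])
        good.append(bool(int(gd)))
    return ColumnQuality(
        protein_id or Path(path).stem,
        np.array(gaps),
        np.array(classes),
        np.array(good),
    )
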