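"""Amino-acid substitution scoring matrices and background frequencies.

BLOSUM matrices are loaded from Biopython and exposed as dense numpy lookup
tables indexed by the integer residue codes of :mod:`coevscreen.core_io`.
The BLOSUM62 background frequencies are used both as the equilibrium of the
sequence simulator and to derive its exchangeability rate matrix.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from coevscreen.core_io import ALPHABET, AMINO_ACIDS

#: Amino-acid background frequencies underlying BLOSUM62 (Henikoff counts),
#: indexed like :data:`coevscreen.core_io.AMINO_ACIDS`; normalised to sum 1.
BLOSUM62_FREQS = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


def background_frequencies() -> np.ndarray:
    freqs = np.array([BLOSUM62_FREQS[aa] for aa in AMINO_ACIDS])
    return freqs / freqs.sum()


@lru_cache(maxsize=None)
def score_table(name: str = "BLOSUM62") -> np.ndarray:
    """Dense score lookup over the full residue alphabet.

    Entries involving a gap are NaN (a gapped pair carries no transition
    score and is masked upstream); 'X' uses the matrix's own X scores.
    """
    mat = substitution_matrices.load(name)
    k = len(ALPHABET)
    table = np.full((k, k), np.nan)
    for i, a in enumerate(ALPHABET[:-1]):  # exclude the gap symbol
        for j, b in enumerate(ALPHABET[:-1]):
            table[i, j] = mat[a, b]
    return table


@lru_cache(maxsize=None)
def rate_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A 20x20 reversible substitution rate matrix derived from a BLOSUM
    matrix.

    BLOSUM log-odds scores are (scaled) ``log(q_ab / (p_a p_b))``; the
    implied target ratios ``2^(S/2)`` are used as symmetric
    exchangeabilities, combined with the background frequencies
    (``Q_ab = pi_b * 2^(S_ab/2)`` for ``a != b``) and normalised so the
    expected substitution rate at equilibrium is one per unit branch length.
    """
    mat = substitution_matrices.load(name)
    pi = background_frequencies()
    n = len(AMINO_ACIDS)
    s = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            s[i, j] = mat[a, b]
    ex = np.power(2.0, s / 2.0)
    q = ex * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(np.sum(pi * np.diag(q)))
    return q / scale
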