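"""Pairwise protein alignment used by classification and homology calling.

All alignments use BLOSUM62 with affine gap penalties: a gap of length k
costs ``open + k * extend`` with open = 11 and extend = 1 (the conventional
protein-search defaults).  Global alignments are Needleman-Wunsch with
end gaps penalized; local scores are Smith-Waterman.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import FormatError

GAP_OPEN = 11   # charged on the first residue of a gap, on top of extend
GAP_EXTEND = 1


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def global_align(a: str, b: str):
    """Highest-scoring global alignment (first optimum, deterministic)."""
    if not a or not b:
        raise FormatError("cannot align an empty sequence")
    return _aligner("global").align(a, b)[0]


def global_score(a: str, b: str) -> float:
    if not a or not b:
        raise FormatError("cannot align an empty sequence")
    return float(_aligner("global").score(a, b))


def local_score(a: str, b: str) -> float:
    """Smith-Waterman score; 0 when no positive-scoring local alignment."""
    if not a or not b:
        raise FormatError("cannot align an empty sequence")
    return float(_aligner("local").score(a, b))


def aligned_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns aligned residue-to-residue.

    Computed from one optimal global alignment; 0.0 when the optimum aligns
    no residue pairs at all.  The input pair is put in canonical order first
    so the result is exactly symmetric even when optima are tied.
    """
    if b < a:
        a, b = b, a
    alignment = global_align(a, b)
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        aligned_cols += a1 - a0
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if a[i] == b[j]:
                matches += 1
    if aligned_cols == 0:
        return 0.0
    return matches / aligned_cols
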