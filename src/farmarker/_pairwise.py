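"""Shared semi-global pairwise alignment (fragment against reference).

Two scoring schemes: unit scoring (+1 match, -1 mismatch, -2 gap) for
nucleotide fragment placement, and BLOSUM62 with affine gaps (-11/-1)
for protein homolog fitting, where unit scores are too coarse to keep
divergent sequences in register.  Both use free end gaps on the
reference only, so the fragment/query aligns end-to-end inside the
reference.
"""

from __future__ import annotations

from typing import NamedTuple

from Bio import Align
from Bio.Align import substitution_matrices


class SemiGlobalHit(NamedTuple):
    score: float
    #: fragment position (0-based) -> reference position (0-based), matched
    #: columns only; fragment positions inside reference-relative insertions
    #: are absent.
    mapping: dict[int, int]


def _free_reference_ends(a: Align.PairwiseAligner) -> None:
    # attribute name depends on the Biopython version
    try:
        a.end_insertion_score = 0
    except AttributeError:
        a.target_end_gap_score = 0


def _unit_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    _free_reference_ends(a)
    return a


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    _free_reference_ends(a)
    return a


def semi_global_align(
    fragment: str, reference: str, protein: bool = False
) -> SemiGlobalHit:
    """Best semi-global fit of *fragment* within *reference*."""
    aligner = _protein_aligner() if protein else _unit_aligner()
    aln = aligner.align(reference, fragment)[0]
    mapping: dict[int, int] = {}
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for off in range(t1 - t0):
            mapping[int(q0) + off] = int(t0) + off
    return SemiGlobalHit(float(aln.score), mapping)
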