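"""Distance-based phylogenetic placement of recovered fragments.

Amplicons and screened contigs are placed relative to a reference
alignment by p-distance and neighbor-joining: the fragment is fitted
semi-globally against each reference, mapped into alignment columns via
the best-scoring reference, and distances are computed only over the
columns the fragment covers.  The result reports the ranked nearest
references and the fragment's sister group in the NJ tree.

NJ is the classic Saitou–Nei agglomeration with a deterministic
lexicographic tie-break, so placement is exactly reproducible; on
additive matrices it recovers the generating topology and branch
lengths exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from ._pairwise import semi_global_align
from .seqio import DNA, PROTEIN, AMINO_ACIDS, SequenceRecord, ValidationError, reverse_complement

__all__ = [
    "InsufficientOverlapError",
    "PlacementResult",
    "p_distance",
    "distance_matrix",
    "nj_tree",
    "place_fragment",
]


class InsufficientOverlapError(ValueError):
    """Too few comparable aligned columns between two sequences."""


_UNAMBIGUOUS = {DNA: frozenset("ACGT"), PROTEIN: AMINO_ACIDS}


def _comparable(a: str, b: str, alphabet: str) -> tuple[int, int]:
    ok = _UNAMBIGUOUS[alphabet]
    comparable = mismatch = 0
    for x, y in zip(a, b):
        if x in ok and y in ok:
            comparable += 1
            if x != y:
                mismatch += 1
    return mismatch, comparable


def p_distance(
    a: SequenceRecord, b: SequenceRecord, min_overlap: int = 100
) -> float:
    """Proportion of differing positions among comparable columns.

    Columns with a gap or an ambiguity symbol in either sequence are
    excluded; fewer than *min_overlap* comparable columns is an error,
    never a NaN.
    """
    if len(a.seq) != len(b.seq):
        raise ValidationError(
            f"aligned lengths differ: {a.id!r} {len(a.seq)} vs {b.id!r} {len(b.seq)}"
        )
    mismatch, comparable = _comparable(a.seq, b.seq, a.alphabet)
    if comparable < min_overlap:
        raise InsufficientOverlapError(
            f"{a.id!r} vs {b.id!r}: only {comparable} comparable columns "
            f"(< {min_overlap})"
        )
    return mismatch / comparable


def distance_matrix(
    alignment: Sequence[SequenceRecord], min_overlap: int = 100
) -> DistanceMatrix:
    """Pairwise p-distance matrix of an alignment (vectorised)."""
    ids = [r.id for r in alignment]
    alphabet = alignment[0].alphabet
    ok = _UNAMBIGUOUS[alphabet]
    arrs = [np.frombuffer(r.seq.encode("ascii"), dtype=np.uint8) for r in alignment]
    okmask = np.zeros(128, dtype=bool)
    for sym in ok:
        okmask[ord(sym)] = True
    valid = [okmask[a] for a in arrs]
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable < min_overlap:
                raise InsufficientOverlapError(
                    f"{ids[i]!r} vs {ids[j]!r}: only {comparable} comparable "
                    f"columns (< {min_overlap})"
                )
            mism = int((arrs[i][both] != arrs[j][both]).sum())
            d[i, j] = d[j, i] = mism / comparable
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# Neighbor-joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor-joining with deterministic tie-breaking.

    Pair selection minimises the Q criterion; ties are broken by the
    lexicographically smallest (sorted) label pair.  Negative branch
    lengths are clamped to 0 and the total clamped deficit is stored on
    the returned root as ``clamp_deficit``.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValidationError("nj_tree needs at least 3 taxa")
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            d[(a, b)] = float(dm[i, j])
    newick: dict[str, str] = {lab: _quote(lab) for lab in labels}
    clamp_deficit = 0.0
    active = list(labels)
    counter = 0

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else d[(a, b)]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, x) for x in active) for a in active}
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                key = (q, tuple(sorted((a, b))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = dab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        la, lb, clamp_deficit = _clamp(la, lb, clamp_deficit)
        new = f"__internal{counter}"
        counter += 1
        for x in active:
            if x in (a, b):
                continue
            dux = (dist(a, x) + dist(b, x) - dab) / 2
            d[(new, x)] = d[(x, new)] = dux
        newick[new] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        active = [x for x in active if x not in (a, b)] + [new]

    a, b, c = active
    # three-point formulas
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
    la, lb, clamp_deficit = _clamp(la, lb, clamp_deficit)
    lc, _, clamp_deficit = _clamp(lc, 0.0, clamp_deficit)
    nwk = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"
    tree = TreeNode.read(io.StringIO(nwk), convert_underscores=False)
    tree.clamp_deficit = clamp_deficit
    return tree


def _clamp(x: float, y: float, deficit: float) -> tuple[float, float, float]:
    if x < 0:
        deficit += -x
        x = 0.0
    if y < 0:
        deficit += -y
        y = 0.0
    return x, y, deficit


def _quote(label: str) -> str:
    return label.replace(" ", "_")


# ---------------------------------------------------------------------------
# Placement


@dataclass(frozen=True)
class PlacementResult:
    fragment_id: str
    ranking: tuple[tuple[str, float], ...]  # (reference id, p-distance), ascending
    tree: TreeNode
    newick: str
    sister_group: tuple[str, ...]
    best_reference: str
    covered_columns: int

    @property
    def nearest(self) -> str:
        return self.ranking[0][0]


def place_fragment(
    fragment: SequenceRecord,
    reference_alignment: Sequence[SequenceRecord],
    min_overlap: int = 100,
) -> PlacementResult:
    """Place one fragment among the references of an aligned FASTA.

    The fragment (both strands for DNA) is fitted semi-globally
    (+1/−1 match/mismatch, −2 gap) against each reference's ungapped
    sequence; the top-scoring reference maps it into alignment columns.
    p-distances over the fragment-covered columns feed an NJ tree whose
    fragment sister group is reported along with the distance ranking.
    """
    if len(reference_alignment) < 3:
        raise ValidationError("need >= 3 reference sequences")
    frag_variants = [fragment.seq.replace("-", "")]
    if fragment.alphabet == DNA:
        frag_variants.append(reverse_complement(frag_variants[0]))

    best = None  # (score, ref index, mapping, fragment string)
    ungapped = [r.ungapped().seq for r in reference_alignment]
    for fseq in frag_variants:
        for idx, ref in enumerate(ungapped):
            hit = semi_global_align(fseq, ref)
            if best is None or hit.score > best[0]:
                best = (hit.score, idx, hit.mapping, fseq)
    _, ref_idx, mapping, fseq = best
    best_ref = reference_alignment[ref_idx]

    # reference ungapped position -> alignment column (0-based)
    pos_to_col = [i for i, s in enumerate(best_ref.seq) if s != "-"]
    ncol = len(best_ref.seq)
    row = ["-"] * ncol
    for qpos, rpos in mapping.items():
        row[pos_to_col[rpos]] = fseq[qpos]
    frag_row = SequenceRecord(
        id=fragment.id, seq="".join(row), alphabet=fragment.alphabet
    )

    covered = [i for i, s in enumerate(frag_row.seq) if s != "-"]
    if len(covered) < min_overlap:
        raise InsufficientOverlapError(
            f"fragment {fragment.id!r} covers only {len(covered)} reference "
            f"columns (< {min_overlap})"
        )
    # restrict everything to fragment-covered columns
    def restrict(rec: SequenceRecord) -> SequenceRecord:
        return SequenceRecord(
            id=rec.id,
            seq="".join(rec.seq[i] for i in covered),
            alphabet=rec.alphabet,
        )

    rows = [restrict(r) for r in reference_alignment] + [restrict(frag_row)]
    dm = distance_matrix(rows, min_overlap=min(min_overlap, len(covered)))
    tree = nj_tree(dm)

    frag_leaf = _quote(fragment.id)
    node = tree.find(frag_leaf)
    sisters: list[str] = []
    parent = node.parent
    while parent is not None and not sisters:
        for sib in parent.children:
            if sib is node:
                continue
            if sib.is_tip():
                sisters.append(sib.name)
            else:
                sisters.extend(t.name for t in sib.tips())
        node, parent = parent, parent.parent
    sisters = [s for s in sisters if s != frag_leaf]

    frag_i = len(rows) - 1
    ranking = sorted(
        (
            (rows[j].id, float(dm[frag_i, j]))
            for j in range(len(rows) - 1)
        ),
        key=lambda t: (t[1], t[0]),
    )
    return PlacementResult(
        fragment_id=fragment.id,
        ranking=tuple(ranking),
        tree=tree,
        newick=str(tree),
        sister_group=tuple(sisters),
        best_reference=best_ref.id,
        covered_columns=len(covered),
    )
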