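"""Motif screening and far-red / white-light classification.

The diagnostic logic of the marker: far-red ApcE2 proteins carry a
VIPEDV-like motif where white-light ApcE1 carries ENACS-like, and the
phytochrome-binding cysteine (reference residue 217) is present only in
the white-light paralog.  This module scans proteins and six-frame
translated DNA (contigs or ~100 bp reads) for the motifs, classifies
apcE-like records, and extracts the 46-residue query fragment used for
fragment-level searching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Sequence

from ._pairwise import semi_global_align
from .seqio import (
    DNA,
    PROTEIN,
    SequenceRecord,
    ValidationError,
    six_frame_translations,
)

__all__ = [
    "MotifModel",
    "ScreenHit",
    "ClassificationCall",
    "CysCheck",
    "FAR_RED",
    "WHITE_LIGHT",
    "AMBIGUOUS",
    "NO_CALL",
    "far_red_motif",
    "white_light_motif",
    "scan_protein",
    "screen_reads",
    "classify_apce",
    "extract_query_fragment",
]

FAR_RED = "FAR_RED"
WHITE_LIGHT = "WHITE_LIGHT"
AMBIGUOUS = "AMBIGUOUS"
NO_CALL = "NO_CALL"


@dataclass(frozen=True)
class MotifModel:
    """A short diagnostic protein motif with a minimum-match threshold.

    ``allowed`` optionally widens individual positions beyond the
    reference residue ("-like" variants); by default each position
    admits only the reference residue and a window scores by how many
    positions match, calling a hit at >= ``min_matches``.
    """

    name: str
    motif: str
    min_matches: int
    allowed: tuple[frozenset[str], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValidationError("motif length must be >= 4")
        if not ceil(len(self.motif) / 2) <= self.min_matches <= len(self.motif):
            raise ValidationError(
                f"min_matches must be in [ceil(len/2), len] for {self.motif!r}"
            )
        if not self.allowed:
            object.__setattr__(
                self, "allowed", tuple(frozenset(r) for r in self.motif)
            )
        elif len(self.allowed) != len(self.motif):
            raise ValidationError("allowed sets must cover every motif position")

    def __len__(self) -> int:
        return len(self.motif)


def far_red_motif(min_matches: int = 5) -> MotifModel:
    """Default far-red model: VIPEDV-like, >=5 of 6 identities."""
    return MotifModel("VIPEDV-like", "VIPEDV", min_matches)


def white_light_motif(min_matches: int = 4) -> MotifModel:
    """Default white-light model: ENACS-like, >=4 of 5 identities."""
    return MotifModel("ENACS-like", "ENACS", min_matches)


@dataclass(frozen=True)
class ScreenHit:
    record_id: str
    position: int            # 1-based protein position of motif start
    matched: str
    matches: int
    frame: int | None = None  # reading frame for DNA input

    @property
    def score(self) -> float:
        return self.matches / len(self.matched)


def scan_protein(
    protein: str,
    motif: MotifModel,
    record_id: str = "",
    frame: int | None = None,
) -> list[ScreenHit]:
    """Sliding-window motif scan; every window >= min_matches is a hit.

    ``X`` in the protein never counts as a match; hits are reported in
    left-to-right order.
    """
    k = len(motif)
    hits = []
    for start in range(len(protein) - k + 1):
        window = protein[start:start + k]
        matches = sum(
            1
            for res, allowed in zip(window, motif.allowed)
            if res != "X" and res in allowed
        )
        if matches >= motif.min_matches:
            hits.append(ScreenHit(record_id, start + 1, window, matches, frame))
    return hits


def screen_reads(
    reads: Iterable[SequenceRecord],
    motif: MotifModel,
) -> list[ScreenHit]:
    """Six-frame translated motif search over DNA reads or contigs.

    Each read is translated in all six frames; hits carry the frame and
    the 1-based position on that frame's translation.  A read shorter
    than ``3*len(motif)+2`` can still hit when one frame covers the
    motif; partial motifs at read ends never call.
    """
    out: list[ScreenHit] = []
    for read in reads:
        if read.alphabet != DNA:
            raise ValidationError(f"read {read.id!r} is not DNA")
        for frame, protein in six_frame_translations(read.seq):
            out.extend(scan_protein(protein, motif, read.id, frame))
    return out


@dataclass(frozen=True)
class CysCheck:
    """Locates the diagnostic cysteine column via a reference alignment.

    ``reference_alignment`` is an aligned protein collection containing
    ``reference_id``; ``residue`` is the 1-based ungapped residue index
    on that reference (217 by convention).  The homologous query
    position is located by anchoring on the motif locus — the cysteine
    sits a fixed offset downstream of the motif start, so when both the
    reference and the query carry a motif hit the offset maps the
    position exactly; without an anchor the query is fitted against the
    reference by BLOSUM62 semi-global alignment.
    """

    reference_alignment: Sequence[SequenceRecord]
    reference_id: str
    residue: int = 217

    def _reference_protein(self) -> str:
        ref = next(
            (r for r in self.reference_alignment if r.id == self.reference_id),
            None,
        )
        if ref is None:
            raise KeyError(
                f"reference id {self.reference_id!r} not in alignment"
            )
        ungapped = ref.ungapped().seq
        if not 1 <= self.residue <= len(ungapped):
            raise ValidationError(
                f"residue {self.residue} outside reference 1..{len(ungapped)}"
            )
        return ungapped

    def diagnostic_residue(
        self,
        protein: str,
        anchor: "ScreenHit | None" = None,
        motifs: "Sequence[MotifModel] | None" = None,
    ) -> str | None:
        """The query residue homologous to the diagnostic position.

        *anchor* is the query's motif hit (its best one); *motifs* are
        used to find the corresponding anchor on the reference.  Returns
        ``None`` when the query does not cover the position.
        """
        reference = self._reference_protein()
        if anchor is not None and motifs:
            ref_anchor = max(
                (
                    h
                    for motif in motifs
                    for h in scan_protein(reference, motif, "ref")
                ),
                key=lambda h: h.score,
                default=None,
            )
            if ref_anchor is not None:
                pos = anchor.position + (self.residue - ref_anchor.position)
                if 1 <= pos <= len(protein):
                    return protein[pos - 1]
                return None
        hit = semi_global_align(protein, reference, protein=True)
        target = self.residue - 1
        for qpos, rpos in hit.mapping.items():
            if rpos == target:
                return protein[qpos]
        return None


@dataclass(frozen=True)
class ClassificationCall:
    record_id: str
    label: str
    far_red_hits: tuple[ScreenHit, ...]
    white_light_hits: tuple[ScreenHit, ...]
    cysteine: str | None = None  # 'present' / 'absent' / None (not checkable)


def _choose_frame(record: SequenceRecord, motifs: Sequence[MotifModel]):
    """Scan all six frames; return the frame/protein with the best hit.

    The best hit is the one with the highest match fraction across both
    motifs; frames are tried in the fixed order +1..+3, -1..-3 so the
    choice is deterministic.  Returns ``(protein, frame)`` — the first
    frame when nothing hits anywhere.
    """
    best = None  # (score, protein, frame)
    first = None
    for frame, protein in six_frame_translations(record.seq):
        if first is None:
            first = (protein, frame)
        for motif in motifs:
            for hit in scan_protein(protein, motif, record.id, frame):
                if best is None or hit.score > best[0]:
                    best = (hit.score, protein, frame)
    if best is None:
        return first
    return best[1], best[2]


def classify_apce(
    record: SequenceRecord,
    fr_motif: MotifModel | None = None,
    wl_motif: MotifModel | None = None,
    cys_check: CysCheck | None = None,
) -> ClassificationCall:
    """Call a record FAR_RED, WHITE_LIGHT, AMBIGUOUS or NO_CALL.

    The two motifs compete at the record's motif locus: the call goes to
    the motif with the better best-hit score (fraction of matching
    positions); equally good hits for both motifs are AMBIGUOUS and no
    hit for either is NO_CALL.  When a reference alignment makes the
    diagnostic cysteine checkable, a FAR_RED call additionally requires
    the cysteine ABSENT and a WHITE_LIGHT call requires it PRESENT
    (conflicts are AMBIGUOUS); the cysteine also breaks score ties.
    DNA input is scanned in all six frames and the call is made on the
    frame carrying the best hit.
    """
    fr_motif = fr_motif or far_red_motif()
    wl_motif = wl_motif or white_light_motif()
    if record.alphabet == PROTEIN:
        protein, frame = record.seq, None
    else:
        protein, frame = _choose_frame(record, [fr_motif, wl_motif])
    fr_hits = scan_protein(protein, fr_motif, record.id, frame)
    wl_hits = scan_protein(protein, wl_motif, record.id, frame)

    cysteine = None
    if cys_check is not None:
        anchor = max(
            fr_hits + wl_hits, key=lambda h: h.score, default=None
        )
        res = cys_check.diagnostic_residue(
            protein, anchor=anchor, motifs=[fr_motif, wl_motif]
        )
        if res is not None:
            cysteine = "present" if res == "C" else "absent"

    fr_best = max((h.score for h in fr_hits), default=None)
    wl_best = max((h.score for h in wl_hits), default=None)
    if fr_best is None and wl_best is None:
        label = NO_CALL
    elif wl_best is None or (fr_best is not None and fr_best > wl_best):
        label = FAR_RED if cysteine != "present" else AMBIGUOUS
    elif fr_best is None or wl_best > fr_best:
        label = WHITE_LIGHT if cysteine != "absent" else AMBIGUOUS
    else:  # equally strong hits for both motifs: cysteine decides if known
        if cysteine == "absent":
            label = FAR_RED
        elif cysteine == "present":
            label = WHITE_LIGHT
        else:
            label = AMBIGUOUS
    return ClassificationCall(
        record.id, label, tuple(fr_hits), tuple(wl_hits), cysteine
    )


def extract_query_fragment(
    protein: str, hit: ScreenHit, total_len: int = 46
) -> str:
    """Fragment of *total_len* residues centred on a motif hit.

    The window is shifted inward at sequence ends so the motif stays
    fully inside; proteins shorter than *total_len* are returned whole.
    This is the fragment-level search query (46 aa by convention, short
    enough to match 100 bp unassembled reads).
    """
    n = len(protein)
    k = len(hit.matched)
    if hit.position < 1 or hit.position + k - 1 > n:
        raise ValidationError("hit does not lie within the protein")
    if total_len >= n:
        return protein
    mid = hit.position - 1 + k / 2          # 0-based motif midpoint
    start = int(round(mid - total_len / 2))
    start = max(0, min(start, n - total_len))
    # keep the motif fully inside after clamping
    start = min(start, hit.position - 1)
    start = max(start, hit.position - 1 + k - total_len)
    return protein[start:start + total_len]
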