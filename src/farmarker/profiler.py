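"""Per-column alignment profiles and discriminative conserved windows.

The marker-discovery step: given one merged alignment split into a
target class (far-red *apcE2*-like) and a background class (*apcE1*-like),
build per-column symbol-frequency profiles for each class and scan for
"far-red islands" — windows that are conserved within the target class
but whose consensus differs from the background.  This replaces the
visual inspection of class-split alignments with an explicit, seeded
predicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .seqio import SequenceRecord, ValidationError

__all__ = [
    "ColumnProfile",
    "IslandCandidate",
    "build_profile",
    "discriminative_islands",
    "map_column_to_reference",
    "ReferencePosition",
]


@dataclass(frozen=True)
class ColumnProfile:
    """Symbol statistics of one alignment column within one class.

    ``freqs`` maps non-gap symbols to frequencies summing to 1 over the
    non-gap residues of the column; ``gap_fraction`` is the fraction of
    gaps; ``consensus`` is the majority non-gap symbol (lexicographically
    smallest on ties, ``None`` for all-gap columns) and ``conservation``
    its frequency.
    """

    freqs: dict[str, float]
    gap_fraction: float
    consensus: str | None
    conservation: float


def build_profile(alignment: Sequence[SequenceRecord]) -> list[ColumnProfile]:
    """Profile every column of an alignment (>=2 equal-length records)."""
    if len(alignment) < 2:
        raise ValidationError("build_profile needs at least 2 sequences")
    length = len(alignment[0].seq)
    alphabet = alignment[0].alphabet
    for rec in alignment:
        if len(rec.seq) != length:
            raise ValidationError(
                f"ragged alignment: record {rec.id!r} has length "
                f"{len(rec.seq)}, expected {length}"
            )
        if rec.alphabet != alphabet:
            raise ValidationError(f"record {rec.id!r} has a different alphabet")
    n = len(alignment)
    profiles = []
    for col in range(length):
        counts: dict[str, int] = {}
        gaps = 0
        for rec in alignment:
            sym = rec.seq[col]
            if sym == "-":
                gaps += 1
            else:
                counts[sym] = counts.get(sym, 0) + 1
        nongap = n - gaps
        if nongap == 0:
            profiles.append(ColumnProfile({}, 1.0, None, 0.0))
            continue
        freqs = {s: c / nongap for s, c in counts.items()}
        # deterministic consensus: highest frequency, then lexicographic
        consensus = min(freqs, key=lambda s: (-freqs[s], s))
        profiles.append(
            ColumnProfile(freqs, gaps / n, consensus, freqs[consensus])
        )
    return profiles


@dataclass(frozen=True)
class IslandCandidate:
    """A candidate discriminative window on the merged-alignment columns.

    Coordinates are 1-based inclusive alignment columns.
    ``target_conservation`` is the minimum per-column target-class
    conservation over the window; ``discrimination`` is the mean, over
    window columns, of 1 minus the background frequency of the target
    consensus symbol.  ``ref_start``/``ref_end`` (optional) give the
    corresponding 1-based ungapped positions on a named reference.
    """

    start: int
    end: int
    target_conservation: float
    discrimination: float
    ref_start: int | None = None
    ref_end: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def discriminative_islands(
    target_profile: Sequence[ColumnProfile],
    background_profile: Sequence[ColumnProfile],
    window_len: int = 18,
    min_target_conservation: float = 0.8,
    min_discrim_cols: float = 0.5,
    max_gap_fraction: float = 0.2,
) -> list[IslandCandidate]:
    """Scan all windows for target-conserved, background-distinct islands.

    A window of *window_len* columns qualifies iff

    * every column has target-class conservation >= *min_target_conservation*,
    * every column has gap fraction <= *max_gap_fraction* in both classes,
    * the fraction of columns whose target consensus differs from the
      background consensus is >= *min_discrim_cols*.

    Qualifying windows are ranked by discrimination score, then by
    within-target conservation, ties broken by leftmost start.
    """
    if len(target_profile) != len(background_profile):
        raise ValidationError("profiles must share one column coordinate system")
    if window_len < 6:
        raise ValidationError("window_len must be >= 6")
    ncol = len(target_profile)
    if window_len > ncol:
        raise ValidationError(
            f"window_len {window_len} exceeds alignment length {ncol}"
        )
    out: list[IslandCandidate] = []
    for start in range(ncol - window_len + 1):
        cols = range(start, start + window_len)
        ok = True
        discrim_cols = 0
        discrim_sum = 0.0
        min_cons = 1.0
        for c in cols:
            t, b = target_profile[c], background_profile[c]
            if (
                t.consensus is None
                or t.conservation < min_target_conservation
                or t.gap_fraction > max_gap_fraction
                or b.gap_fraction > max_gap_fraction
            ):
                ok = False
                break
            if t.consensus != b.consensus:
                discrim_cols += 1
            discrim_sum += 1.0 - b.freqs.get(t.consensus, 0.0)
            min_cons = min(min_cons, t.conservation)
        if not ok or discrim_cols / window_len < min_discrim_cols:
            continue
        out.append(
            IslandCandidate(
                start=start + 1,
                end=start + window_len,
                target_conservation=min_cons,
                discrimination=discrim_sum / window_len,
            )
        )
    out.sort(key=lambda i: (-i.discrimination, -i.target_conservation, i.start))
    return out


class ReferencePosition(NamedTuple):
    """Ungapped 1-based residue index on a reference, with exactness flag.

    ``exact`` is False when the reference carries a gap at the queried
    column; the index then refers to the nearest preceding non-gap
    residue (0 if none exists).
    """

    residue: int
    exact: bool


def map_column_to_reference(
    alignment: Sequence[SequenceRecord], reference_id: str, column: int
) -> ReferencePosition:
    """Map a 1-based alignment column to a reference's ungapped coordinate."""
    ref = next((r for r in alignment if r.id == reference_id), None)
    if ref is None:
        raise KeyError(f"reference id {reference_id!r} not in alignment")
    if not 1 <= column <= len(ref.seq):
        raise ValidationError(
            f"column {column} out of bounds 1..{len(ref.seq)}"
        )
    residue = sum(1 for s in ref.seq[:column] if s != "-")
    return ReferencePosition(residue, exact=ref.seq[column - 1] != "-")


def annotate_reference_span(
    island: IslandCandidate,
    alignment: Sequence[SequenceRecord],
    reference_id: str,
) -> IslandCandidate:
    """Return the island with its span mapped onto a reference sequence."""
    start = map_column_to_reference(alignment, reference_id, island.start)
    end = map_column_to_reference(alignment, reference_id, island.end)
    return IslandCandidate(
        start=island.start,
        end=island.end,
        target_conservation=island.target_conservation,
        discrimination=island.discrimination,
        ref_start=start.residue,
        ref_end=end.residue,
    )
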