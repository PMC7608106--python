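"""In-silico PCR: degenerate primer binding sites and predicted amplicons.

A primer core matches a template position when, treating every symbol
as its IUPAC base set, the sets intersect at all but at most
``max_mismatch`` positions AND the 3'-terminal ``clamp_len`` positions
all match.  Only the core binds; 5' tags are ignored for matching.
Both strands are scanned, and a pair amplifies wherever a forward and a
reverse site converge (3' ends facing each other) with a product length
inside the requested bounds.

Matching is vectorised with 4-bit base masks so whole genomes scan in
milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .primers import DegeneratePrimer, PrimerPair
from .seqio import IUPAC_SETS, SequenceRecord, ValidationError, reverse_complement

__all__ = ["PrimerSite", "Amplicon", "find_primer_sites", "amplify"]

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_SYMBOL_MASK = np.zeros(128, dtype=np.uint8)
for _sym, _bases in IUPAC_SETS.items():
    _SYMBOL_MASK[ord(_sym)] = sum(_BASE_BIT[b] for b in _bases)


@dataclass(frozen=True)
class PrimerSite:
    """One core match: 1-based start on the + strand, strand of binding."""

    template_id: str
    strand: str          # '+' or '-'
    start: int           # 1-based start of the matched window on + strand
    mismatches: int
    three_prime_clamp_ok: bool = True


@dataclass(frozen=True)
class Amplicon:
    """Predicted product spanning the outermost bases of both core matches."""

    template_id: str
    start: int           # 1-based inclusive, + strand
    end: int
    sequence: str        # + strand

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _encode(seq: str) -> np.ndarray:
    arr = _SYMBOL_MASK[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        pos = int(np.argmax(arr == 0)) + 1
        raise ValidationError(
            f"illegal DNA symbol {seq[pos - 1]!r} at position {pos}"
        )
    return arr


def _scan(tmask: np.ndarray, cmask: np.ndarray, max_mismatch: int, clamp: slice):
    """Starts (0-based) and mismatch counts of windows matching the core."""
    n, k = len(tmask), len(cmask)
    if k > n:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(tmask, k)
    hit = (windows & cmask) != 0      # IUPAC-intersection test per position
    mism = k - hit.sum(axis=1)
    ok = (mism <= max_mismatch) & hit[:, clamp].all(axis=1)
    starts = np.nonzero(ok)[0]
    return starts, mism[starts]


def find_primer_sites(
    template: SequenceRecord,
    primer: DegeneratePrimer,
    max_mismatch: int = 2,
    clamp_len: int = 3,
) -> list[PrimerSite]:
    """All core binding sites on both strands, sorted by + strand coordinate.

    The 3' clamp (*clamp_len* terminal positions, default 3) must match
    exactly; up to *max_mismatch* failures of the IUPAC-intersection
    test are tolerated elsewhere.  A core longer than the template
    yields an empty list.
    """
    if max_mismatch < 0 or clamp_len < 0:
        raise ValidationError("max_mismatch and clamp_len must be >= 0")
    core = primer.core
    if len(core) > len(template.seq):
        return []
    tmask = _encode(template.seq)
    sites: list[PrimerSite] = []
    # + strand: core read 5'->3' along the template; 3' end is rightmost
    plus_clamp = slice(len(core) - clamp_len, len(core)) if clamp_len else slice(0, 0)
    starts, mism = _scan(tmask, _encode(core), max_mismatch, plus_clamp)
    sites += [
        PrimerSite(template.id, "+", int(s) + 1, int(m))
        for s, m in zip(starts, mism)
    ]
    # - strand: compare revcomp(core) on the + strand; 3' end is leftmost
    minus_clamp = slice(0, clamp_len)
    starts, mism = _scan(
        tmask, _encode(reverse_complement(core)), max_mismatch, minus_clamp
    )
    sites += [
        PrimerSite(template.id, "-", int(s) + 1, int(m))
        for s, m in zip(starts, mism)
    ]
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(
    template: SequenceRecord,
    pair: PrimerPair,
    size_bounds: tuple[int, int] = (100, 5000),
    max_mismatch: int = 2,
    clamp_len: int = 3,
) -> list[Amplicon]:
    """Predict all products of a primer pair on one template.

    Every convergent combination of a forward and a reverse site (one
    per strand, 3' ends facing inward) whose span lies within
    *size_bounds* is reported, sorted by length then start; no nesting
    filter is applied.
    """
    lo, hi = size_bounds
    if lo > hi:
        raise ValidationError(f"bad size bounds {size_bounds}")
    fw_sites = find_primer_sites(template, pair.forward, max_mismatch, clamp_len)
    rv_sites = find_primer_sites(template, pair.reverse, max_mismatch, clamp_len)
    out: list[Amplicon] = []
    for f in fw_sites:
        flen = len(pair.forward.core)
        for r in rv_sites:
            rlen = len(pair.reverse.core)
            if f.strand == r.strand:
                continue
            left, llen = (f, flen) if f.strand == "+" else (r, rlen)
            right, rl = (r, rlen) if f.strand == "+" else (f, flen)
            if right.strand != "-" or left.start > right.start:
                continue  # divergent (outward-facing) sites never amplify
            end = right.start + rl - 1
            length = end - left.start + 1
            if length < max(llen, rl) or not lo <= length <= hi:
                continue
            out.append(
                Amplicon(
                    template.id,
                    start=left.start,
                    end=end,
                    sequence=template.seq[left.start - 1:end],
                )
            )
    out.sort(key=lambda a: (a.length, a.start))
    return out


def amplify_many(
    templates: Sequence[SequenceRecord],
    pair: PrimerPair,
    size_bounds: tuple[int, int] = (100, 5000),
    max_mismatch: int = 2,
    clamp_len: int = 3,
) -> list[Amplicon]:
    """Convenience: :func:`amplify` over a template collection."""
    out: list[Amplicon] = []
    for t in templates:
        out += amplify(t, pair, size_bounds, max_mismatch, clamp_len)
    return out
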