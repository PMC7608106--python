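"""Tagged degenerate primer design against discriminative islands.

Turns a class-specific island (forward) and a both-class conserved
"universal" window (reverse) into a degenerate primer pair: an IUPAC
consensus core built from column frequencies, an optional concrete
5' tag (20 bp by convention, to improve product recovery), Wallace-rule
melting temperatures and a degeneracy budget with low/medium/high
presets.  Degeneracy is controlled by a per-column frequency floor:
rare bases below the floor are dropped from the consensus set, which is
how the "partially constrained degeneracy" primer sets arise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

from .profiler import ColumnProfile, IslandCandidate
from .seqio import (
    IUPAC_SETS,
    SET_TO_IUPAC,
    SequenceRecord,
    ValidationError,
    reverse_complement,
)

__all__ = [
    "DegeneratePrimer",
    "PrimerPair",
    "DesignError",
    "DEGENERACY_PRESETS",
    "consensus_degenerate",
    "tm_range",
    "attach_tag",
    "tag_background_check",
    "TagCheckResult",
    "TagMatch",
    "universal_windows",
    "design_pair",
    "design_marker_pair",
]

#: Degeneracy caps echoing the three primer sets of increasing degeneracy;
#: "medium" is the default (the set that amplified best).
DEGENERACY_PRESETS = {"low": 128, "medium": 512, "high": 4096}


class DesignError(ValueError):
    """No primer satisfying the requested constraints exists."""


@dataclass(frozen=True)
class DegeneratePrimer:
    """A degenerate oligo: variable 3' core plus optional concrete 5' tag.

    Degeneracy and Tm are computed on the core only; the tag is carried
    separately and contributes to neither.
    """

    core: str
    tag: str = ""
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(f"bad orientation {self.orientation!r}")
        for pos, sym in enumerate(self.core, start=1):
            if sym not in IUPAC_SETS:
                raise ValidationError(
                    f"primer core: illegal symbol {sym!r} at position {pos}"
                )
        for pos, sym in enumerate(self.tag, start=1):
            if sym not in "ACGT":
                raise ValidationError(
                    f"primer tag: ambiguous or illegal symbol {sym!r} "
                    f"at position {pos} (tags must be concrete DNA)"
                )

    @property
    def degeneracy(self) -> int:
        d = 1
        for sym in self.core:
            d *= len(IUPAC_SETS[sym])
        return d

    @property
    def full_sequence(self) -> str:
        """5'->3' oligo as synthesised: tag then core."""
        return self.tag + self.core

    @property
    def tm_min(self) -> float:
        return tm_range(self.core)[0]

    @property
    def tm_max(self) -> float:
        return tm_range(self.core)[1]


@dataclass(frozen=True)
class PrimerPair:
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    product_min_bp: int
    product_max_bp: int

    @property
    def delta_tm(self) -> float:
        """Absolute difference of the two cores' Tm-range midpoints (°C)."""
        fmid = sum(tm_range(self.forward.core)) / 2
        rmid = sum(tm_range(self.reverse.core)) / 2
        return abs(fmid - rmid)


# ---------------------------------------------------------------------------
# Core construction


def _column_base_freqs(profile: ColumnProfile) -> dict[str, float]:
    """Fold ambiguity symbols into concrete-base frequencies (split evenly)."""
    out = {b: 0.0 for b in "ACGT"}
    for sym, f in profile.freqs.items():
        bases = IUPAC_SETS.get(sym)
        if bases is None:
            raise ValidationError(f"non-DNA symbol {sym!r} in profile column")
        share = f / len(bases)
        for b in bases:
            out[b] += share
    return out


def consensus_degenerate(
    window: Sequence[ColumnProfile],
    freq_floor: float = 0.1,
    cap: int = DEGENERACY_PRESETS["medium"],
) -> str:
    """IUPAC consensus core of a profile window.

    At each column the symbol covers exactly the bases with frequency
    >= *freq_floor*; the majority base is always included, so the set is
    never empty.  Lowering the floor weakly increases degeneracy.
    Refuses (reporting the minimal sufficient cap) if the product of the
    per-column set sizes exceeds *cap*.
    """
    if not window:
        raise ValidationError("empty profile window")
    core = []
    d = 1
    for profile in window:
        if profile.consensus is None:
            raise ValidationError("all-gap column in primer window")
        base_freqs = _column_base_freqs(profile)
        majority = max(sorted(base_freqs), key=lambda b: base_freqs[b])
        chosen = {b for b, f in base_freqs.items() if f >= freq_floor}
        chosen.add(majority)
        core.append(SET_TO_IUPAC[frozenset(chosen)])
        d *= len(chosen)
    if d > cap:
        raise DesignError(
            f"core degeneracy {d} exceeds cap {cap}; a cap of at least {d} "
            f"is needed at freq_floor={freq_floor}"
        )
    return "".join(core)


# min/max number of G+C bases a single IUPAC symbol can contribute
_GC_RANGE = {
    sym: (
        min(1 if b in "GC" else 0 for b in bases),
        max(1 if b in "GC" else 0 for b in bases),
    )
    for sym, bases in IUPAC_SETS.items()
}


def tm_range(core: str) -> tuple[float, float]:
    """Wallace-rule melting-temperature range of a degenerate core.

    Tm = 2(A+T) + 4(G+C) for every concrete expansion; since the rule
    depends only on the GC count, the extremes follow from the minimal
    and maximal GC contribution of each ambiguity symbol.
    """
    if not 6 <= len(core) <= 36:
        raise ValidationError(
            f"core length {len(core)} outside the supported 6..36 range"
        )
    lo = hi = 2 * len(core)
    for sym in core:
        if sym not in _GC_RANGE:
            raise ValidationError(f"illegal core symbol {sym!r}")
        gmin, gmax = _GC_RANGE[sym]
        lo += 2 * gmin
        hi += 2 * gmax
    return float(lo), float(hi)


def attach_tag(primer: DegeneratePrimer, tag: str) -> DegeneratePrimer:
    """Attach a concrete 5' tag (length 0-30); core Tm/degeneracy unchanged."""
    if len(tag) > 30:
        raise ValidationError(f"tag length {len(tag)} exceeds 30")
    return replace(primer, tag=tag)  # symbol validation runs in __post_init__


# ---------------------------------------------------------------------------
# Tag homology screen


class TagMatch(NamedTuple):
    background_id: str
    start: int        # 1-based on the background (+) strand
    length: int
    tag_strand: str   # '+' tag as-is, '-' reverse complement


class TagCheckResult(NamedTuple):
    longest: int
    matches: list[TagMatch]


def tag_background_check(
    tag: str,
    background: Sequence[SequenceRecord],
    min_report_len: int = 8,
) -> TagCheckResult:
    """Longest exact substring shared between a tag and background DNA.

    Scans the tag and its reverse complement against every background
    sequence; matches of length >= *min_report_len* are reported with
    1-based coordinates.  A fast stand-in for the BLAST check that tags
    have low homology to cyanobacterial DNA.
    """
    if not background:
        raise ValidationError("background must be non-empty")
    if not tag:
        raise ValidationError("tag must be non-empty")
    queries = {"+": tag, "-": reverse_complement(tag)}
    longest = 0
    matches: list[TagMatch] = []
    for rec in background:
        best_len, best_loc = 0, None
        for strand, q in queries.items():
            for length in range(len(q), best_len, -1):
                found = False
                for s in range(len(q) - length + 1):
                    idx = rec.seq.find(q[s:s + length])
                    if idx >= 0:
                        best_len, best_loc = length, (idx + 1, strand)
                        found = True
                        break
                if found:
                    break
        longest = max(longest, best_len)
        if best_loc is not None and best_len >= min_report_len:
            matches.append(TagMatch(rec.id, best_loc[0], best_len, best_loc[1]))
    return TagCheckResult(longest, matches)


# ---------------------------------------------------------------------------
# Pair design


def universal_windows(
    target_profile: Sequence[ColumnProfile],
    background_profile: Sequence[ColumnProfile],
    window_len: int = 18,
    min_conservation: float = 0.9,
    max_gap_fraction: float = 0.2,
) -> list[tuple[int, int]]:
    """Column windows conserved in BOTH classes with a shared consensus.

    These are candidate reverse-primer sites: "universal" means the
    window looks the same in far-red and white-light sequences alike,
    so every column must reach *min_conservation* in each class and the
    two class consensuses must agree.  Windows are returned ranked by
    the minimum per-column conservation across both classes (most
    conserved first), ties by leftmost start; 1-based inclusive.
    """
    if len(target_profile) != len(background_profile):
        raise ValidationError("profiles must share one column coordinate system")
    ncol = len(target_profile)
    scored = []
    for start in range(ncol - window_len + 1):
        score = 1.0
        ok = True
        for c in range(start, start + window_len):
            t, b = target_profile[c], background_profile[c]
            if (
                t.consensus is None
                or t.consensus != b.consensus
                or t.conservation < min_conservation
                or b.conservation < min_conservation
                or t.gap_fraction > max_gap_fraction
                or b.gap_fraction > max_gap_fraction
            ):
                ok = False
                break
            score = min(score, t.conservation, b.conservation)
        if ok:
            scored.append((-score, start + 1, start + window_len))
    scored.sort()
    return [(s, e) for _, s, e in scored]


def _ungapped_pos(template: SequenceRecord, column: int) -> int:
    return sum(1 for s in template.seq[:column] if s != "-")


def design_pair(
    island: IslandCandidate,
    target_profile: Sequence[ColumnProfile],
    merged_profile: Sequence[ColumnProfile],
    universal_window: tuple[int, int],
    template: SequenceRecord,
    product_range: tuple[int, int] = (800, 1600),
    max_delta_tm: float = 6.0,
    cap: int = DEGENERACY_PRESETS["medium"],
    freq_floor: float = 0.1,
) -> PrimerPair:
    """Build a forward/reverse pair from an island and a universal window.

    The forward core is the consensus-degenerate of the target profile
    over the island columns; the reverse core is the reverse complement
    of the consensus-degenerate of the merged (both-class) profile over
    the universal window.  The predicted product size on *template*
    (island start to universal-window end, ungapped coordinates) must
    fall in *product_range* and the annealing midpoints must differ by
    at most *max_delta_tm*; otherwise a :class:`DesignError` states
    which constraint failed.
    """
    lo, hi = product_range
    if lo > hi:
        raise ValidationError(f"bad product range {product_range}")
    ustart, uend = universal_window
    fw_core = consensus_degenerate(
        target_profile[island.start - 1:island.end], freq_floor, cap
    )
    rev_sense = consensus_degenerate(
        merged_profile[ustart - 1:uend], freq_floor, cap
    )
    rv_core = reverse_complement(rev_sense)
    fstart = _ungapped_pos(template, island.start)
    rend = _ungapped_pos(template, uend)
    product = rend - fstart + 1
    if not lo <= product <= hi:
        raise DesignError(
            f"predicted product {product} bp on template {template.id!r} "
            f"outside range {lo}..{hi}"
        )
    fw = DegeneratePrimer(core=fw_core, orientation="forward")
    rv = DegeneratePrimer(core=rv_core, orientation="reverse")
    pair = PrimerPair(fw, rv, product_min_bp=product, product_max_bp=product)
    if pair.delta_tm > max_delta_tm:
        raise DesignError(
            f"annealing mismatch: ΔTm {pair.delta_tm:.1f} °C exceeds "
            f"{max_delta_tm} °C"
        )
    return pair


def select_primer_island(
    islands: Sequence[IslandCandidate],
) -> IslandCandidate:
    """Pick the island to put the forward core on.

    Discrimination ranks islands, but a primer core — especially its 3'
    clamp — wants the fewest within-target variants, so the island with
    the highest within-target conservation wins; ties keep the
    discrimination ranking order.
    """
    if not islands:
        raise DesignError("no discriminative island available")
    return max(
        enumerate(islands),
        key=lambda t: (t[1].target_conservation, -t[0]),
    )[1]


def design_marker_pair(
    islands: IslandCandidate | Sequence[IslandCandidate],
    target_profile: Sequence[ColumnProfile],
    background_profile: Sequence[ColumnProfile],
    merged_profile: Sequence[ColumnProfile],
    template: SequenceRecord,
    product_range: tuple[int, int] = (800, 1600),
    max_delta_tm: float = 6.0,
    cap: int = DEGENERACY_PRESETS["medium"],
    freq_floor: float = 0.1,
    window_len: int = 18,
    min_universal_conservation: float = 0.9,
) -> PrimerPair:
    """Pick a primer-grade island, search universal windows, design a pair.

    *islands* may be the ranked list from ``discriminative_islands`` (the
    most conserved island is used, see :func:`select_primer_island`)
    or a single pre-chosen island.  Universal-window candidates are tried
    most-conserved first; the first one giving a product inside
    *product_range* with matched annealing wins.  Raises
    :class:`DesignError` with diagnostics when no combination works.
    """
    if isinstance(islands, IslandCandidate):
        island = islands
    else:
        island = select_primer_island(list(islands))
    candidates = universal_windows(
        target_profile, background_profile, window_len,
        min_universal_conservation,
    )
    candidates = [w for w in candidates if w[0] > island.end]
    if not candidates:
        raise DesignError("no universal window downstream of the island")
    failures = []
    for window in candidates:
        try:
            return design_pair(
                island, target_profile, merged_profile, window, template,
                product_range, max_delta_tm, cap, freq_floor,
            )
        except DesignError as exc:
            failures.append(f"window {window}: {exc}")
    raise DesignError(
        "no universal window satisfies the product-size/ΔTm constraints; "
        + "; ".join(failures[:3])
    )
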