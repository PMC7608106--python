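"""Sequence I/O and nucleotide algebra.

FASTA/FASTQ reading and writing (via Biopython), alphabet validation,
IUPAC ambiguity-code algebra, reverse complement, six-frame translation
and degenerate-oligo expansion.  Every other module consumes the
:class:`SequenceRecord` container defined here.

Conventions
-----------
* DNA uses the full IUPAC nucleotide alphabet plus the gap character
  ``-``; ``U`` is normalised to ``T`` on input and never written out.
* Proteins use the 20 standard amino acids plus ``X`` (unknown), ``*``
  (stop) and ``-`` (gap).
* Coordinates are 1-based and inclusive throughout the package.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "DNA",
    "PROTEIN",
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "SET_TO_IUPAC",
    "SequenceRecord",
    "ValidationError",
    "FastaParseError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "reverse_complement",
    "translate",
    "six_frame_translations",
    "expand_degenerate",
    "degeneracy",
    "iupac_match",
]

# ---------------------------------------------------------------------------
# Alphabets and IUPAC tables

DNA = "DNA"
PROTEIN = "PROTEIN"

#: IUPAC nucleotide symbol -> set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),   # not A
    "D": frozenset("AGT"),   # not C
    "H": frozenset("ACT"),   # not G
    "V": frozenset("ACG"),   # not T
    "N": frozenset("ACGT"),
}

#: set of concrete bases -> IUPAC symbol (inverse of IUPAC_SETS).
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

DNA_SYMBOLS = frozenset(IUPAC_SETS) | {"-"}
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_SYMBOLS = AMINO_ACIDS | {"X", "*", "-"}

_ALPHABETS = {DNA: DNA_SYMBOLS, PROTEIN: PROTEIN_SYMBOLS}

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code


class ValidationError(ValueError):
    """A sequence, symbol or parameter violated its contract."""


class FastaParseError(ValueError):
    """The input file is not well-formed FASTA/FASTQ."""


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class SequenceRecord:
    """An identifier plus a DNA or protein string over a declared alphabet.

    Parameters
    ----------
    id : str
        Non-empty record identifier (first whitespace-delimited token of
        the FASTA header).
    seq : str
        Upper-case sequence over the declared alphabet.
    alphabet : {"DNA", "PROTEIN"}
    description : str
        Remainder of the header line, possibly empty.
    """

    id: str
    seq: str
    alphabet: str = DNA
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if self.alphabet not in _ALPHABETS:
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        allowed = _ALPHABETS[self.alphabet]
        for pos, sym in enumerate(self.seq, start=1):
            if sym not in allowed:
                raise ValidationError(
                    f"record {self.id!r}: illegal {self.alphabet} symbol "
                    f"{sym!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> "SequenceRecord":
        """Return a copy with all gap characters removed."""
        return replace(self, seq=self.seq.replace("-", ""))


def _normalise_dna(raw: str) -> str:
    return raw.upper().replace("U", "T")


def _make_record(id_: str, description: str, raw: str, alphabet: str) -> SequenceRecord:
    seq = _normalise_dna(raw) if alphabet == DNA else raw.upper()
    return SequenceRecord(id=id_, seq=seq, alphabet=alphabet, description=description)


def read_fasta(path: str | Path, alphabet: str = DNA) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into validated records, order preserved.

    ``U`` is normalised to ``T`` for DNA input.  Raises
    :class:`FastaParseError` on structural problems (no header, empty
    sequence) and :class:`ValidationError` on illegal symbols, naming the
    record and position.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(f"{path}: line 1 does not start with '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip()
        records.append(_make_record(rec.id, desc, str(rec.seq), alphabet))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    _check_unique_ids(records)
    return records


def read_fastq(path: str | Path, alphabet: str = DNA) -> list[SequenceRecord]:
    """Read FASTQ, discarding quality strings (no quality filtering)."""
    records = []
    for rec in SeqIO.parse(str(Path(path)), "fastq"):
        desc = rec.description[len(rec.id):].strip()
        records.append(_make_record(rec.id, desc, str(rec.seq), alphabet))
    if not records:
        raise FastaParseError(f"{path}: no FASTQ records found")
    _check_unique_ids(records)
    return records


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA; ids must be unique."""
    records = list(records)
    _check_unique_ids(records)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Nucleotide algebra


def _require_ungapped_dna(seq: str, what: str = "sequence") -> None:
    for pos, sym in enumerate(seq, start=1):
        if sym not in IUPAC_SETS:
            raise ValidationError(f"{what}: illegal DNA symbol {sym!r} at position {pos}")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement of an ungapped DNA string.

    The complement is closed over the ambiguity alphabet (e.g. the
    complement of ``H`` = {A,C,T} is ``D`` = {A,G,T}).
    """
    _require_ungapped_dna(seq, "reverse_complement")
    return "".join(IUPAC_COMPLEMENT[s] for s in reversed(seq))


def iupac_match(a: str, b: str) -> bool:
    """True when the base sets of two IUPAC symbols intersect."""
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def degeneracy(oligo: str) -> int:
    """Number of concrete oligos a degenerate oligo denotes."""
    _require_ungapped_dna(oligo, "degeneracy")
    d = 1
    for sym in oligo:
        d *= len(IUPAC_SETS[sym])
    return d


def expand_degenerate(oligo: str, cap: int = 4096) -> set[str]:
    """Enumerate the concrete oligos denoted by a degenerate oligo.

    Refuses (reporting the product) when the degeneracy exceeds *cap*.
    """
    _require_ungapped_dna(oligo, "expand_degenerate")
    d = degeneracy(oligo)
    if d > cap:
        raise ValidationError(f"degeneracy {d} exceeds cap {cap}")
    pools = [sorted(IUPAC_SETS[s]) for s in oligo]
    return {"".join(p) for p in itertools.product(*pools)}


@functools.lru_cache(maxsize=4096)
def _translate_codon(codon: str) -> str:
    """Translate one codon; unresolvable ambiguity yields 'X', stop '*'."""
    aas = set()
    for concrete in expand_degenerate(codon, cap=64):
        if concrete in _CODON_TABLE.stop_codons:
            aas.add("*")
        else:
            aas.add(_CODON_TABLE.forward_table[concrete])
    if len(aas) == 1:
        return aas.pop()
    return "X"


def translate(seq: str, frame: int = 1) -> str:
    """Translate DNA in one of six frames (+1..+3, -1..-3).

    Standard genetic code; the trailing partial codon is dropped.  A
    codon containing ambiguity symbols translates to the amino acid all
    its expansions share, else ``X``; stop codons are emitted as ``*``.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValidationError(f"frame must be in ±1..±3, got {frame}")
    _require_ungapped_dna(seq, "translate")
    s = reverse_complement(seq) if frame < 0 else seq
    offset = abs(frame) - 1
    s = s[offset:]
    return "".join(
        _translate_codon(s[i:i + 3]) for i in range(0, len(s) - len(s) % 3, 3)
    )


def six_frame_translations(seq: str) -> Iterator[tuple[int, str]]:
    """Yield ``(frame, protein)`` for all six reading frames."""
    for frame in (1, 2, 3, -1, -2, -3):
        yield frame, translate(seq, frame)
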