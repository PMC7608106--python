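"""Synthetic two-class apcE-like gene families and read sets.

Generates families with the structure the marker method assumes, so the
whole pipeline is testable without any database access:

* a random ancestral coding sequence (~2270 bp, sense codons only);
* a far-red target class carrying the VIPEDV motif encoded at reference
  residues 204-209 and a non-cysteine residue at position 217;
* a white-light background class carrying ENACS at the homologous
  columns and the diagnostic cysteine at residue 217;
* a "universal" block, identical and frozen in both classes, placed so
  the forward-island -> universal-block span is 1200 bp on the ungapped
  gene (the ~1.2 kb amplicon geometry);
* independent per-site substitutions everywhere else, two-level
  (root -> class ancestor -> individual) so the classes form clades.

All randomness flows through one seeded generator; the same seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np

from .seqio import DNA, PROTEIN, SequenceRecord, ValidationError, reverse_complement, translate

__all__ = ["FamilySpec", "Family", "generate_family", "generate_reads"]

# fixed codon encodings for planted residues (one codon per amino acid,
# so planted blocks are perfectly conserved at the DNA level)
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}

_STOPS = {"TAA", "TAG", "TGA"}

# fixed universal (both-class) block: sense codons, GC content matched to
# the planted island codons so annealing temperatures can be matched
_UNIVERSAL_SEED = "GGTAATCATACTGATTCA"
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
_BASES = np.array(list("ACGT"))


def _encode_protein(motif: str) -> str:
    return "".join(_CODON[r] for r in motif)


@dataclass(frozen=True)
class FamilySpec:
    """Study conditions for one synthetic family.

    Defaults mirror the marker gene's geometry: a ~2270 bp gene, the
    far-red motif at residues 204-209, the diagnostic cysteine at 217
    (background only), a 1200 bp island-to-universal span, and modest
    within-class divergence (5% per site) around a larger between-class
    split (10% per branch).
    """

    n_target: int = 20
    n_background: int = 20
    gene_length_bp: int = 2270
    substitution_rate: float = 0.05
    class_divergence: float = 0.10
    indel_prob: float = 0.0
    mutate_planted: bool = False
    fr_motif: str = "VIPEDV"
    wl_motif: str = "ENACS"
    motif_residue_start: int = 204
    cys_residue: int = 217
    amplicon_span_bp: int = 1200
    universal_len: int = 18
    seed: int = 0

    # --- derived geometry (0-based, half-open, on the root coordinates)
    @property
    def fr_block(self) -> tuple[int, int]:
        s = (self.motif_residue_start - 1) * 3
        return s, s + 3 * len(self.fr_motif)

    @property
    def wl_block(self) -> tuple[int, int]:
        s = (self.motif_residue_start - 1) * 3
        return s, s + 3 * len(self.wl_motif)

    @property
    def cys_block(self) -> tuple[int, int]:
        s = (self.cys_residue - 1) * 3
        return s, s + 3

    @property
    def universal_block(self) -> tuple[int, int]:
        end = self.fr_block[0] + self.amplicon_span_bp
        return end - self.universal_len, end

    def validate(self) -> None:
        if self.n_target < 1 or self.n_background < 1:
            raise ValidationError("both classes need at least one sequence")
        if not 0 <= self.substitution_rate <= 1:
            raise ValidationError("substitution_rate must be in [0,1]")
        needed = max(
            self.universal_block[1], self.cys_block[1], self.fr_block[1]
        )
        if self.gene_length_bp < needed:
            raise ValidationError(
                f"gene_length_bp {self.gene_length_bp} too short for the "
                f"planted geometry (needs >= {needed})"
            )


@dataclass(frozen=True)
class Family:
    """Output of :func:`generate_family`: alignment, classes and truth."""

    spec: FamilySpec
    alignment: tuple[SequenceRecord, ...]   # merged, one column system
    class_map: dict[str, str]               # id -> "target" | "background"
    #: 1-based inclusive alignment columns of the planted blocks
    island_columns: tuple[int, int]
    universal_columns: tuple[int, int]
    cys_columns: tuple[int, int]

    @property
    def records(self) -> list[SequenceRecord]:
        return [r.ungapped() for r in self.alignment]

    @property
    def reference_id(self) -> str:
        return self.alignment[0].id

    def class_alignment(self, label: str) -> list[SequenceRecord]:
        return [r for r in self.alignment if self.class_map[r.id] == label]

    def protein_alignment(self) -> list[SequenceRecord]:
        """Frame +1 codon-wise translation of the merged alignment."""
        out = []
        for rec in self.alignment:
            n = len(rec.seq) - len(rec.seq) % 3
            aas = []
            for i in range(0, n, 3):
                codon = rec.seq[i:i + 3]
                aas.append("-" if codon == "---" else
                           "X" if "-" in codon else translate(codon))
            out.append(SequenceRecord(rec.id, "".join(aas), PROTEIN))
        return out


def _mutate(seq: np.ndarray, rate: float, frozen: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution among the 3 alternative bases, frozen sites kept."""
    out = seq.copy()
    hit = (rng.random(len(seq)) < rate) & ~frozen
    idx = np.nonzero(hit)[0]
    for i in idx:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
    return out


def _plant(seq: np.ndarray, block: tuple[int, int], encoding: str) -> None:
    seq[block[0]:block[1]] = list(encoding)


def _repair_stops(seq: np.ndarray, parent: np.ndarray) -> np.ndarray:
    """Revert substitutions that created in-frame stop codons.

    The family encodes functional proteins, so purifying selection is
    assumed to remove nonsense mutations; the parent codon (never a
    stop) is restored.
    """
    for c in range(0, (len(seq) // 3) * 3, 3):
        if "".join(seq[c:c + 3]) in _STOPS:
            seq[c:c + 3] = parent[c:c + 3]
    return seq


def generate_family(spec: FamilySpec) -> Family:
    """Generate one deterministic two-class family from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.gene_length_bp
    ncodons = ceil(L / 3)
    root = np.array(
        list("".join(rng.choice(_SENSE_CODONS, size=ncodons))[:L])
    )
    universal = (_UNIVERSAL_SEED * ceil(spec.universal_len / len(_UNIVERSAL_SEED)))
    _plant(root, spec.universal_block, universal[:spec.universal_len])

    frozen_universal = np.zeros(L, dtype=bool)
    frozen_universal[slice(*spec.universal_block)] = True

    def class_frozen(blocks: Sequence[tuple[int, int]]) -> np.ndarray:
        if spec.mutate_planted:
            return np.zeros(L, dtype=bool)
        f = frozen_universal.copy()
        for b in blocks:
            f[slice(*b)] = True
        return f

    records: list[SequenceRecord] = []
    class_map: dict[str, str] = {}
    for label, n, blocks, plantings in (
        (
            "target",
            spec.n_target,
            (spec.fr_block, spec.cys_block),
            ((spec.fr_block, _encode_protein(spec.fr_motif)),
             (spec.cys_block, _CODON["S"])),      # cysteine absent
        ),
        (
            "background",
            spec.n_background,
            (spec.wl_block, spec.cys_block),
            ((spec.wl_block, _encode_protein(spec.wl_motif)),
             (spec.cys_block, _CODON["C"])),      # diagnostic cysteine
        ),
    ):
        ancestor = _repair_stops(
            _mutate(root, spec.class_divergence, frozen_universal, rng), root
        )
        for block, encoding in plantings:
            _plant(ancestor, block, encoding)
        frozen = class_frozen(blocks)
        for i in range(n):
            seq = _repair_stops(
                _mutate(ancestor, spec.substitution_rate, frozen, rng), ancestor
            )
            if not spec.mutate_planted:
                for block, encoding in plantings:
                    _plant(seq, block, encoding)
            aligned = _apply_deletions(seq, spec, frozen, rng)
            rec_id = f"{label}_{i + 1:02d}"
            records.append(SequenceRecord(rec_id, "".join(aligned), DNA))
            class_map[rec_id] = label

    return Family(
        spec=spec,
        alignment=tuple(records),
        class_map=class_map,
        island_columns=(spec.fr_block[0] + 1, spec.fr_block[1]),
        universal_columns=(spec.universal_block[0] + 1, spec.universal_block[1]),
        cys_columns=(spec.cys_block[0] + 1, spec.cys_block[1]),
    )


def _apply_deletions(seq: np.ndarray, spec: FamilySpec, frozen: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Optional codon-sized deletions, re-gapped on the root coordinates."""
    if spec.indel_prob <= 0:
        return seq
    out = seq.copy()
    for c in range(0, (len(seq) // 3) * 3, 3):
        if frozen[c:c + 3].any():
            continue
        if rng.random() < spec.indel_prob:
            out[c:c + 3] = "-"
    return out


def generate_reads(
    family: Family,
    read_length_bp: int = 100,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Uniform shotgun reads from both strands of the ungapped genes.

    Read ids record provenance as ``src|rN|start|strand`` (1-based start
    on the source + strand).  Substitution errors are applied per base
    at *error_rate*; no indel errors.
    """
    if not 0 <= error_rate <= 1:
        raise ValidationError("error_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    for rec in family.records:
        gene = rec.seq
        if read_length_bp > len(gene):
            raise ValidationError(
                f"read length {read_length_bp} exceeds gene {rec.id!r} "
                f"({len(gene)} bp)"
            )
        n_reads = ceil(coverage * len(gene) / read_length_bp)
        starts = rng.integers(0, len(gene) - read_length_bp + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for i, (start, minus) in enumerate(zip(starts, strands)):
            chunk = gene[start:start + read_length_bp]
            if minus:
                chunk = reverse_complement(chunk)
            if error_rate > 0:
                arr = np.array(list(chunk))
                hit = np.nonzero(rng.random(len(arr)) < error_rate)[0]
                for j in hit:
                    arr[j] = [b for b in "ACGT" if b != arr[j]][rng.integers(3)]
                chunk = "".join(arr)
            strand = "-" if minus else "+"
            reads.append(
                SequenceRecord(
                    f"{rec.id}|r{i + 1}|{int(start) + 1}|{strand}", chunk, DNA
                )
            )
    return reads
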