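# Methods

This note documents the models, rules and numerical choices behind
`farmarker`, and what the synthetic families do and do not show about
real data.

## The marker and its geometry

The toolkit is organised around one biological observation: the far-red
paralog of the phycobilisome linker (*apcE2*) differs from the
white-light paralog (*apcE1*) at a short, conserved locus. Far-red
proteins carry a VIPEDV-like motif at residues 204–209 (in
*C. thermalis* numbering) and lack the phycochrome-binding cysteine at
residue 217; white-light proteins carry ENACS-like residues at the
homologous columns and retain the cysteine. Genes are ~2270 bp, and a
region conserved across *all* apcE paralogs lies ~1.2 kb downstream of
the motif, so a class-specific forward primer on the motif plus a
universal reverse primer yields a ~1.2 kb diagnostic product from
far-red templates only.

## Island discovery

Both classes must come from one merged alignment so columns correspond;
the toolkit never aligns (alignment is an input). Conservation of a
column is the frequency of its majority non-gap symbol
(lexicographically smallest on ties, so profiling is deterministic);
entropy-based scores are deliberately not offered — one thresholdable
metric keeps configuration and ranking unambiguous. A window of length
*w* qualifies as an island when every column reaches the target-class
conservation floor (default 0.8) and the gap ceiling (default 0.2 in
both classes), and at least half the columns (default) have a target
consensus differing from the background consensus. Ranking uses the
discrimination score — the mean over columns of 1 minus the background
frequency of the target consensus — then within-target conservation,
then leftmost start. Defaults: window 18 for DNA (the ~20 bp scale of a
primer core), 6 for proteins (the motif length).

## Primer design

The degenerate core takes, per column, the IUPAC symbol covering
exactly the bases with frequency ≥ `freq_floor` (default 0.1), always
including the majority base; lowering the floor weakly increases
degeneracy. Degeneracy caps come in three presets (low 128, medium 512,
high 4096), medium being the default. Melting temperatures use the
Wallace rule, Tm = 2(A+T) + 4(G+C), evaluated on the core only; because
the rule depends only on the GC count, the (min, max) over all
expansions follows from each symbol's minimal/maximal GC contribution
without enumeration. Nearest-neighbor thermodynamics, hairpin and dimer
checks are out of scope.

Two rules in the pair-level search deserve explanation because the
design space is genuinely open:

* **Universal windows require a shared consensus.** "Universal" means
  the reverse primer must see the same sequence in both classes, so a
  candidate window needs every column conserved (default ≥ 0.9) in each
  class *and* identical class consensuses. Candidates are tried
  most-conserved first; without that ordering the search can latch onto
  windows that clear the threshold by chance and produce products of
  arbitrary size.
* **The forward core goes on the most conserved island.** Discrimination
  ranks islands for reporting, but a primer — especially its 3′ clamp —
  fails on any within-target variant at its terminal bases, so among
  the ranked islands the one with the highest within-target conservation
  carries the core (ties keep the discrimination order).

Tags are concrete (no ambiguity codes), at most 30 bp (20 bp by
convention), stored separately from the core and invisible to
degeneracy, Tm and site matching. The tag-homology check is an exact
longest-common-substring scan of the tag and its reverse complement
against background sequences — deterministic and sufficient to flag
mispriming seeds; it is not a local aligner.

## In-silico PCR

A primer core matches a template position when the IUPAC base sets
intersect at all but at most `max_mismatch` positions (default 2) and
the 3′-terminal `clamp_len` positions (default 3) all pass the
intersection test. Template ambiguity symbols are treated permissively
(intersection, consistent with degenerate-primer semantics). Both
strands are scanned; matching is vectorised with 4-bit base masks.
Amplicons are all convergent forward/reverse site combinations whose
outermost-base span falls inside the size bounds, reported without a
nesting filter and sorted by length. Coordinates are 1-based inclusive
throughout the package.

## Screening and classification

Motif models hold a reference motif, per-position allowed residue sets
(default: the reference residue alone) and a minimum match count.
"VIPEDV-like" is quantified as ≥ 5/6 identities and "ENACS-like" as
≥ 4/5; `X` never counts as a match. Reads and contigs are translated in
all six frames (standard genetic code; ambiguous codons translate to
the shared amino acid of their expansions, else `X`; stops as `*`) and
every frame is scanned.

Classification makes the two motifs *compete at the locus*: the call
goes to the motif with the better best-hit score on the frame carrying
the best hit, with equal best scores AMBIGUOUS and no hit NO_CALL. An
any-hit OR rule was rejected: in a ~750-residue six-frame translation a
spurious ≥ 4/5 ENACS window arises in a few percent of sequences, which
would contaminate calls that are unambiguous at the locus. When a
reference alignment makes the diagnostic cysteine checkable, FAR_RED
additionally requires it absent and WHITE_LIGHT present (conflicts are
AMBIGUOUS), and the cysteine breaks score ties. The cysteine position
in the query is located by anchoring on the motif hit — the diagnostic
residue sits a fixed offset downstream of the motif start, read off the
reference — with a BLOSUM62 semi-global alignment fallback when no hit
anchors the frame. Pure pairwise alignment was not robust enough here:
next to a deliberately non-homologous motif block, unit-score and even
BLOSUM62 alignments occasionally slip one residue on ~30%-divergent
homologs.

The fragment-level search query is 46 residues (a size that still
matches 100 bp unassembled reads), centred on the motif midpoint and
shifted inward at protein ends so the motif stays fully inside.

## Placement

Distances are p-distances: mismatches over columns where both sequences
are non-gap and unambiguous (ambiguity excluded conservatively); fewer
than `min_overlap` comparable columns (default 100) is an error, never
a NaN. Trees are classic Saitou–Nei neighbor joining with the Q
criterion, ties broken by the lexicographically smallest label pair,
and negative branch lengths clamped to zero with the deficit recorded —
fully deterministic, and exact on additive matrices. NJ replaces
maximum likelihood deliberately: placement needs relative affinity at
desk scale and a reproducible sister-group answer, not support values.

Fragments are mapped into reference columns via the best semi-global
fit (+1/−1 match/mismatch, −2 gap; both strands for DNA) against each
reference's ungapped sequence, using the top-scoring reference's gap
pattern. All distances are then computed over the fragment-covered
columns only. Rooting, when wanted, is the user's outgroup choice, not
an algorithm.

## Synthetic families

The generator emulates the structure the method assumes: one random
ancestral coding sequence (sense codons only), two class ancestors
derived at a between-class divergence of 0.10 substitutions/site each,
and individuals at 0.05/site (defaults), with uniform substitution
among the three alternative bases. Planted features are never mutated:
the VIPEDV-encoding island (fixed codons, nucleotides 610–627), the
ENACS-encoding block in the background, the class-specific residue-217
codon (TGC in background, AGC in target), and an 18 bp universal block
whose GC content equals the island's so annealing temperatures are
matchable by construction — emulating the real situation where the gene
offers Tm-matched primer sites. Substitutions that would create
in-frame stop codons are reverted to the parent codon (purifying
selection); without this, internal stops distort translated-protein
comparisons in ways no functional gene family shows. Indels default
off; when enabled they are codon-sized deletions re-gapped on the root
coordinate system, keeping one shared column system without a
realigner. Reads are sampled uniformly from both strands with optional
per-base substitution errors; all randomness flows through one seeded
generator and the same seed reproduces output byte for byte.

What passing on these families shows: the discovery→design→PCR→
screen→place chain is internally consistent and recovers planted truth
under realistic divergence. What it does not show: performance on real
alignments with rate heterogeneity, recombination, codon bias,
sequencing artefacts or taxon sampling biases — and the placement claim
is clade-level on synthetic truth, not a reproduction of published
phylogenies.

## Problem sizes and tolerances

Default verification runs use families of 20+20 genes of 2270 bp,
20-seed sweeps for the end-to-end property, 100-instance sweeps for
oracle-equivalence properties, and 100 random 5–8-taxon additive
matrices for NJ (branch lengths to 1e−9). Amplicon size is asserted
within ±5% of 1200 bp (island ties can shift the designed window by a
few columns). The acceptance script reports rates over 10 fresh
families per run.
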