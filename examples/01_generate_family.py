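"""Generate a synthetic two-class apcE-like gene family.

Builds the default study conditions: 20 far-red (target) and 20
white-light (background) ~2270 bp genes from one ancestor, with the
VIPEDV motif encoded at residues 204-209 in targets only, ENACS at the
homologous columns in backgrounds, the diagnostic cysteine (residue
217) in backgrounds only, and a shared "universal" block 1.2 kb
downstream of the island.
"""

from farmarker import FamilySpec, generate_family, translate

family = generate_family(FamilySpec(seed=1))

print(f"sequences        : {len(family.alignment)}")
print(f"gene length      : {family.spec.gene_length_bp} bp")
print(f"island columns   : {family.island_columns} (nucleotide, 1-based)")
print(f"universal columns: {family.universal_columns}")
print(f"cysteine codon   : {family.cys_columns}")

target = family.class_alignment("target")[0]
background = family.class_alignment("background")[0]
lo, hi = family.island_columns
print(f"target island    : {target.seq[lo-1:hi]} -> {translate(target.seq[lo-1:hi])}")
print(f"background locus : {background.seq[lo-1:hi]} -> {translate(background.seq[lo-1:hi])}")
# The translated island reads VIPEDV in the target class and ENACS(+1
# variable residue) in the background class - the discriminative signal
# every later step relies on.
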