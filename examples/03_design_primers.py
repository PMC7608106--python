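"""Design a tagged degenerate primer pair against the marker.

The forward core is a degenerate IUPAC consensus of the most conserved
discriminative island; the reverse core targets a window conserved in
BOTH classes ("universal"), placed so the product is ~1.2 kb.  A
concrete 20 bp 5' tag is attached to improve product recovery, and its
homology to the background is checked.
"""

from farmarker import (
    FamilySpec,
    attach_tag,
    build_profile,
    design_marker_pair,
    discriminative_islands,
    generate_family,
    tag_background_check,
)

family = generate_family(FamilySpec(seed=1))
target = family.class_alignment("target")
tp = build_profile(target)
bp = build_profile(family.class_alignment("background"))
mp = build_profile(list(family.alignment))

pair = design_marker_pair(
    discriminative_islands(tp, bp), tp, bp, mp, template=target[0]
)
fw = attach_tag(pair.forward, "CCTCTCTATGGGCAGTCGGT")

print(f"forward: 5'-{fw.full_sequence}-3'")
print(f"  core degeneracy {fw.degeneracy}, Tm {fw.tm_min:.0f}-{fw.tm_max:.0f} C")
print(f"reverse: 5'-{pair.reverse.full_sequence}-3'")
print(f"  core degeneracy {pair.reverse.degeneracy}")
print(f"predicted product: {pair.product_min_bp} bp, dTm {pair.delta_tm:.1f} C")

check = tag_background_check(fw.tag, [r.ungapped() for r in family.alignment])
print(f"longest tag/background exact match: {check.longest} bp "
      f"(tag is {len(fw.tag)} bp; short matches cannot misprime)")
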