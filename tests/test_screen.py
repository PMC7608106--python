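import random

import pytest

from farmarker import (
    AMBIGUOUS,
    DNA,
    FAR_RED,
    NO_CALL,
    PROTEIN,
    WHITE_LIGHT,
    CysCheck,
    FamilySpec,
    MotifModel,
    SequenceRecord,
    ValidationError,
    classify_apce,
    extract_query_fragment,
    far_red_motif,
    generate_family,
    reverse_complement,
    scan_protein,
    screen_reads,
    translate,
    white_light_motif,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_protein(rng, n):
    return "".join(rng.choice(AA) for _ in range(n))


class TestMotifModel:
    def test_defaults(self):
        fr = far_red_motif()
        assert (fr.motif, fr.min_matches) == ("VIPEDV", 5)
        wl = white_light_motif()
        assert (wl.motif, wl.min_matches) == ("ENACS", 4)

    def test_threshold_bounds(self):
        with pytest.raises(ValidationError):
            MotifModel("m", "VIPEDV", 2)   # below ceil(6/2)
        with pytest.raises(ValidationError):
            MotifModel("m", "VIP", 3)      # too short


class TestScanProtein:
    def test_exact_hit(self):
        hits = scan_protein("GGGVIPEDVGGG", far_red_motif())
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.position, hit.matched, hit.score) == (4, "VIPEDV", 1.0)

    def test_one_substitution_tolerated(self):
        (hit,) = scan_protein("VIPQDV", far_red_motif())
        assert hit.matches == 5

    def test_x_never_matches(self):
        assert scan_protein("VIPXDV", MotifModel("m", "VIPEDV", 6)) == []

    def test_short_protein_empty(self):
        assert scan_protein("VIP", far_red_motif()) == []

    def test_matches_naive_oracle(self):
        rng = random.Random(31)
        motif = far_red_motif()
        for _ in range(40):
            protein = _rand_protein(rng, rng.randint(6, 120))
            # plant a decayed motif sometimes
            if rng.random() < 0.5 and len(protein) > 10:
                pos = rng.randint(0, len(protein) - 6)
                decayed = list("VIPEDV")
                decayed[rng.randint(0, 5)] = rng.choice(AA)
                protein = (
                    protein[:pos] + "".join(decayed) + protein[pos + 6:]
                )
            oracle = []
            for start in range(len(protein) - 5):
                window = protein[start:start + 6]
                m = sum(
                    a == b and a != "X" for a, b in zip(window, "VIPEDV")
                )
                if m >= 5:
                    oracle.append((start + 1, window, m))
            got = [
                (h.position, h.matched, h.matches)
                for h in scan_protein(protein, motif)
            ]
            assert got == oracle


def _reverse_translate(rng, protein):
    from farmarker.seqio import expand_degenerate, translate as tr

    codons = []
    table = {}
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                table.setdefault(tr(a + b + c), []).append(a + b + c)
    for res in protein:
        codons.append(rng.choice(table[res]))
    return "".join(codons)


class TestScreenReads:
    def test_motif_in_internal_frame(self):
        rng = random.Random(41)
        coding = _reverse_translate(rng, "VIPEDV")
        read = "G" + coding + "A" * (100 - len(coding) - 1)
        hits = screen_reads(
            [SequenceRecord("r", read, DNA)], far_red_motif()
        )
        assert any(h.frame == 2 and h.matched == "VIPEDV" for h in hits)

    def test_strand_symmetry(self):
        rng = random.Random(43)
        coding = _reverse_translate(rng, "VIPEDV")
        read = "GG" + coding + "A" * 40
        rc = reverse_complement(read)
        fwd = screen_reads([SequenceRecord("r", read, DNA)], far_red_motif())
        rev = screen_reads([SequenceRecord("r", rc, DNA)], far_red_motif())
        assert {h.matched for h in fwd} == {h.matched for h in rev}
        assert any(h.frame < 0 for h in rev)

    def test_split_motif_never_called(self):
        rng = random.Random(47)
        coding = _reverse_translate(rng, "VIPEDV")
        read = "A" * 50 + coding[:9]  # only half the motif codons
        assert screen_reads(
            [SequenceRecord("r", read, DNA)],
            MotifModel("m", "VIPEDV", 6),
        ) == []

    def test_full_coverage_recall_on_family_reads(self):
        from farmarker import generate_reads

        fam = generate_family(FamilySpec(seed=5, n_target=5, n_background=5))
        reads = generate_reads(fam, coverage=20, error_rate=0.0, seed=6)
        lo, hi = fam.island_columns  # gapless family: columns = positions
        covering = [
            r for r in reads
            if r.id.startswith("target")
            and int(r.id.split("|")[2]) <= lo
            and int(r.id.split("|")[2]) + 100 - 1 >= hi
        ]
        assert covering, "coverage 20x should cover the motif many times"
        hit_ids = {h.record_id for h in screen_reads(covering, far_red_motif())}
        assert hit_ids == {r.id for r in covering}


class TestClassify:
    def test_family_classification(self, default_family):
        fam = default_family
        cys = CysCheck(fam.protein_alignment(), fam.reference_id, 217)
        for rec in fam.records[:6] + fam.records[-6:]:
            call = classify_apce(rec, cys_check=cys)
            want = (
                FAR_RED if fam.class_map[rec.id] == "target" else WHITE_LIGHT
            )
            assert call.label == want
            assert call.cysteine == (
                "absent" if want == FAR_RED else "present"
            )

    def test_both_planted_motifs_ambiguous(self):
        protein = "G" * 10 + "VIPEDV" + "G" * 10 + "ENACS" + "G" * 10
        call = classify_apce(SequenceRecord("p", protein, PROTEIN))
        assert call.label == AMBIGUOUS

    def test_no_motif_is_no_call(self):
        call = classify_apce(SequenceRecord("p", "G" * 50, PROTEIN))
        assert call.label == NO_CALL

    def test_cysteine_conflict_is_ambiguous(self):
        fam = generate_family(FamilySpec(seed=8, n_target=3, n_background=3))
        cys = CysCheck(fam.protein_alignment(), fam.reference_id, 217)
        # take a target gene but graft the background's cysteine codon in
        rec = fam.class_alignment("target")[1].ungapped()
        lo, _ = fam.cys_columns
        seq = rec.seq[:lo - 1] + "TGC" + rec.seq[lo + 2:]
        call = classify_apce(
            SequenceRecord(rec.id, seq, DNA), cys_check=cys
        )
        assert call.label == AMBIGUOUS
        assert call.cysteine == "present"

    def test_decay_never_flips_label_at_locus(self):
        """Motif decay degrades to NO_CALL, not to the opposite class."""
        flips = 0
        for seed in range(40):
            fam = generate_family(
                FamilySpec(
                    seed=seed, n_target=2, n_background=2,
                    substitution_rate=0.2, mutate_planted=True,
                )
            )
            for rec in fam.records:
                protein = translate(rec.ungapped().seq, 1)
                locus = protein[180:232].replace("*", "X")
                call = classify_apce(SequenceRecord(rec.id, locus, PROTEIN))
                want = (
                    FAR_RED
                    if fam.class_map[rec.id] == "target"
                    else WHITE_LIGHT
                )
                opposite = FAR_RED if want == WHITE_LIGHT else WHITE_LIGHT
                if call.label == opposite:
                    flips += 1
        assert flips == 0


class TestExtractQueryFragment:
    def _hit(self, protein, motif="VIPEDV"):
        (hit,) = scan_protein(protein, MotifModel("m", motif, len(motif)))
        return hit

    def test_centered_46mer(self):
        rng = random.Random(53)
        protein = _rand_protein(rng, 203) + "VIPEDV" + _rand_protein(rng, 91)
        hit = self._hit(protein)
        frag = extract_query_fragment(protein, hit, total_len=46)
        assert len(frag) == 46
        assert "VIPEDV" in frag
        # roughly centered: motif midpoint within 1 residue of fragment middle
        assert abs(frag.index("VIPEDV") + 3 - 23) <= 1

    def test_short_protein_returned_whole(self):
        protein = "GGGGVIPEDVGGGGGGGGGGGGGGGGGGGG"
        frag = extract_query_fragment(protein, self._hit(protein), 46)
        assert frag == protein

    def test_motif_at_start_shifts_inward(self):
        rng = random.Random(59)
        protein = "VIPEDV" + _rand_protein(rng, 94)
        frag = extract_query_fragment(protein, self._hit(protein), 46)
        assert frag == protein[:46]
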