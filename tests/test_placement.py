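import random

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from farmarker import (
    DNA,
    InsufficientOverlapError,
    SequenceRecord,
    ValidationError,
    nj_tree,
    p_distance,
    place_fragment,
    reverse_complement,
)
from farmarker.placement import distance_matrix


def _rec(i, seq):
    return SequenceRecord(i, seq, DNA)


class TestPDistance:
    def test_identical(self):
        assert p_distance(_rec("a", "ACGT"), _rec("b", "ACGT"), 4) == 0.0

    def test_one_of_four(self):
        assert p_distance(_rec("a", "ACGT"), _rec("b", "ACGA"), 4) == 0.25

    def test_gaps_and_ambiguity_excluded(self):
        a = _rec("a", "AC-GNT")
        b = _rec("b", "ACTGAA")
        # comparable columns: 1,2,4,6 -> one mismatch (T vs A)
        assert p_distance(a, b, 3) == pytest.approx(0.25)

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientOverlapError):
            p_distance(_rec("a", "A---"), _rec("b", "A---"), 2)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            p_distance(_rec("a", "ACG"), _rec("b", "ACGT"), 1)

    def test_matches_column_loop_oracle(self):
        rng = random.Random(61)
        for _ in range(30):
            n = rng.randint(20, 80)
            a = "".join(rng.choice("ACGT-N") for _ in range(n))
            b = "".join(rng.choice("ACGT-N") for _ in range(n))
            comparable = mism = 0
            for x, y in zip(a, b):
                if x in "ACGT" and y in "ACGT":
                    comparable += 1
                    mism += x != y
            if comparable == 0:
                continue
            assert p_distance(_rec("a", a), _rec("b", b), 1) == pytest.approx(
                mism / comparable
            )

    def test_distance_matrix_agrees_with_pairwise(self):
        rng = random.Random(67)
        recs = [
            _rec(f"s{i}", "".join(rng.choice("ACGT-") for _ in range(60)))
            for i in range(5)
        ]
        dm = distance_matrix(recs, min_overlap=5)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert dm[i, j] == pytest.approx(
                        p_distance(recs[i], recs[j], 5)
                    )


def _random_tree_distances(rng, ntaxa):
    """Random binary tree; return labels, additive matrix, via path lengths."""
    nodes = [(f"t{i}",) for i in range(ntaxa)]  # tuples of leaf labels
    dist = {}

    def add(a, b, d):
        dist[frozenset((a, b))] = d

    # leaf depth bookkeeping: accumulate per-leaf distance to current root
    depth = {f"t{i}": 0.0 for i in range(ntaxa)}
    groups = [[f"t{i}"] for i in range(ntaxa)]
    while len(groups) > 1:
        i, j = rng.sample(range(len(groups)), 2)
        gi, gj = groups[i], groups[j]
        bi, bj = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        for a in gi:
            for b in gj:
                add(a, b, depth[a] + bi + depth[b] + bj)
        for a in gi:
            depth[a] += bi
        for b in gj:
            depth[b] += bj
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [gi + gj]
    labels = sorted(depth)
    m = np.zeros((len(labels), len(labels)))
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            m[a, b] = m[b, a] = dist[frozenset((labels[a], labels[b]))]
    return labels, m


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
            ["a", "b", "c"],
        )
        tree = nj_tree(dm)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["a"] == pytest.approx(1.0)
        assert tips["b"] == pytest.approx(2.0)
        assert tips["c"] == pytest.approx(3.0)

    def test_closest_pair_joined_first(self):
        # ultrametric 4-taxon matrix: a,b clearly closest
        m = np.array(
            [
                [0, 0.1, 1, 1],
                [0.1, 0, 1, 1],
                [1, 1, 0, 0.4],
                [1, 1, 0.4, 0],
            ]
        )
        tree = nj_tree(DistanceMatrix(m, ["a", "b", "c", "d"]))
        a = tree.find("a")
        assert {t.name for t in a.parent.tips()} == {"a", "b"}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))

    def test_recovers_additive_matrices(self):
        rng = random.Random(71)
        for _ in range(100):
            ntaxa = rng.randint(5, 8)
            labels, m = _random_tree_distances(rng, ntaxa)
            tree = nj_tree(DistanceMatrix(m, labels))
            # tree metric uniqueness: patristic distances must equal input
            dm_out = tree.tip_tip_distances(labels)
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    assert abs(dm_out[a, b] - m[i, j]) < 1e-9

    def test_agrees_with_skbio_topology(self):
        rng = random.Random(73)
        for _ in range(10):
            labels, m = _random_tree_distances(rng, 6)
            mine = nj_tree(DistanceMatrix(m, labels))
            theirs = skbio_nj(DistanceMatrix(m, labels))
            assert mine.compare_rfd(theirs) == 0

    def test_negative_branches_clamped(self):
        m = np.array(
            [
                [0, 0.1, 0.6, 0.6],
                [0.1, 0, 0.6, 0.6],
                [0.6, 0.6, 0, 0.05],
                [0.6, 0.6, 0.05, 0],
            ]
        )
        tree = nj_tree(DistanceMatrix(m, ["a", "b", "c", "d"]))
        assert all(t.length >= 0 for t in tree.postorder() if t.length is not None)


class TestPlacement:
    def test_exact_substring_places_at_source(self, default_family):
        fam = default_family
        src = fam.class_alignment("target")[2]
        frag = SequenceRecord("frag", src.seq[700:1500], DNA)
        res = place_fragment(frag, list(fam.alignment))
        assert res.nearest == src.id
        assert res.ranking[0][1] == 0.0

    def test_amplicon_sisters_within_target_clade(
        self, default_family, default_profiles
    ):
        from farmarker import amplify, design_marker_pair, discriminative_islands

        fam = default_family
        tp, bp, mp = default_profiles
        pair = design_marker_pair(
            discriminative_islands(tp, bp), tp, bp, mp,
            fam.class_alignment("target")[0],
        )
        for rec in fam.class_alignment("target")[:3]:
            (amp,) = amplify(rec.ungapped(), pair, (800, 1600))
            res = place_fragment(
                SequenceRecord("frag", amp.sequence, DNA), list(fam.alignment)
            )
            assert res.sister_group
            assert all(s.startswith("target") for s in res.sister_group)

    def test_reverse_complement_invariance(self, default_family):
        fam = default_family
        src = fam.class_alignment("target")[1]
        frag = src.seq[600:1400]
        res_f = place_fragment(
            SequenceRecord("frag", frag, DNA), list(fam.alignment)
        )
        res_r = place_fragment(
            SequenceRecord("frag", reverse_complement(frag), DNA),
            list(fam.alignment),
        )
        assert res_f.nearest == res_r.nearest
        assert res_f.ranking == res_r.ranking

    def test_reference_order_invariance(self, default_family):
        fam = default_family
        src = fam.class_alignment("background")[0]
        frag = SequenceRecord("frag", src.seq[650:1450], DNA)
        refs = list(fam.alignment)
        res_a = place_fragment(frag, refs)
        res_b = place_fragment(frag, refs[::-1])
        assert res_a.nearest == res_b.nearest
        assert sorted(res_a.ranking) == sorted(res_b.ranking)

    def test_short_fragment_rejected(self, default_family):
        frag = SequenceRecord("frag", "ACGT" * 10, DNA)
        with pytest.raises(InsufficientOverlapError):
            place_fragment(frag, list(default_family.alignment), min_overlap=100)

    def test_newick_serialises(self, default_family):
        fam = default_family
        frag = SequenceRecord(
            "frag", fam.class_alignment("target")[0].seq[700:1200], DNA
        )
        res = place_fragment(frag, list(fam.alignment))
        assert res.newick.count("(") >= 1 and res.newick.rstrip().endswith(";")
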