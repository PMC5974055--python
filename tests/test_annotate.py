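"""ORF calling, operons, family assignment and protein statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers_align import best_global_score, blosum62_sub
from plasmidkit import annotate, synthdata
from plasmidkit.annotate import (
    detect_operons,
    find_orfs,
    pairwise_protein_identity,
    protein_charge,
    protein_stats,
)
from plasmidkit.seqio import CircularSequence, SequenceError, rotate


def test_no_start_codon_no_orfs():
    s = CircularSequence("s", "CCCCCCCCCCCC", topology="linear")
    assert find_orfs(s, min_aa=1) == []


def test_hand_translated_minimal_orf():
    s = CircularSequence("s", "ATGAAATAG", topology="linear")
    orfs = find_orfs(s, min_aa=2, starts=("ATG",))
    assert len(orfs) == 1
    assert orfs[0].protein == "MK"
    assert orfs[0].feature.start == 1 and orfs[0].feature.end == 9


def test_minus_strand_orf_coordinates():
    # revcomp of ATGAAATAG, embedded linearly
    s = CircularSequence("s", "CTATTTCAT", topology="linear")
    orfs = find_orfs(s, min_aa=2, starts=("ATG",))
    assert len(orfs) == 1
    assert orfs[0].protein == "MK"
    assert orfs[0].feature.strand == "-"
    assert (orfs[0].feature.start, orfs[0].feature.end) == (1, 9)


def test_orf_set_rotation_invariant(ancestor):
    seq, _ = ancestor
    base = {(g.protein, g.feature.strand) for g in find_orfs(seq, min_aa=40)}
    for k in (1000, 3172, 5500):
        rot = rotate(seq, k)
        prots = {
            (g.protein, g.feature.strand) for g in find_orfs(rot, min_aa=40)
        }
        assert prots == base


def test_origin_spanning_orf_recovered():
    # place a gene across the origin by rotating into its middle
    s = CircularSequence(
        "s", "ATGAAACCCGGGTTTACCTAA" + "CCGGCCGGCC"
    )
    orfs = find_orfs(s, min_aa=5, starts=("ATG",))
    assert any(g.protein == "MKPGFT" for g in orfs)
    rot = rotate(s, 10)  # gene now wraps
    orfs_r = find_orfs(rot, min_aa=5, starts=("ATG",))
    hit = [g for g in orfs_r if g.protein == "MKPGFT"]
    assert len(hit) == 1
    assert hit[0].feature.spans_origin()


def test_nested_starts_report_longest_with_alternatives():
    s = CircularSequence("s", "ATGCCCATGAAACCCTAA", topology="linear")
    orfs = find_orfs(s, min_aa=2, starts=("ATG",))
    assert len(orfs) == 1
    assert orfs[0].protein.startswith("MPMK")
    assert "alt_starts" in orfs[0].feature.attributes


def test_planted_genes_recovered_exactly(ancestor):
    seq, truth = ancestor
    called = {
        (g.feature.start, g.feature.end, g.feature.strand)
        for g in find_orfs(seq, min_aa=30)
    }
    for label, coords in truth.genes["ancestor"].items():
        assert tuple(coords) in called, label


# ---------------------------------------------------------------------------
# operons
# ---------------------------------------------------------------------------

def _gene(seq_id, start, end, strand="+"):
    from plasmidkit.seqio import Feature

    return annotate.GeneModel(
        feature=Feature(seq_id, start, end, strand, "CDS"),
        protein="M" * 10,
        start_codon="ATG",
    )


def test_overlapping_genes_grouped():
    genes = [_gene("p", 1, 300), _gene("p", 297, 600)]
    groups = detect_operons(genes)
    assert len(groups) == 1
    assert groups[0][1].overlaps_previous


def test_distant_genes_split():
    genes = [_gene("p", 1, 300), _gene("p", 801, 1100)]
    assert len(detect_operons(genes)) == 2


def test_gap_within_threshold_grouped():
    genes = [_gene("p", 1, 300), _gene("p", 320, 600)]
    assert len(detect_operons(genes)) == 1


def test_forward_operon_recovered_in_family(family):
    """The three forward genes form a single operon in every leaf."""
    seqs, truth = family
    for s in seqs:
        genes = truth.genes[s.id]
        models = []
        for lab in ("F1", "F2", "F3"):
            a, b, strand = genes[lab]
            models.append(_gene(s.id, a, b, strand))
        groups = detect_operons(models)
        assert len(groups) == 1
        assert len(groups[0]) == 3


# ---------------------------------------------------------------------------
# protein statistics
# ---------------------------------------------------------------------------

def test_basic_protein_high_pi():
    _, pi, _ = protein_stats("K" * 20)
    assert pi > 9


def test_acidic_protein_low_pi():
    _, pi, _ = protein_stats("D" * 20)
    assert pi < 4


def test_unknown_residue_rejected():
    with pytest.raises(SequenceError):
        protein_stats("MKXK")


@settings(deadline=None, max_examples=50)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40))
def test_charge_zero_at_pi(protein):
    _, pi, _ = protein_stats(protein, tol=1e-6)
    assert abs(protein_charge(protein, pi)) < 1e-4


@settings(deadline=None, max_examples=30)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40))
def test_charge_monotone_decreasing(protein):
    phs = np.linspace(0.5, 13.5, 27)
    charges = [protein_charge(protein, ph) for ph in phs]
    assert all(a >= b - 1e-9 for a, b in zip(charges, charges[1:]))


def test_pi_agrees_with_independent_implementation():
    """Cross-check against Biopython's Bjellqvist-table pI.

    Different pKa tables shift pI by a few tenths, so the comparison is
    deliberately loose.
    """
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

    rng = np.random.default_rng(0)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(10):
        protein = "".join(rng.choice(list(aas), size=60))
        _, pi, _ = protein_stats(protein)
        ref = IsoelectricPoint(protein).pi()
        assert abs(pi - ref) < 1.0


# ---------------------------------------------------------------------------
# protein identity
# ---------------------------------------------------------------------------

def test_identity_identical_sequences():
    assert pairwise_protein_identity("MKLVATW" * 5, "MKLVATW" * 5) == 100.0


def test_identity_low_for_reversed_random():
    rng = np.random.default_rng(1)
    p = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
    assert pairwise_protein_identity(p, p[::-1]) < 40.0


def test_identity_symmetric():
    a = "MKLVATWDE" * 4
    b = "MKIVATWEE" * 4
    assert pairwise_protein_identity(a, b) == pairwise_protein_identity(b, a)


def test_protein_alignment_score_matches_exhaustive_oracle():
    """Affine BLOSUM62 global DP equals brute-force enumeration (<=8 aa)."""
    from plasmidkit.annotate import _protein_aligner

    rng = np.random.default_rng(3)
    aligner = _protein_aligner()
    sub = blosum62_sub()
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(40):
        a = "".join(rng.choice(aas, size=rng.integers(1, 9)))
        b = "".join(rng.choice(aas, size=rng.integers(1, 9)))
        expected = best_global_score(a, b, sub, 11.0, 1.0)
        assert aligner.score(a, b) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# family assignment
# ---------------------------------------------------------------------------

def test_single_shared_gene_clusters(small_family):
    seqs, truth = small_family
    a, b = seqs[0], seqs[1]
    genes = {
        s.id: [
            m
            for m in annotate.find_orfs(s, min_aa=30)
            if (m.feature.start, m.feature.end, m.feature.strand)
            == tuple(truth.genes[s.id]["F2"])
        ]
        for s in (a, b)
    }
    fam = annotate.assign_families(genes)
    assert fam.labels(a.id) == fam.labels(b.id)
    assert fam.labels(a.id)[0] != "other"


def test_family_assignment_recovers_core(family):
    seqs, truth = family
    genes = {s.id: annotate.find_orfs(s, min_aa=30) for s in seqs}
    fam = annotate.assign_families(genes)
    core = {"F1", "F2", "F3", "R4", "R5", "R6", "R7"}
    for s in seqs:
        labels = dict()
        for lab, g in fam.assignments[s.id]:
            labels[lab] = (g.feature.start, g.feature.end, g.feature.strand)
        present = core & set(labels)
        # every core family present in the truth must be labeled and at
        # the planted coordinates
        for lab in sorted(core):
            if lab not in truth.genes[s.id]:
                continue
            assert lab in present
            assert labels[lab] == tuple(truth.genes[s.id][lab]), lab


def test_family_assignment_input_order_invariant(small_family):
    seqs, _ = small_family
    genes = {s.id: annotate.find_orfs(s, min_aa=30) for s in seqs[:3]}
    fam1 = annotate.assign_families(dict(sorted(genes.items())))
    fam2 = annotate.assign_families(dict(sorted(genes.items(), reverse=True)))
    for pid in genes:
        assert fam1.labels(pid) == fam2.labels(pid)


def test_requires_two_plasmids():
    with pytest.raises(SequenceError):
        annotate.assign_families({"only": []})
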