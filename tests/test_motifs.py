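"""Degenerate motif scanning, RBS search, inverted repeats, CIS."""

import numpy as np
import pytest

from plasmidkit import annotate, compare, motifs, synthdata
from plasmidkit.motifs import (
    IUPAC,
    PROMOTER_CONSENSUS,
    detect_cis,
    find_inverted_repeats,
    find_rbs,
    iupac_match_probability,
    promoter_positional_filter,
    scan_iupac,
)
from plasmidkit.seqio import CircularSequence, Feature, SequenceError, rotate, subsequence


def test_nn_pattern_matches_everywhere():
    s = CircularSequence("s", "ACGTACGTAC")
    hits = scan_iupac(s, "NN", strands="+")
    assert len(hits) == s.length  # circular: every start position


def test_invalid_iupac_letter_rejected():
    s = CircularSequence("s", "ACGTACGT")
    with pytest.raises(SequenceError):
        scan_iupac(s, "AXG")


def _brute_matches(seq, pattern, max_mismatch):
    """Independent re-implementation: direct window comparison."""
    out = []
    dbl = seq.residues + seq.residues[: len(pattern) - 1]
    for i in range(seq.length):
        window = dbl[i : i + len(pattern)]
        mism = sum(
            1
            for p, b in zip(pattern.upper(), window)
            if p != "N" and b not in IUPAC[p]
        )
        if mism <= max_mismatch:
            out.append(i + 1)
    return out


@pytest.mark.parametrize("pattern", ["SRNNRNNNTTWW", "GGAGGTGA", "WWSS"])
@pytest.mark.parametrize("max_mismatch", [0, 1])
def test_scan_matches_brute_force(pattern, max_mismatch):
    rng = np.random.default_rng(11)
    for _ in range(5):
        s = CircularSequence(
            "s", "".join(rng.choice(list("ACGT"), size=rng.integers(30, 200)))
        )
        got = [
            h.start
            for h in scan_iupac(s, pattern, strands="+", max_mismatch=max_mismatch)
        ]
        assert got == _brute_matches(s, pattern, max_mismatch)


def test_hits_rotation_covariant():
    rng = np.random.default_rng(12)
    s = CircularSequence("s", "".join(rng.choice(list("ACGT"), size=300)))
    base = {(h.start, h.strand) for h in scan_iupac(s, "SRNNRNNNTTWW")}
    k = 101
    r = rotate(s, k)
    rotated = {(h.start, h.strand) for h in scan_iupac(r, "SRNNRNNNTTWW")}
    expected = {((p - k) % s.length + 1, st) for p, st in base}
    assert rotated == expected


def test_background_count_matches_closed_form():
    """Hit counts on i.i.d. sequence agree with the analytic expectation."""
    rng = np.random.default_rng(13)
    gc = 0.4
    p = iupac_match_probability(PROMOTER_CONSENSUS, gc)
    n, L = 40, 1000
    counts = []
    for i in range(n):
        s = CircularSequence(
            "s",
            "".join(
                rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=L)
            ),
        )
        counts.append(len(scan_iupac(s, PROMOTER_CONSENSUS, strands="both")))
    mean = np.mean(counts)
    expect = 2 * L * p  # both strands
    sigma = np.sqrt(2 * L * p / n)  # SE of the mean (Poisson-like)
    assert abs(mean - expect) <= 3 * sigma


def test_planted_promoter_recovered(ancestor):
    seq, truth = ancestor
    el = truth.elements["ancestor"]
    hits = scan_iupac(seq, PROMOTER_CONSENSUS, strands="both")
    fwd = el["promoter_fwd"]
    rev = el["promoter_rev"]
    assert any(h.start == fwd[0] and h.strand == "+" for h in hits)
    assert any(h.start == rev[0] and h.strand == "-" for h in hits)


# ---------------------------------------------------------------------------
# RBS
# ---------------------------------------------------------------------------

def test_planted_exact_rbs_found():
    gene_start = 101
    up = "C" * (gene_start - 1 - 8 - 5) + "GGAGGTGA" + "C" * 5
    s = CircularSequence("s", up + "ATG" + "GCA" * 30 + "TGA" + "C" * 20)
    gene = Feature("s", gene_start, gene_start + 95, "+", "CDS")
    hit = find_rbs(s, gene)
    assert hit is not None
    assert hit.mismatches == 0
    assert hit.offset_to_anchor == 5


def test_absent_rbs_returns_none():
    s = CircularSequence("s", "C" * 100 + "ATG" + "GCA" * 30 + "TGA")
    gene = Feature("s", 101, 196, "+", "CDS")
    assert find_rbs(s, gene) is None


def test_family_f3_rbs_offset_four(family):
    """GGAGGCGA sits 4 nt upstream of every F3 start across the family."""
    seqs, truth = family
    for s in seqs:
        coords = truth.genes[s.id]["F3"]
        gene = Feature(s.id, coords[0], coords[1], coords[2], "CDS")
        hit = find_rbs(s, gene)
        assert hit is not None
        assert hit.offset_to_anchor == 4
        assert hit.feature.attributes["matched"] == "GGAGGCGA"
        assert hit.mismatches == 1  # C vs consensus T


def test_rbs_on_reverse_strand_gene():
    # revcomp construction of the forward case
    fwd = "C" * 87 + "GGAGGTGA" + "C" * 5 + "ATG" + "GCA" * 30 + "TGA" + "C" * 20
    from plasmidkit.seqio import reverse_complement

    s = CircularSequence("s", reverse_complement(fwd))
    L = s.length
    # forward gene at 101..196 maps to reverse interval L-195..L-100
    gene = Feature("s", L - 195, L - 100, "-", "CDS")
    hit = find_rbs(s, gene)
    assert hit is not None and hit.offset_to_anchor == 5


# ---------------------------------------------------------------------------
# inverted repeats
# ---------------------------------------------------------------------------

def test_planted_palindrome_found():
    s = CircularSequence("s", "TTTT" + "AAGGCC" + "ACGG" + "GGCCTT" + "TTTT")
    irs = find_inverted_repeats(s, min_arm=6, max_loop=6)
    top = irs[0]
    assert (top.arm_len, top.loop_len, top.mismatches) == (6, 4, 0)
    assert (top.left_start, top.left_end) == (5, 10)
    assert (top.right_start, top.right_end) == (15, 20)


def test_arm_is_reverse_complement():
    rng = np.random.default_rng(14)
    s = CircularSequence("s", "".join(rng.choice(list("ACGT"), size=200)))
    for ir in find_inverted_repeats(s, min_arm=4, max_loop=8)[:20]:
        left = subsequence(s, ir.left_start, ir.left_end, "+")
        right = subsequence(s, ir.right_start, ir.right_end, "+")
        from plasmidkit.seqio import reverse_complement

        assert sum(
            1 for a, b in zip(reverse_complement(left), right) if a != b
        ) == ir.mismatches


def test_long_arms_rare_in_random_sequence():
    """Exact 8-nt arms appear at the ~4^-8 per-center rate."""
    rng = np.random.default_rng(15)
    n_windows, w = 300, 80
    total = 0
    for _ in range(n_windows):
        s = CircularSequence(
            "s", "".join(rng.choice(list("ACGT"), size=w)), topology="linear"
        )
        total += len(find_inverted_repeats(s, min_arm=8, max_loop=8, max_mismatch=0))
    # expectation ~= windows * centers * loops * 4^-8 ~ 2.5; allow Poisson tail
    assert total <= 12


def test_family_r4_proximal_ir_recovered(family):
    """The planted IR upstream of R4 is found at -16..-25 in every leaf."""
    seqs, truth = family
    for s in seqs:
        r4 = truth.genes[s.id]["R4"]
        ir_truth = truth.elements[s.id].get("R4_PIR")
        assert ir_truth is not None
        # upstream of a reverse-strand gene = positions after its end
        irs = find_inverted_repeats(
            s, start=r4[1] + 1, end=min(s.length, r4[1] + 60), min_arm=5
        )
        hits = [
            ir
            for ir in irs
            if abs(ir.left_start - ir_truth[0]) <= 4
            and abs(ir.right_end - ir_truth[1]) <= 4
        ]
        assert hits, s.id
        best = hits[0]
        center = (best.left_start + best.right_end) / 2
        offset = center - r4[1]  # upstream distance on the minus strand
        assert 10 <= offset <= 30
        assert best.at_motif_len >= 4


# ---------------------------------------------------------------------------
# CIS detection
# ---------------------------------------------------------------------------

def test_identical_msa_returns_intergenic_region():
    row = "A" * 30 + "ATGCCCGGGTAA" * 5 + "T" * 40 + "ATGCCCGGGTAA" * 5
    rows = [row] * 3
    ids = ["a", "b", "c"]
    genes = {
        i: [
            Feature(i, 31, 90, "+", "CDS"),
            Feature(i, 131, 190, "+", "CDS"),
        ]
        for i in ids
    }
    cis = detect_cis(ids, rows, genes, min_len=12)
    spans = [(r.col_start, r.col_end) for r in cis]
    assert (0, 29) in spans
    assert (90, 129) in spans  # columns between gene1 end and gene2 start


def test_randomized_intergenic_not_conserved():
    rng = np.random.default_rng(16)
    gene = "ATG" + "GCA" * 20 + "TAA"
    rows = []
    for _ in range(4):
        inter = "".join(rng.choice(list("ACGT"), size=50))
        rows.append(inter + gene)
    ids = list("abcd")
    genes = {i: [Feature(i, 51, 50 + len(gene), "+", "CDS")] for i in ids}
    assert detect_cis(ids, rows, genes, min_len=12) == []


def test_cis_input_order_invariant(family):
    seqs, truth = family
    ids, rows, _ = compare.progressive_msa(seqs)
    genes = {
        pid: [
            Feature(pid, s, e, st, "CDS")
            for s, e, st in truth.genes[pid].values()
        ]
        for pid in ids
    }
    cis1 = detect_cis(ids, rows, genes)
    perm = [2, 0, 4, 1, 3]
    cis2 = detect_cis(
        [ids[p] for p in perm], [rows[p] for p in perm], genes
    )
    assert [(r.col_start, r.col_end) for r in cis1] == [
        (r.col_start, r.col_end) for r in cis2
    ]


def test_planted_cis_islands_recovered(family):
    """Planted conserved intergenic islands map back within 5 nt."""
    seqs, truth = family
    ids, rows, _ = compare.progressive_msa(seqs)
    genes = {
        pid: [
            Feature(pid, s, e, st, "CDS")
            for s, e, st in truth.genes[pid].values()
        ]
        for pid in ids
    }
    cis = detect_cis(ids, rows, genes, min_len=12, min_conservation=0.9)
    assert len(cis) >= 2
    recovered = 0
    for name in ("CIS_I", "CIS_III"):
        found = False
        for r in cis:
            for pid in ids:
                t = truth.elements[pid].get(name)
                iv = r.intervals.get(pid)
                if t and iv and abs(iv[0] - t[0]) <= 5 and abs(iv[1] - t[1]) <= 5:
                    found = True
        recovered += found
    assert recovered == 2


# ---------------------------------------------------------------------------
# positional filtering
# ---------------------------------------------------------------------------

def test_filter_keeps_hit_at_minus_27():
    gene = Feature("s", 200, 400, "+", "CDS")
    hit_feature = Feature("s", 168, 179, "+", "motif")
    hit = motifs.MotifHit(feature=hit_feature, pattern_id="p", mismatches=0)
    kept = promoter_positional_filter([hit], [gene], (-30, -20), seq_length=1000)
    assert kept and kept[0].offset_to_anchor in (-27, -26)  # center 173.5


def test_filter_removes_distant_hit():
    gene = Feature("s", 200, 400, "+", "CDS")
    hit = motifs.MotifHit(
        feature=Feature("s", 95, 106, "+", "motif"), pattern_id="p", mismatches=0
    )
    assert promoter_positional_filter([hit], [gene], (-30, -20), 1000) == []


def test_planted_promoter_survives_filter(ancestor):
    """Only the planted CIS I forward promoter sits -30..-20 of a start."""
    seq, truth = ancestor
    hits = scan_iupac(seq, PROMOTER_CONSENSUS, strands="both")
    genes = [
        Feature(seq.id, s, e, st, "CDS")
        for s, e, st in truth.genes["ancestor"].values()
    ]
    kept = promoter_positional_filter(
        hits, genes, (-30, -20), seq_length=seq.length
    )
    fwd = truth.elements["ancestor"]["promoter_fwd"]
    assert any(h.start == fwd[0] and h.strand == "+" for h in kept)
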