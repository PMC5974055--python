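"""Circular alignment, MSA, distances and neighbor joining."""

import numpy as np
import pytest

from helpers_align import best_global_score, nt_sub
from plasmidkit import compare
from plasmidkit.compare import (
    Tree,
    bootstrap_nj,
    circular_align,
    msa_distance_matrix,
    nj_tree,
    progressive_msa,
    region_similarity,
    tree_bipartitions,
)
from plasmidkit.seqio import CircularSequence, SequenceError, rotate


def _random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), p=p, size=n))


def test_self_alignment_is_perfect():
    rng = np.random.default_rng(0)
    s = CircularSequence("s", _random_seq(rng, 400))
    aln = circular_align(s, s)
    assert aln.identity == 100.0
    assert aln.rotation_offset == 1


def test_rotated_copy_realigned_exactly():
    rng = np.random.default_rng(1)
    s = CircularSequence("s", _random_seq(rng, 500))
    for k in rng.integers(2, 500, size=12):
        r = rotate(s, int(k))
        aln = circular_align(s, r)
        assert aln.identity == 100.0
        # recovered rotation must undo k
        assert rotate(r, aln.rotation_offset).residues == s.residues


def test_short_sequences_rejected():
    a = CircularSequence("a", "ACGT" * 10)
    with pytest.raises(SequenceError):
        circular_align(a, a)


def test_nt_alignment_score_matches_exhaustive_oracle():
    """Affine global DP equals brute-force enumeration on <=10 nt."""
    from plasmidkit.compare import _nt_aligner

    rng = np.random.default_rng(5)
    aligner = _nt_aligner()
    sub = nt_sub(1.0, -1.0)
    for _ in range(60):
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 11)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 11)))
        expected = best_global_score(a, b, sub, 5.0, 1.0)
        assert aligner.score(a, b) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# MSA
# ---------------------------------------------------------------------------

def test_msa_of_identical_sequences_gap_free():
    rng = np.random.default_rng(2)
    s = _random_seq(rng, 300)
    seqs = [CircularSequence(f"s{i}", s) for i in range(4)]
    _ids, rows, _off = progressive_msa(seqs)
    assert all(r == s for r in rows)


def test_msa_two_sequences_matches_pairwise_identity():
    rng = np.random.default_rng(3)
    s = _random_seq(rng, 400)
    mutated = list(s)
    for i in rng.integers(0, 400, size=40):
        mutated[i] = "ACGT"[rng.integers(4)]
    seqs = [CircularSequence("a", s), CircularSequence("b", "".join(mutated))]
    aln = circular_align(seqs[0], seqs[1])
    ids, rows, _off = progressive_msa(seqs)
    pair_id = compare.msa_identity(rows, 0, 1)
    assert pair_id == pytest.approx(aln.identity, abs=1.0)


def _sp_score(rows, match=1.0, mismatch=-1.0, open_=5.0, extend=1.0):
    """Sum-of-pairs score of an MSA with affine gaps per pairwise row."""
    total = 0.0
    n = len(rows)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            in_gap = None
            for x, y in zip(a, b):
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    side = 0 if x == "-" else 1
                    total -= extend
                    if in_gap != side:
                        total -= open_
                    in_gap = side
                else:
                    total += match if x == y else mismatch
                    in_gap = None
    return total


def _star_msa(seqs):
    """Naive star alignment: merge pairwise alignments to the first."""
    center = seqs[0].residues
    others = []
    for s in seqs[1:]:
        _, ra, rb = compare.global_align(center, s.residues)
        others.append((ra, rb))
    # merge gap patterns into a common center coordinate frame
    gap_sets = []
    for ra, _rb in others:
        pos, gaps = 0, {}
        for ch in ra:
            if ch == "-":
                gaps[pos] = gaps.get(pos, 0) + 1
            else:
                pos += 1
        gap_sets.append(gaps)
    merged_gaps = {}
    for gaps in gap_sets:
        for pos, n in gaps.items():
            merged_gaps[pos] = max(merged_gaps.get(pos, 0), n)

    def expand(row, own_gaps):
        out, pos = [], 0
        i = 0
        for pos in range(len(center) + 1):
            need = merged_gaps.get(pos, 0)
            have = own_gaps.get(pos, 0)
            while have:
                out.append(row[i]); i += 1; have -= 1; need -= 1
            out.extend("-" * need)
            if pos < len(center):
                out.append(row[i]); i += 1
        return "".join(out)

    rows = [expand(center, {})]
    for (ra, rb), gaps in zip(others, gap_sets):
        rows.append(expand(rb, gaps))
    return rows


def test_msa_sum_of_pairs_beats_star_alignment():
    rng = np.random.default_rng(4)
    base = _random_seq(rng, 200)
    seqs = []
    for i in range(4):
        m = list(base)
        for k in rng.integers(0, 200, size=30):
            m[k] = "ACGT"[rng.integers(4)]
        seqs.append(CircularSequence(f"s{i}", "".join(m)))
    _ids, rows, _off = progressive_msa(seqs, rotation_normalize=False)
    star = _star_msa(seqs)
    assert _sp_score(rows) >= _sp_score(star) - 1e-9


def test_region_similarity_identical():
    s = "ACGTACGTGGCC" * 20
    seqs = [CircularSequence(f"s{i}", s) for i in range(3)]
    ids, rows, _off = progressive_msa(seqs)
    assert region_similarity(ids, rows, (10, 60)) == pytest.approx(100.0)


def test_two_tier_region_similarity(family):
    """Forward block ~84% identity, remainder ~54%, as generated."""
    seqs, truth = family
    ids, rows, _off = progressive_msa(seqs)
    f_end = truth.regions[ids[0]]["F_block"][1]
    f_sim = region_similarity(ids, rows, (1, f_end))
    rest_sim = region_similarity(ids, rows, (f_end + 1, seqs[0].length))
    assert f_sim == pytest.approx(84.0, abs=5.0)
    assert rest_sim == pytest.approx(54.0, abs=5.0)
    assert f_sim > rest_sim + 20


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_three_taxa_closed_form():
    d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
    t = nj_tree(d, ["a", "b", "c"])
    lengths = {c.label: bl for c, bl in t.children}
    assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)


def _random_additive(rng, n):
    """Random binary tree on n labeled leaves plus its path-distance matrix."""
    import itertools

    nodes = [(str(i), None) for i in range(n)]
    dist = {}
    for a, b in itertools.combinations(range(n), 2):
        dist[(a, b)] = 0.0
    # build by random joins, accumulating path lengths
    leaf_sets = [{i} for i in range(n)]
    extra = [0.0] * n  # distance from each leaf to its current subtree root
    trees = list(range(n))
    paths = np.zeros((n, n))
    roots = [{i: 0.0} for i in range(n)]  # leaf -> dist to root per subtree
    while len(roots) > 1:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        bi, bj = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        for la, da in roots[i].items():
            for lb, db in roots[j].items():
                a, b = min(la, lb), max(la, lb)
                paths[a, b] = paths[b, a] = da + bi + db + bj
        merged = {l: d + bi for l, d in roots[i].items()}
        merged.update({l: d + bj for l, d in roots[j].items()})
        roots = [r for k, r in enumerate(roots) if k not in (i, j)] + [merged]
        # remember bipartition of this join
    return paths


def test_nj_recovers_additive_topology():
    """On additive matrices NJ reconstructs tree distances exactly."""
    rng = np.random.default_rng(6)
    for rep in range(10):
        n = int(rng.integers(5, 9))
        paths = _random_additive(rng, n)
        labels = [str(i) for i in range(n)]
        t = nj_tree(paths, labels)
        # additive => NJ branch lengths reproduce all pairwise distances
        recovered = _tree_distances(t, labels)
        assert np.allclose(recovered, paths, atol=1e-8)


def _tree_distances(tree: Tree, labels):
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    d = np.zeros((n, n))

    def walk(node, acc):
        if not node.children:
            return {node.label: acc}
        below = {}
        for child, bl in node.children:
            below.update(walk(child, acc + bl))
        return below

    # gather leaf depths from every internal node to compute path sums
    def pairs(node):
        child_maps = []
        for child, bl in node.children:
            m = _leaf_depths(child)
            child_maps.append({l: dd + bl for l, dd in m.items()})
            pairs(child)
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for la, da in child_maps[i].items():
                    for lb, db in child_maps[j].items():
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db

    def _leaf_depths(node):
        if not node.children:
            return {node.label: 0.0}
        out = {}
        for child, bl in node.children:
            for l, dd in _leaf_depths(child).items():
                out[l] = dd + bl
        return out

    pairs(tree)
    return d


def test_nj_input_order_invariant():
    rng = np.random.default_rng(8)
    paths = _random_additive(rng, 6)
    labels = [str(i) for i in range(6)]
    t1 = nj_tree(paths, labels)
    perm = [3, 1, 5, 0, 4, 2]
    t2 = nj_tree(paths[np.ix_(perm, perm)], [labels[p] for p in perm])
    assert tree_bipartitions(t1) == tree_bipartitions(t2)


def test_nj_agrees_with_dendropy():
    import dendropy

    rng = np.random.default_rng(9)
    paths = _random_additive(rng, 7)
    labels = [f"t{i}" for i in range(7)]
    ours = nj_tree(paths, labels)

    csv_rows = ["," + ",".join(labels)]
    for i, l in enumerate(labels):
        csv_rows.append(l + "," + ",".join(str(x) for x in paths[i]))
    import io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO("\n".join(csv_rows)), delimiter=","
    )
    ref = pdm.nj_tree()
    ref_bips = set()
    taxa = {t.label for t in ref.taxon_namespace}
    anchor = min(taxa)
    for edge in ref.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.head_node.parent_node is None:
            continue
        side = frozenset(
            l.taxon.label for l in edge.head_node.leaf_iter()
        )
        if 1 < len(side) < len(taxa) - 1:
            if anchor in side:
                side = frozenset(taxa - side)
            ref_bips.add(side)
    assert tree_bipartitions(ours) == ref_bips


def test_negative_branch_clamped():
    d = np.array(
        [
            [0.0, 0.1, 0.5, 0.55],
            [0.1, 0.0, 0.45, 0.5],
            [0.5, 0.45, 0.0, 0.02],
            [0.55, 0.5, 0.02, 0.0],
        ]
    )
    t = nj_tree(d, list("abcd"))

    def all_lengths(node):
        out = []
        for c, bl in node.children:
            out.append(bl)
            out.extend(all_lengths(c))
        return out

    assert all(bl >= 0 for bl in all_lengths(t))


def test_bootstrap_deterministic_and_supported(family):
    seqs, _truth = family
    ids, rows, _off = progressive_msa(seqs)
    t1 = bootstrap_nj(ids, rows, n_replicates=30, seed=4)
    t2 = bootstrap_nj(ids, rows, n_replicates=30, seed=4)
    assert t1.newick() == t2.newick()

    def supports(node):
        out = []
        for c, _bl in node.children:
            if c.support is not None:
                out.append(c.support)
            out.extend(supports(c))
        return out

    assert all(0.0 <= s <= 1.0 for s in supports(t1))


def test_family_tree_recovers_sister_clades(family):
    seqs, _truth = family
    ids, rows, _off = progressive_msa(seqs)
    tree = bootstrap_nj(ids, rows, n_replicates=50, seed=0)
    bips = tree_bipartitions(tree)
    assert frozenset({"P_A", "P_B"}) in bips or frozenset(
        set(ids) - {"P_A", "P_B"}
    ) in bips
    assert frozenset({"P_C", "P_D"}) in bips or frozenset(
        set(ids) - {"P_C", "P_D"}
    ) in bips


def test_distance_matrix_symmetry(small_family):
    seqs, _ = small_family
    labels, d, _alns = compare.distance_matrix(seqs[:3])
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
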