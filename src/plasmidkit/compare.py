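"""Family-wide sequence comparison: circular-aware pairwise alignment,
progressive multiple alignment, distance matrices and neighbor-joining
trees with bootstrap support.

Circular replicons deposited in databases are linearized at arbitrary
points, so naive global alignment of two relatives can look far more
diverged than they are.  ``circular_align`` first recovers the relative
rotation by a k-mer offset vote, re-linearizes one partner, and only
then runs affine-gap global alignment.

The multiple alignment is progressive: a guide order from pairwise
distances, consensus-sequence profile merging, affine gaps.  Trees are
canonical neighbor-joining (Saitou–Nei Q-matrix) with bootstrap by MSA
column resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .seqio import CircularSequence, SequenceError, rotate

DEFAULT_NT_SCORES = {"match": 1.0, "mismatch": -1.0, "open": -5.0, "extend": -1.0}


@dataclass
class PairwiseAlignment:
    """A gapped pair of circular sequences with identity bookkeeping."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    identity: float
    rotation_offset: int  # 1-based new origin applied to b before aligning
    window_identity: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class Tree:
    """Unrooted binary tree node; leaves carry ``label``."""

    children: list[tuple["Tree", float]] = field(default_factory=list)
    label: str | None = None
    support: float | None = None

    def leaves(self) -> list[str]:
        if self.label is not None and not self.children:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(
            f"{c._newick(with_support)}:{bl:.6f}" for c, bl in self.children
        )
        lab = ""
        if with_support and self.support is not None:
            lab = f"{self.support:.2f}"
        return f"({inner}){lab}"


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

def _nt_aligner(scores: dict | None = None, mode: str = "global") -> Align.PairwiseAligner:
    s = dict(DEFAULT_NT_SCORES)
    if scores:
        s.update(scores)
    aligner = Align.PairwiseAligner()
    aligner.match_score = s["match"]
    aligner.mismatch_score = s["mismatch"]
    # gap of length L costs |open| + L * |extend|
    aligner.open_gap_score = s["open"] + s["extend"]
    aligner.extend_gap_score = s["extend"]
    aligner.mode = mode
    return aligner


def alignment_rows(aln) -> tuple[str, str]:
    return str(aln[0]), str(aln[1])


def global_align(a: str, b: str, scores: dict | None = None):
    """Affine-gap global DP; returns (score, row_a, row_b)."""
    aligner = _nt_aligner(scores)
    aln = aligner.align(a, b)[0]
    ra, rb = alignment_rows(aln)
    return float(aln.score), ra, rb


def best_rotation(a: CircularSequence, b: CircularSequence, k: int = 12) -> int:
    """1-based origin for ``rotate(b, .)`` maximizing a k-mer offset vote."""
    index: dict[str, list[int]] = {}
    ra = a.residues
    for i in range(len(ra) - k + 1):
        index.setdefault(ra[i : i + k], []).append(i)
    Lb = b.length
    votes = np.zeros(Lb, dtype=np.int64)
    rb = b.residues + b.residues[: k - 1]
    for j in range(Lb):
        for i in index.get(rb[j : j + k], ()):
            votes[(j - i) % Lb] += 1
    if votes.max() == 0:
        return 1
    # locate the offset neighborhood with smoothing (indels smear votes
    # over adjacent offsets), then take the raw-vote peak inside it
    kernel = np.ones(5)
    smoothed = np.convolve(
        np.concatenate([votes[-2:], votes, votes[:2]]), kernel, mode="valid"
    )
    center = int(np.argmax(smoothed))
    window = [(center + d) % Lb for d in range(-2, 3)]
    best = max(window, key=lambda i: votes[i])
    return best + 1


def circular_align(
    a: CircularSequence,
    b: CircularSequence,
    scores: dict | None = None,
    k: int = 12,
    window: int = 200,
) -> PairwiseAlignment:
    """Rotation-normalized global alignment of two circular sequences.

    Identity = identical columns / all alignment columns (gap columns
    count against identity).  ``window_identity`` is the identity in
    windows of ``window`` columns, reported at the window-center
    position of ``a``.
    """
    if min(a.length, b.length) < 100:
        raise SequenceError("circular alignment needs sequences >= 100 nt")
    if not (a.is_circular and b.is_circular):
        raise SequenceError("both sequences must be circular")
    offset = best_rotation(a, b, k=k)
    b_rot = rotate(b, offset)
    _, ra, rb = global_align(a.residues, b_rot.residues, scores)
    ncols = len(ra)
    ident_cols = np.fromiter(
        (ra[i] == rb[i] and ra[i] != "-" for i in range(ncols)),
        dtype=bool,
        count=ncols,
    )
    identity = 100.0 * ident_cols.sum() / ncols
    # per-window identity along a's coordinates
    a_pos = np.cumsum([c != "-" for c in ra])  # a-position per column
    win_id = []
    for lo in range(0, ncols, window):
        hi = min(lo + window, ncols)
        center_a = int(a_pos[(lo + hi) // 2 - 1])
        win_id.append(
            (center_a, 100.0 * ident_cols[lo:hi].sum() / (hi - lo))
        )
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        aligned_a=ra,
        aligned_b=rb,
        identity=identity,
        rotation_offset=offset,
        window_identity=win_id,
    )


# ---------------------------------------------------------------------------
# multiple alignment
# ---------------------------------------------------------------------------

def _consensus(rows: list[str]) -> str:
    """Column-majority consensus of a gapped profile (gaps lose ties)."""
    if len(rows) == 1:
        return rows[0].replace("-", "N") if "-" in rows[0] else rows[0]
    arr = np.array([list(r) for r in rows])
    out = []
    for col in arr.T:
        vals, counts = np.unique(col[col != "-"], return_counts=True)
        out.append(vals[np.argmax(counts)] if len(vals) else "N")
    return "".join(out)


def _merge_profiles(p1: list[str], p2: list[str], scores: dict | None):
    c1, c2 = _consensus(p1), _consensus(p2)
    _, r1, r2 = global_align(c1, c2, scores)
    out1, out2 = [], []
    i = j = 0
    gaps1, gaps2 = [], []  # column indices where to insert gaps
    for col, (x, y) in enumerate(zip(r1, r2)):
        if x == "-":
            gaps1.append(i)
        else:
            i += 1
        if y == "-":
            gaps2.append(j)
        else:
            j += 1

    def widen(rows, gaps):
        widened = []
        for r in rows:
            chars = list(r)
            for g in reversed(gaps):
                chars.insert(g, "-")
            widened.append("".join(chars))
        return widened

    return widen(p1, gaps1) + widen(p2, gaps2)


def progressive_msa(
    seqs: list[CircularSequence],
    scores: dict | None = None,
    rotation_normalize: bool = True,
) -> tuple[list[str], list[str], list[int]]:
    """Progressive multiple alignment; returns (ids, gapped rows, offsets).

    Sequences are rotation-normalized against the first (the applied
    1-based origins are returned as ``offsets``), then merged in a guide
    order from pairwise consensus distances (closest pair first).
    Columns >= length of the longest input.
    """
    if len(seqs) < 2:
        raise SequenceError("MSA needs >= 2 sequences")
    work = [seqs[0]]
    offsets = [1]
    for s in seqs[1:]:
        if rotation_normalize and s.is_circular:
            off = best_rotation(seqs[0], s)
            work.append(rotate(s, off))
            offsets.append(off)
        else:
            work.append(s)
            offsets.append(1)
    n = len(work)
    # guide distances from pairwise global alignments of the raw strings
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ra, rb = global_align(work[i].residues, work[j].residues, scores)
            ident = sum(x == y and x != "-" for x, y in zip(ra, rb)) / len(ra)
            dist[i, j] = dist[j, i] = 1.0 - ident

    # agglomerate closest profiles first (UPGMA-style order)
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [work[i].residues]) for i in range(n)
    }
    active = set(range(n))
    dmat = dist.copy()
    next_id = n
    dstore = {i: {j: dmat[i, j] for j in range(n) if j != i} for i in range(n)}
    while len(active) > 1:
        best_pair, best_d = None, np.inf
        for i in sorted(active):
            for j in sorted(active):
                if i < j and dstore[i][j] < best_d:
                    best_pair, best_d = (i, j), dstore[i][j]
        i, j = best_pair
        ids_i, rows_i = profiles.pop(i)
        ids_j, rows_j = profiles.pop(j)
        merged = _merge_profiles(rows_i, rows_j, scores)
        profiles[next_id] = (ids_i + ids_j, merged)
        active -= {i, j}
        dstore[next_id] = {}
        for m in active:
            d = 0.5 * (dstore[i][m] + dstore[j][m])
            dstore[next_id][m] = d
            dstore[m][next_id] = d
        active.add(next_id)
        next_id += 1

    order, rows = profiles.popitem()[1]
    id_list = [work[i].id for i in order]
    # restore input order
    perm = sorted(range(len(order)), key=lambda t: order[t])
    return (
        [id_list[t] for t in perm],
        [rows[t] for t in perm],
        [offsets[order[t]] for t in perm],
    )


def msa_identity(rows: list[str], i: int, j: int, cols: slice | None = None) -> float:
    """Percent identity of two MSA rows over columns where either has a base."""
    a = rows[i] if cols is None else rows[i][cols]
    b = rows[j] if cols is None else rows[j][cols]
    pairs = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
    if not pairs:
        raise SequenceError("no aligned columns")
    n_id = sum(1 for x, y in pairs if x == y and x != "-")
    return 100.0 * n_id / len(pairs)


def region_similarity(
    ids: list[str], rows: list[str], region: tuple[int, int], reference: int = 0
) -> float:
    """Mean pairwise identity over MSA columns mapping into ``region``.

    ``region`` is 1-based inclusive in the coordinates of the
    ``reference`` row's ungapped sequence.
    """
    start, end = region
    ref = rows[reference]
    pos = 0
    cols = []
    for c, ch in enumerate(ref):
        if ch != "-":
            pos += 1
            if start <= pos <= end:
                cols.append(c)
    if not cols:
        raise SequenceError("region has no aligned columns")
    lo, hi = cols[0], cols[-1] + 1
    sl = slice(lo, hi)
    vals = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            vals.append(msa_identity(rows, i, j, sl))
    return float(np.mean(vals))


def msa_distance_matrix(rows: list[str]) -> np.ndarray:
    """p-distance matrix (1 - identity) from MSA rows."""
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - msa_identity(rows, i, j) / 100.0
    return d


def distance_matrix(
    seqs: list[CircularSequence], scores: dict | None = None
) -> tuple[list[str], np.ndarray, list[PairwiseAlignment]]:
    """All-pairs circular alignment -> labels, 1-identity matrix, alignments."""
    n = len(seqs)
    d = np.zeros((n, n))
    alns = []
    for i in range(n):
        for j in range(i + 1, n):
            aln = circular_align(seqs[i], seqs[j], scores)
            d[i, j] = d[j, i] = 1.0 - aln.identity / 100.0
            alns.append(aln)
    return [s.id for s in seqs], d, alns


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: np.ndarray, labels: list[str]) -> Tree:
    """Canonical Saitou–Nei neighbor joining.

    Negative branch lengths are clamped to zero.  For 3 taxa the unique
    unrooted topology with three-point branch lengths is returned.
    """
    n = len(labels)
    if n < 3:
        raise SequenceError("NJ needs >= 3 taxa")
    if dist.shape != (n, n):
        raise SequenceError("distance matrix shape mismatch")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise SequenceError("distance matrix must be symmetric with zero diagonal")
    nodes: list[Tree] = [Tree(label=l) for l in labels]
    d = dist.astype(float).copy()
    idx = list(range(n))

    while len(idx) > 3:
        m = len(idx)
        sub = d[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        a, b = np.unravel_index(np.argmin(q), q.shape)
        if a > b:
            a, b = b, a
        ia, ib = idx[a], idx[b]
        dab = sub[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = Tree(children=[(nodes[ia], la), (nodes[ib], lb)])
        # distances from the new node
        dnew = 0.5 * (d[ia, idx] + d[ib, idx] - dab)
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, idx] = dnew
        d[idx, k] = dnew
        d[k, k] = 0.0
        nodes.append(new)
        idx = [t for t in idx if t not in (ia, ib)] + [k]

    # join the final three around the root
    ia, ib, ic = idx
    la = 0.5 * (d[ia, ib] + d[ia, ic] - d[ib, ic])
    lb = 0.5 * (d[ia, ib] + d[ib, ic] - d[ia, ic])
    lc = 0.5 * (d[ia, ic] + d[ib, ic] - d[ia, ib])
    return Tree(
        children=[
            (nodes[ia], max(la, 0.0)),
            (nodes[ib], max(lb, 0.0)),
            (nodes[ic], max(lc, 0.0)),
        ]
    )


def tree_bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized to the side not
    containing the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    parts: set[frozenset[str]] = set()

    def walk(node: Tree):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                if anchor in side:
                    side = all_leaves - side
                parts.add(side)
            walk(child)

    walk(tree)
    return parts


def bootstrap_nj(
    ids: list[str],
    rows: list[str],
    n_replicates: int = 100,
    seed: int = 0,
) -> Tree:
    """NJ tree from an MSA with bootstrap supports on internal edges.

    Columns are resampled with replacement; support = fraction of
    replicate NJ trees containing each bipartition of the full-data
    tree.  Deterministic for a fixed seed.
    """
    full = nj_tree(msa_distance_matrix(rows), ids)
    if n_replicates <= 0:
        return full
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in rows])
    ncols = arr.shape[1]
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree_bipartitions(full)}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        sampled = ["".join(row) for row in arr[:, cols]]
        try:
            rep = nj_tree(msa_distance_matrix(sampled), ids)
        except SequenceError:
            continue
        for bp in tree_bipartitions(rep):
            if bp in counts:
                counts[bp] += 1

    def annotate(node: Tree, parent_leaves: frozenset[str]):
        all_leaves = frozenset(ids)
        anchor = min(all_leaves)
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                key = all_leaves - side if anchor in side else side
                child.support = counts.get(key, 0) / n_replicates
            annotate(child, side)

    annotate(full, frozenset(ids))
    return full
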