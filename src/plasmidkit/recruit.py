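"""Iterative read recruitment and reassembly to circular closure.

Reproduces, at desk scale, the procedure used to reconstruct a plasmid
from metavirome shotgun data: map (recruit) reads against a related
reference, de novo reassemble the recruited reads, take the longest
contig as the new reference, and repeat until the contig's ends overlap
— the signature of a completed circle — or recruitment stalls.

Recruitment is k-mer-seeded (k=15) with identity verified by edit
distance (edlib); assembly is a de Bruijn graph over canonical k-mers
with coverage-1 pruning and maximal non-branching unitig extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .seqio import CircularSequence, SequenceError
from .synthdata import ReadSet

SEED_K = 15
_RC = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass
class Contig:
    sequence: str
    coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyState:
    """Progress of the recruit–assemble loop."""

    iteration: int
    recruited_ids: set[str]
    contigs: list[Contig]
    closed: bool
    final: CircularSequence | None
    rounds: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

def _position_index(target: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        idx.setdefault(target[i : i + k], []).append(i)
    return idx


def _nw_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def recruit_reads(
    reads: ReadSet,
    reference: CircularSequence | str,
    min_identity: float = 0.90,
    min_cov_frac: float = 0.8,
    k: int = SEED_K,
    min_overlap: int = 25,
) -> ReadSet:
    """Reads recruited to a reference by seeded overlap alignment.

    Shared ``k``-mer seeds vote for a read-to-reference offset; the
    implied overlapping spans are then verified by edit-distance
    identity.  On a circular reference the whole read must align at
    >= ``min_identity`` over >= ``min_cov_frac`` of its length; on a
    linear reference (a growing contig) a read may overhang either end,
    so an end overlap of >= ``min_overlap`` nt at >= ``min_identity``
    suffices — this is what lets iterative rounds extend contigs.
    """
    if isinstance(reference, CircularSequence):
        ref, circular = reference.residues, reference.is_circular
    else:
        ref, circular = reference, False
    target = ref + ref if circular else ref
    index = _position_index(target, k)
    L = len(ref)
    kept = []
    for rid, seq, qual in reads.reads:
        if len(seq) < k + 1:
            continue
        hit = False
        for q in (seq, _rc(seq)):
            # offset vote from seed hits
            votes: dict[int, int] = {}
            for i in range(0, len(q) - k + 1, 4):
                for j in index.get(q[i : i + k], ()):
                    o = j - i
                    if circular:
                        o %= L
                    votes[o] = votes.get(o, 0) + 1
            if not votes:
                continue
            for o, _n in sorted(votes.items(), key=lambda t: -t[1])[:3]:
                ref_lo = max(0, o)
                ref_hi = min(len(target), o + len(q))
                span = ref_hi - ref_lo
                need = (
                    int(min_cov_frac * len(q))
                    if circular
                    else min(min_overlap, len(q))
                )
                if span < need:
                    continue
                ident = _nw_identity(
                    q[ref_lo - o : ref_hi - o], target[ref_lo:ref_hi]
                )
                if ident >= min_identity:
                    hit = True
                    break
            if hit:
                break
        if hit:
            kept.append((rid, seq, qual))
    return ReadSet(reads=kept, source=dict(reads.source))


# ---------------------------------------------------------------------------
# de Bruijn assembly
# ---------------------------------------------------------------------------

def _kmer_counts(reads: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in reads:
        for s in (r, _rc(r)):
            for i in range(len(s) - k + 1):
                m = s[i : i + k]
                if "N" in m:
                    continue
                counts[m] = counts.get(m, 0) + 1
    return counts


def assemble(reads: ReadSet, k: int = 31) -> list[Contig]:
    """Unitigs of the pruned de Bruijn graph of the reads.

    ``k`` must be odd, 11..63.  k-mers seen once are dropped when the
    coverage distribution indicates they are errors (max count > 2);
    unitigs are maximal non-branching paths, reported once per
    reverse-complement pair, sorted longest first.
    """
    if k % 2 == 0 or not 11 <= k <= 63:
        raise SequenceError("k must be odd and in 11..63")
    seqs = [s for _id, s, _q in reads.reads if len(s) >= k + 1]
    if not seqs:
        raise SequenceError("no reads to assemble")
    counts = _kmer_counts(seqs, k)
    if counts and max(counts.values()) > 2:
        # singleton error k-mers dominate the distinct-k-mer multiset,
        # so gauge genuine coverage from k-mers seen at least twice; at
        # high coverage errors recur, hence the cutoff scales up to 3
        genuine = [c for c in counts.values() if c >= 2]
        med = float(np.median(genuine)) if genuine else 2.0
        cutoff = max(2, min(3, int(round(0.2 * med))))
        counts = {m: c for m, c in counts.items() if c >= cutoff}
    if not counts:
        raise SequenceError("no k-mers survive pruning")

    # node = (k-1)-mer; edge = k-mer
    def successors(node: str):
        out = []
        for b in "ACGT":
            if node + b in counts:
                out.append(node[1:] + b)
        return out

    def predecessors(node: str):
        out = []
        for b in "ACGT":
            if b + node in counts:
                out.append(b + node[:-1])
        return out

    nodes = set()
    for m in counts:
        nodes.add(m[:-1])
        nodes.add(m[1:])

    def is_branchless(node: str) -> bool:
        return len(successors(node)) == 1 and len(predecessors(node)) == 1

    contigs: list[Contig] = []
    used_edges: set[str] = set()

    def walk(start: str, first_next: str) -> str:
        path = start + first_next[-1]
        used_edges.add(path[-k:])
        node = first_next
        while is_branchless(node):
            nxt = successors(node)[0]
            edge = node + nxt[-1]
            if edge in used_edges:
                break
            used_edges.add(edge)
            path += nxt[-1]
            node = nxt
        return path

    starts = sorted(n for n in nodes if not is_branchless(n))
    for node in starts:
        for nxt in successors(node):
            edge = node + nxt[-1]
            if edge in used_edges:
                continue
            contigs.append(_make_contig(walk(node, nxt), counts, k))
    # isolated cycles (e.g. a clean circular plasmid): no branch nodes
    remaining = sorted(set(counts) - used_edges)
    while remaining:
        edge = remaining[0]
        node0 = edge[:-1]
        contigs.append(_make_contig(walk(node0, edge[1:]), counts, k))
        remaining = sorted(set(counts) - used_edges)

    # deduplicate reverse complements, keep canonical representative
    seen: set[str] = set()
    unique: list[Contig] = []
    for c in sorted(contigs, key=lambda c: (-len(c.sequence), c.sequence)):
        canon = min(c.sequence, _rc(c.sequence))
        if canon in seen:
            continue
        seen.add(canon)
        unique.append(c)
    return unique


def _make_contig(path: str, counts: dict[str, int], k: int) -> Contig:
    cov = [counts[path[i : i + k]] for i in range(len(path) - k + 1)]
    return Contig(sequence=path, coverage=float(sum(cov) / len(cov)))


# ---------------------------------------------------------------------------
# iterative closure
# ---------------------------------------------------------------------------

def detect_closure(contig: str, k: int) -> str | None:
    """Trimmed circular sequence if the contig ends overlap by >= k-1."""
    ov = k - 1
    if len(contig) > 2 * ov and contig[:ov] == contig[-ov:]:
        return contig[:-ov]
    return None


def _orient_like(circle: str, reference: CircularSequence | str, k: int = SEED_K) -> str:
    """Return the orientation of ``circle`` sharing more k-mers with the seed."""
    ref = reference.residues if isinstance(reference, CircularSequence) else reference
    ref_kmers = {ref[i : i + k] for i in range(len(ref) - k + 1)}

    def shared(s: str) -> int:
        return sum(1 for i in range(len(s) - k + 1) if s[i : i + k] in ref_kmers)

    rc = _rc(circle)
    return circle if shared(circle) >= shared(rc) else rc


def iterative_closure(
    reads: ReadSet,
    seed_reference: CircularSequence | str,
    max_rounds: int = 40,
    k: int = 31,
    min_identity: float = 0.90,
    min_cov_frac: float = 0.8,
) -> AssemblyState:
    """recruit -> assemble -> extend loop until circular closure.

    Stops with ``closed=False`` when the recruited set and longest
    contig stop growing for two consecutive rounds, or after
    ``max_rounds``.  The recruited read set is monotone non-decreasing:
    reads once recruited stay in the pool.
    """
    recruited_ids: set[str] = set()
    pool: dict[str, tuple[str, str, str | None]] = {}
    reference = seed_reference
    rounds: list[dict] = []
    stalls = 0
    prev_len = 0
    contigs: list[Contig] = []
    for it in range(1, max_rounds + 1):
        newly = recruit_reads(
            reads, reference, min_identity=min_identity, min_cov_frac=min_cov_frac
        )
        for r in newly.reads:
            pool[r[0]] = r
        recruited_ids = set(pool)
        if not pool:
            rounds.append(
                {"round": it, "recruited": 0, "longest": 0, "closed": False}
            )
            return AssemblyState(it, recruited_ids, [], False, None, rounds)
        contigs = assemble(ReadSet(reads=list(pool.values())), k=k)
        longest = contigs[0]
        circle = detect_closure(longest.sequence, k)
        rounds.append(
            {
                "round": it,
                "recruited": len(pool),
                "longest": len(longest.sequence),
                "closed": circle is not None,
            }
        )
        if circle is not None:
            circle = _orient_like(circle, seed_reference)
            final = CircularSequence(id="assembled", residues=circle)
            return AssemblyState(it, recruited_ids, contigs, True, final, rounds)
        grew = len(longest.sequence) > prev_len or (
            it == 1 or len(pool) > rounds[-2]["recruited"]
        )
        stalls = 0 if grew else stalls + 1
        prev_len = len(longest.sequence)
        if stalls >= 2:
            break
        reference = longest.sequence
    return AssemblyState(
        len(rounds), recruited_ids, contigs, False, None, rounds
    )
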