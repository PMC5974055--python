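"""Gene annotation for small circular replicons.

Covers circular ORF calling (origin-spanning genes included), operon
grouping via overlapping stop/start codons or short intergenic gaps,
cross-plasmid gene-family assignment by reciprocal-best protein
identity, and per-protein statistics (length, isoelectric point, net
charge).

Start codons default to ATG/GTG: in haloarchaea transcripts are largely
leaderless and the great majority initiate at ATG, with GTG apparently
reserved for poorly expressed genes; TTG is excluded by default but can
be passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import (
    CircularSequence,
    Feature,
    SequenceError,
    reverse_complement,
    wrap_position,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_STARTS = ("ATG", "GTG")

# EMBOSS iep pKa values (charge model for pI / net charge)
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class GeneModel:
    """A called CDS with its protein product."""

    feature: Feature
    protein: str
    start_codon: str
    overlaps_previous: bool = False

    @property
    def seq_id(self) -> str:
        return self.feature.seq_id

    @property
    def start(self) -> int:
        return self.feature.start

    @property
    def end(self) -> int:
        return self.feature.end

    @property
    def strand(self) -> str:
        return self.feature.strand


@dataclass
class FamilyAssignment:
    """Gene-family labels per plasmid plus the identity evidence."""

    assignments: dict[str, list[tuple[str, GeneModel]]]
    evidence: dict = field(default_factory=dict)

    def labels(self, plasmid_id: str) -> list[str]:
        return [lab for lab, _ in self.assignments[plasmid_id]]


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

def _strand_to_genome(i: int, strand: str, length: int) -> int:
    """Map 0-based strand-local position to 1-based genome position."""
    if strand == "+":
        return wrap_position(i + 1, length)
    return wrap_position(length - i, length)


def find_orfs(
    seq: CircularSequence,
    min_aa: int = 30,
    starts: tuple[str, ...] = DEFAULT_STARTS,
) -> list[GeneModel]:
    """Call ORFs on both strands, including origin-spanning ones.

    Within one stop-bounded reading frame the longest ORF (5'-most
    start) is reported; nested alternative starts are listed in the
    feature's ``alt_starts`` attribute.  Coordinates follow the package
    convention: ``start..end`` walked forward on the genome yields the
    coding strand after applying ``strand``.
    """
    if min_aa < 1:
        raise SequenceError("min_aa must be >= 1")
    bad = set(starts) - {"ATG", "GTG", "TTG"}
    if bad:
        raise SequenceError(f"unsupported start codons: {sorted(bad)}")
    L = seq.length
    models: list[GeneModel] = []
    for strand in "+-":
        s = seq.residues if strand == "+" else reverse_complement(seq.residues)
        dbl = s + s if seq.is_circular else s
        # group candidate starts by the position of their stop codon
        by_stop: dict[int, list[tuple[int, int]]] = {}
        for p in range(L):
            if dbl[p : p + 3] not in starts:
                continue
            q = p + 3
            while q + 3 <= len(dbl) and q - p <= L:
                if dbl[q : q + 3] in STOP_CODONS:
                    key = q % L if seq.is_circular else q
                    by_stop.setdefault(key, []).append((p, q))
                    break
                q += 3
        for plist in by_stop.values():
            # longest ORF first; ties broken by strand-local start
            plist.sort(key=lambda pq: (-(pq[1] - pq[0]), pq[0]))
            p, q = plist[0]
            n_aa = (q - p) // 3
            if n_aa < min_aa:
                continue  # alternatives are nested, hence shorter
            nt = dbl[p : q]  # excludes the stop codon
            protein = str(Seq(nt).translate(table=11))
            # report ATG/GTG as M per the bacterial/archaeal table
            if protein and nt[:3] in ("GTG", "TTG"):
                protein = "M" + protein[1:]
            g_start = _strand_to_genome(p, strand, L)
            g_stop_end = _strand_to_genome(q + 2, strand, L)
            if strand == "+":
                fstart, fend = g_start, g_stop_end
            else:
                fstart, fend = g_stop_end, g_start
            alt = [
                _strand_to_genome(pp, strand, L)
                for pp, qq in plist[1:]
                if (qq - pp) // 3 >= min_aa
            ]
            attrs = {"n_aa": n_aa}
            if alt:
                attrs["alt_starts"] = ",".join(map(str, alt))
            feat = Feature(
                seq_id=seq.id,
                start=fstart,
                end=fend,
                strand=strand,
                type="CDS",
                attributes=attrs,
            )
            models.append(
                GeneModel(feature=feat, protein=protein, start_codon=nt[:3])
            )
    models.sort(key=lambda m: (m.start, m.end, m.strand))
    return models


# ---------------------------------------------------------------------------
# operons
# ---------------------------------------------------------------------------

def detect_operons(
    genes: list[GeneModel], gap_max: int = 30
) -> list[list[GeneModel]]:
    """Group same-strand neighbours into operon candidates.

    Two consecutive genes on one strand join a group when their
    stop/start codons overlap by >= 1 nt or their intergenic gap is at
    most ``gap_max`` (default 30 nt, the family's average intergenic
    distance in the reverse block).  Overlap additionally sets
    ``overlaps_previous`` on the downstream gene.
    """
    groups: list[list[GeneModel]] = []
    for strand in "+-":
        members = sorted(
            (g for g in genes if g.strand == strand), key=lambda g: g.start
        )
        current: list[GeneModel] = []
        for g in members:
            if not current:
                current = [g]
                continue
            prev = current[-1]
            gap = g.start - prev.end - 1
            overlap = g.start <= prev.end
            if overlap or gap <= gap_max:
                g.overlaps_previous = overlap
                current.append(g)
            else:
                groups.append(current)
                current = [g]
        if current:
            groups.append(current)
    return groups


def select_gene_models(
    genes: list[GeneModel], max_overlap: int = 30
) -> list[GeneModel]:
    """Greedy longest-first non-overlapping gene tiling.

    Random sequence is littered with short spurious ORFs nested inside
    or antisense to real genes; annotation keeps the longest ORFs and
    drops any candidate overlapping an accepted one by more than
    ``max_overlap`` nt (stop/start-overlapping operon junctions stay).
    """
    chosen: list[GeneModel] = []
    for g in sorted(genes, key=lambda g: (-len(g.protein), g.start)):
        ok = True
        for c in chosen:
            ov = min(g.end, c.end) - max(g.start, c.start) + 1
            if ov > max_overlap:
                ok = False
                break
        if ok:
            chosen.append(g)
    chosen.sort(key=lambda g: (g.start, g.end))
    return chosen


# ---------------------------------------------------------------------------
# protein statistics
# ---------------------------------------------------------------------------

def protein_charge(protein: str, ph: float) -> float:
    """Net charge at the given pH (Henderson–Hasselbalch, EMBOSS pKa)."""
    unknown = set(protein) - AA20
    if unknown:
        raise SequenceError(f"unknown residues: {sorted(unknown)}")
    if not protein:
        raise SequenceError("empty protein")
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa, pka in PKA_POSITIVE.items():
        if aa == "Nterm":
            continue
        charge += protein.count(aa) / (1.0 + 10 ** (ph - pka))
    for aa, pka in PKA_NEGATIVE.items():
        if aa == "Cterm":
            continue
        charge -= protein.count(aa) / (1.0 + 10 ** (pka - ph))
    return charge


def protein_stats(protein: str, tol: float = 1e-4) -> tuple[int, float, float]:
    """(length aa, isoelectric point, net charge at pH 7).

    The pI is the bisection root of the monotone-decreasing
    Henderson–Hasselbalch net-charge function.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if protein_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return len(protein), 0.5 * (lo + hi), protein_charge(protein, 7.0)


# ---------------------------------------------------------------------------
# protein identity
# ---------------------------------------------------------------------------

def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # gap of length L costs 11 + L (BLAST-style affine convention)
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def aligned_identity(row_a: str, row_b: str, trim_terminal: bool = True) -> float:
    """Percent identical columns over alignment columns.

    Internal gap columns count in the denominator; terminal overhangs
    (end runs where one row is all gaps) are excluded when
    ``trim_terminal``.
    """
    lo, hi = 0, len(row_a)
    if trim_terminal:
        while lo < hi and _is_overhang_col(row_a, row_b, lo):
            lo += 1
        while hi > lo and _is_overhang_col(row_a, row_b, hi - 1):
            hi -= 1
    if hi <= lo:
        return 0.0
    n_id = sum(
        1 for i in range(lo, hi) if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    return 100.0 * n_id / (hi - lo)


def _is_overhang_col(row_a: str, row_b: str, i: int) -> bool:
    return row_a[i] == "-" or row_b[i] == "-"


def pairwise_protein_identity(a: str, b: str) -> float:
    """Global BLOSUM62 identity percent between two proteins.

    Denominator = alignment columns between the first and last aligned
    residue pair (internal gaps included, terminal overhangs excluded).
    """
    if not a or not b:
        raise SequenceError("empty protein")
    aligner = _protein_aligner()
    aln = aligner.align(a, b)[0]
    row_a, row_b = _alignment_rows(aln)
    return aligned_identity(row_a, row_b)


def _alignment_rows(aln) -> tuple[str, str]:
    """Gapped row strings from a Bio.Align.Alignment."""
    return str(aln[0]), str(aln[1])


# ---------------------------------------------------------------------------
# family assignment
# ---------------------------------------------------------------------------

def assign_families(
    plasmid_genes: dict[str, list[GeneModel]],
    forward_order: tuple[str, ...] = ("F1", "F2", "F3", "F3.1", "F3.2"),
    reverse_order: tuple[str, ...] = ("R7", "R6", "R5", "R4"),
    min_identity: float = 30.0,
    min_coverage: float = 0.6,
    tile: bool = True,
    synteny_merge_tol: float = 0.04,
) -> FamilyAssignment:
    """Cluster genes across plasmids and label them by synteny.

    Each plasmid's gene list is first reduced to a longest-first
    non-overlapping tiling (unless ``tile=False``), discarding the
    spurious nested/antisense ORFs of random sequence.  Genes from
    different plasmids are then linked when each is the other's
    reciprocal best match at >= ``min_identity`` percent over
    >= ``min_coverage`` of the shorter protein; connected components
    form families.  Components spanning at least half the plasmids are
    ordered by mean fractional start position and labeled
    forward-strand families left-to-right (F1, F2, F3, ...) and
    reverse-strand families left-to-right (R7, R6, R5, R4) to match
    the family's gene layout.  Everything else is ``other``.
    """
    if len(plasmid_genes) < 2:
        raise SequenceError("family assignment needs >= 2 plasmids")
    if tile:
        plasmid_genes = {
            pid: select_gene_models(gl) for pid, gl in plasmid_genes.items()
        }
    plasmids = sorted(plasmid_genes)
    nodes = [
        (pid, idx) for pid in plasmids for idx in range(len(plasmid_genes[pid]))
    ]
    ident: dict[tuple, float] = {}

    def gene(node):
        return plasmid_genes[node[0]][node[1]]

    # pairwise identities across plasmids
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if u[0] == v[0]:
                continue
            pa, pb = gene(u).protein, gene(v).protein
            if min(len(pa), len(pb)) < min_coverage * max(len(pa), len(pb)):
                continue
            pid = pairwise_protein_identity(pa, pb)
            if pid >= min_identity:
                ident[(u, v)] = ident[(v, u)] = pid

    # reciprocal best hits, deterministic tie-break by lower coordinate
    best: dict[tuple, dict[str, tuple]] = {}
    ties: list[tuple] = []
    for u in nodes:
        best[u] = {}
        for other_pid in plasmids:
            if other_pid == u[0]:
                continue
            cands = [
                v
                for v in nodes
                if v[0] == other_pid and (u, v) in ident
            ]
            if not cands:
                continue
            top = max(ident[(u, v)] for v in cands)
            winners = [v for v in cands if ident[(u, v)] == top]
            winners.sort(key=lambda v: gene(v).start)
            if len(winners) > 1:
                ties.append((u, winners[0]))
            best[u][other_pid] = winners[0]

    # union-find over reciprocal best pairs
    parent = {u: u for u in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for u in nodes:
        for other_pid, v in best[u].items():
            if best.get(v, {}).get(u[0]) == u:
                union(u, v)

    clusters: dict[tuple, list[tuple]] = {}
    for u in nodes:
        clusters.setdefault(find(u), []).append(u)

    def mean_fraction(members):
        return _mean_fraction(members, gene, plasmid_genes)

    # synteny completion: the family is collinear, so clusters that
    # fragmented because distant relatives fall below the identity
    # threshold are re-joined when they occupy the same relative
    # position on the same strand, with compatible protein lengths, in
    # disjoint plasmid sets; closest length match merges first
    def mean_len(members):
        return sum(len(gene(m).protein) for m in members) / len(members)

    import math

    while True:
        reps = sorted(clusters)
        candidates = []
        for i, r1 in enumerate(reps):
            for r2 in reps[i + 1 :]:
                c1, c2 = clusters[r1], clusters[r2]
                if {m[0] for m in c1} & {m[0] for m in c2}:
                    continue
                if gene(c1[0]).strand != gene(c2[0]).strand:
                    continue
                df = abs(mean_fraction(c1) - mean_fraction(c2))
                if df > synteny_merge_tol:
                    continue
                l1, l2 = mean_len(c1), mean_len(c2)
                if min(l1, l2) < min_coverage * max(l1, l2):
                    continue
                candidates.append((abs(math.log(l1 / l2)), df, r1, r2))
        if not candidates:
            break
        _, _, r1, r2 = min(candidates)
        clusters[r1] = clusters[r1] + clusters.pop(r2)

    min_span = max(2, (len(plasmids) + 1) // 2)
    multi = [
        c for c in clusters.values() if len({m[0] for m in c}) >= min_span
    ]

    def total_aa(members):
        return sum(len(gene(m).protein) for m in members)

    # major labels (no dot) go to the largest clusters by total protein
    # content, ordered along the plasmid — short conserved junk ORFs
    # cannot displace a real family this way; minor labels (F3.1-style)
    # go positionally to what remains downstream of the majors
    label_of: dict[tuple, str] = {}
    for labels, strand in ((forward_order, "+"), (reverse_order, "-")):
        majors = [l for l in labels if "." not in l]
        minors = [l for l in labels if "." in l]
        cands = [c for c in multi if gene(c[0]).strand == strand]
        chosen = sorted(cands, key=total_aa, reverse=True)[: len(majors)]
        chosen.sort(key=mean_fraction)
        for lab, comp in zip(majors, chosen):
            for m in comp:
                label_of[m] = lab
        if minors and chosen:
            anchor = mean_fraction(chosen[-1])
            rest = sorted(
                (c for c in cands if c not in chosen and mean_fraction(c) > anchor),
                key=mean_fraction,
            )
            for lab, comp in zip(minors, rest):
                for m in comp:
                    label_of[m] = lab

    assignments: dict[str, list[tuple[str, GeneModel]]] = {}
    for pid in plasmids:
        labeled = []
        seen: set[str] = set()
        for idx, g in enumerate(plasmid_genes[pid]):
            lab = label_of.get((pid, idx), "other")
            if lab != "other" and lab in seen:
                lab = "other"
            seen.add(lab)
            g.feature = _with_family(g.feature, lab)
            labeled.append((lab, g))
        assignments[pid] = labeled

    evidence = {
        "identity": {
            (f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}"): w
            for (u, v), w in ident.items()
        },
        "ties": [(f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}") for u, v in ties],
    }
    return FamilyAssignment(assignments=assignments, evidence=evidence)


def _mean_fraction(members, gene, plasmid_genes) -> float:
    """Mean fractional start position of a cluster's genes.

    Plasmid length is proxied by the max gene end on that plasmid."""
    fs = []
    for m in members:
        g = gene(m)
        pl = max(x.end for x in plasmid_genes[m[0]])
        fs.append(g.start / pl)
    return sum(fs) / len(fs)


def _with_family(feature: Feature, family: str) -> Feature:
    from dataclasses import replace

    return replace(feature, family=family)
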