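"""Synthetic plasmid families with known ground truth.

Generates ~6-kb circular plasmids that emulate the architecture of the
PL6 family of *Haloquadratum*: a high-GC forward block of three genes
with overlapping stop/start codons (an operon), an AT-rich central
intergenic region, a reverse block of four closely spaced genes, planted
regulatory elements (an oppositely oriented promoter pair inside a
conserved intergenic sequence, an RBS four nt upstream of the third
forward gene, an inverted repeat proximal to the first reverse gene,
five conserved intergenic islands) and a -1 frameshift signature
(slippery heptamer plus downstream hairpin) inside one reverse gene.

Families are evolved along a guide tree with region-specific
Jukes–Cantor substitution (two divergence tiers mirroring the observed
~84% forward-block vs ~54% remainder identities), indels restricted to
unprotected intergenic sequence, and optional lineage-specific events
(an AT-rich methylase-like gene insertion; a single-base deletion
creating a premature stop in one reverse gene).

Every generator is deterministic under a fixed seed, and every planted
coordinate is recorded in a :class:`SyntheticTruth` ledger that tests
use as the oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import CircularSequence, SequenceError

STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))

# overlapping, oppositely oriented promoter pair: the forward 12-mer
# matches SRnnRnnnTTWW at offset 0 and the reverse complement of the
# 12-mer at offset 10 matches it on the minus strand
PROMOTER_PAIR = "GAACGAAATTATAATTTCGTTC"
PROMOTER_FWD = PROMOTER_PAIR[:12]
RBS_SEQ = "GGAGGCGA"
SLIPPERY = "AAAAAAC"

DEFAULT_GENE_AA = {
    "F1": 99, "F2": 297, "F3": 570,
    "R7": 109, "R6": 278, "R5": 214, "R4": 115,
}

DEFAULT_TREE = {
    # ((A,B),(C,D),E) with sister pairs less diverged than the rest
    "topology": (("A", "B"), ("C", "D"), "E"),
    "x": 0.35, "y": 0.30, "z": 0.65,
}


@dataclass
class FamilyParams:
    """Generator settings; the defaults are the study conditions."""

    n_plasmids: int = 5
    gene_aa: dict = field(default_factory=lambda: dict(DEFAULT_GENE_AA))
    gc_forward: float = 0.55
    gc_center: float = 0.42
    gc_reverse: float = 0.51
    origin_intergenic: int = 260   # CIS I/II island region before F1
    center_intergenic: int = 650   # AT-rich gap between F3 and R7
    reverse_gap: int = 30          # intergenic spacing in the R block
    terminal_intergenic: int = 100  # R4-proximal region back to the origin
    divergence_forward: float = 0.16   # expected pairwise distance, F block
    divergence_rest: float = 0.46      # central + reverse block
    indel_rate: float = 5e-4           # per intergenic site per unit branch
    indel_mean_len: float = 3.0
    plant_elements: bool = True
    insertion_lineage: str | None = None   # leaf receiving the methylase gene
    pseudogene_lineage: str | None = None  # leaf receiving the R6 deletion

    def scaled(self, factor: float) -> "FamilyParams":
        """A proportionally smaller family for fast repeated simulation."""
        gene_aa = {
            k: max(52, int(v * factor)) for k, v in self.gene_aa.items()
        }
        return replace(
            self,
            gene_aa=gene_aa,
            origin_intergenic=max(120, int(self.origin_intergenic * factor)),
            center_intergenic=max(120, int(self.center_intergenic * factor)),
            terminal_intergenic=max(60, int(self.terminal_intergenic * factor)),
        )


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one generated ancestor or family."""

    genes: dict = field(default_factory=dict)      # per seq: label -> (start, end, strand)
    elements: dict = field(default_factory=dict)   # per seq: name -> (start, end, strand)
    regions: dict = field(default_factory=dict)    # per seq: name -> (start, end)
    tree_newick: str | None = None
    realized_identity: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)     # lineage-specific events


@dataclass
class ReadSet:
    """Shotgun reads: (id, sequence, qualities or None)."""

    reads: list[tuple[str, str, str | None]]
    source: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _intergenic(rng: np.random.Generator, n: int, gc: float) -> str:
    """Random intergenic sequence without long stop-free stretches.

    Pure i.i.d. sequence occasionally contains ORF-sized stop-free runs
    in some frame; real intergenic sequence between the plasmids' dense
    gene blocks does not.  Any run of >= 60 nt without a stop codon (in
    any of the six frames) gets a stop injected at its center.
    """
    if n < 70:
        return _random_bases(rng, n, gc)
    # stop-salting injects AT-rich codons, so retune the sampling GC
    # until the salted product lands close to the target (the study's
    # regional GC bands are only ~2 points wide, e.g. 41-43%)
    t = gc
    best, best_err = None, 1.0
    for _ in range(20):
        out = _salt_stops(rng, n, t)
        got = (out.count("G") + out.count("C")) / n
        err = abs(got - gc)
        if err < best_err:
            best, best_err = out, err
        if err <= 0.01:
            return out
        t = min(0.95, max(0.05, t + (gc - got)))
    return best


def _salt_stops(rng: np.random.Generator, n: int, gc: float) -> str:
    s = list(_random_bases(rng, n, gc))
    for _ in range(30):
        text = "".join(s)
        rc = text.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        worst = None
        for strand_seq, minus in ((text, False), (rc, True)):
            for frame in range(3):
                run_start = frame
                p = frame
                while p + 3 <= n:
                    if strand_seq[p : p + 3] in STOPS:
                        run_start = p + 3
                    elif p + 3 - run_start >= 60:
                        worst = (minus, run_start, p + 3)
                        break
                    p += 3
                if worst:
                    break
            if worst:
                break
        if worst is None:
            return "".join(s)
        minus, a, b = worst
        mid = (a + b) // 2
        mid -= (mid - a) % 3
        if minus:
            # position in forward coordinates; stop on minus strand = TTA
            fa = n - (mid + 3)
            s[fa : fa + 3] = list("TTA")
        else:
            s[mid : mid + 3] = list("TAA")
    return "".join(s)


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Stop-free random codons with base composition near ``gc``."""
    out = []
    while len(out) < n_codons:
        cod = _random_bases(rng, 3, gc)
        if cod not in STOPS:
            out.append(cod)
    return "".join(out)


def _tune_gc(rng: np.random.Generator, make, target: float, tol: float = 0.02):
    """Resample with a corrected target until GC lands within ``tol``;
    falls back to the closest candidate seen."""
    t = target
    best, best_err = None, 1.0
    for _ in range(15):
        s = make(t)
        gc = (s.count("G") + s.count("C")) / len(s)
        err = abs(gc - target)
        if err < best_err:
            best, best_err = s, err
        if err <= tol:
            return s
        t = min(0.95, max(0.05, t + (target - gc)))
    return best


def _gene_nt(rng: np.random.Generator, n_aa: int, gc: float) -> str:
    """ATG + stop-free codons + TGA stop; GC within ~2 points of target."""
    body = _tune_gc(
        rng, lambda t: _random_codons(rng, n_aa - 1, t), gc
    )
    return "ATG" + body + "TGA"


def _guard_next_frame(gene_nt: str) -> str:
    """Rewrite two codons near the gene's 3' end to GCT+AAC.

    In the overlapping-gene layout the next gene's reading frame is
    offset by two within this gene, so the T|AA straddling the codon
    junction is an in-frame stop for the downstream gene — it guards
    the downstream start from upstream ORF extension without changing
    this gene's own frame (Ala-Asn is stop-free).
    """
    n = len(gene_nt) // 3
    lo = 3 * (n - 8)
    out = gene_nt[:lo] + "GCTAAC" + gene_nt[lo + 6 :]
    # final body codon ends in C so the x+TG straddling the stop/start
    # junction cannot itself read as an ATG/GTG start
    return out[: 3 * (n - 2)] + "GCC" + out[3 * (n - 1) :]


def _hairpin_insert(rng: np.random.Generator) -> str:
    """A strong stem-loop whose sequence is stop-free in every frame."""
    # 10-bp GC stem + 4-nt loop; checked below for frame safety
    for _ in range(100):
        arm = "".join(rng.choice(list("GC"), size=10))
        loop = "GCAA"
        rc = arm.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        s = arm + loop + rc
        if not any(s[i : i + 3] in STOPS for i in range(len(s) - 2)):
            return s
    raise SequenceError("could not build a frame-safe hairpin")


def generate_ancestor(
    params: FamilyParams | None = None, seed: int = 0
) -> tuple[CircularSequence, SyntheticTruth]:
    """Construct the family ancestor with all planted elements.

    Layout (1-based, forward):  origin intergenic (CIS I with the
    overlapping promoter pair, CIS II) -> F1 -> F2 -> F3 (stop/start
    overlaps, RBS 4 nt upstream of the F3 start) -> AT-rich central
    intergenic (CIS III, IV) -> R7..R4 on the reverse strand (CIS V in
    the R6/R7 gap, slippery site + hairpin inside R6, inverted repeat
    16–25 nt upstream of the R4 start) -> back to the origin.
    """
    params = params or FamilyParams()
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    genes: dict[str, tuple[int, int, str]] = {}
    elements: dict[str, tuple[int, int, str]] = {}
    regions: dict[str, tuple[int, int]] = {}

    parts: list[str] = []
    pos = 0  # 0-based running length

    def emit(s: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(s)
        start = pos + 1
        pos += len(s)
        return start, pos

    # --- origin intergenic with CIS II then CIS I; the CIS I promoter
    # pair is placed so the forward member's center sits ~26 nt
    # upstream of the F1 start (haloarchaeal promoters center -27/-28)
    gc_i = params.gc_forward
    emit(_intergenic(rng, 30, gc_i))
    if params.plant_elements:
        s, e = emit(_random_bases(rng, 18, 0.5))
        elements["CIS_II"] = (s, e, "+")
        filler = params.origin_intergenic - pos - 35
        emit(_intergenic(rng, filler, gc_i))
        core = (
            _random_bases(rng, 4, 0.5)
            + PROMOTER_PAIR
            + _random_bases(rng, 4, 0.5)
        )
        s, e = emit(core)
        elements["CIS_I"] = (s, e, "+")
        p0 = s + 4
        elements["promoter_fwd"] = (p0, p0 + 11, "+")
        elements["promoter_rev"] = (p0 + 10, p0 + 21, "-")
        emit(_random_bases(rng, 2, gc_i))
    else:
        emit(_intergenic(rng, params.origin_intergenic - 33, gc_i))
    # in-frame stop guarding the F1 start, so the longest-ORF convention
    # recovers exactly the planted gene
    s, e = emit("TAA")
    elements["_guard_F1"] = (s, e, "+")
    regions["origin_intergenic"] = (1, pos)

    # --- forward operon F1 -> F2 -> F3 with overlapping stop/starts.
    # Each gene ends with TGA; the next gene's ATG reuses the stop's
    # final A (the classic TGATG junction), so we emit gene[1:].
    f_start = pos + 1
    f1 = _guard_next_frame(_gene_nt(rng, params.gene_aa["F1"], params.gc_forward))
    s, e = emit(f1)
    genes["F1"] = (s, e, "+")
    # covers the planted in-frame stop and the junction codon whose
    # final base must stay non-A/G (no start immediately upstream)
    elements["_guard_F2"] = (e - 21, e - 3, "+")
    f2 = _guard_next_frame(_gene_nt(rng, params.gene_aa["F2"], params.gc_forward))
    s, e = emit(f2[1:])
    genes["F2"] = (e - len(f2) + 1, e, "+")
    elements["_guard_F3"] = (e - 21, e - 3, "+")
    f3 = _gene_nt(rng, params.gene_aa["F3"], params.gc_forward)
    s3, e3 = emit(f3[1:])
    genes["F3"] = (e3 - len(f3) + 1, e3, "+")
    regions["F_block"] = (f_start, e3)

    # rewrite: plant RBS 4 nt upstream of the F3 start, inside F2
    if params.plant_elements:
        seq_so_far = "".join(parts)
        f3_s = genes["F3"][0]
        rbs_end = f3_s - 5      # 4 intervening nt
        rbs_start = rbs_end - len(RBS_SEQ) + 1
        seq_list = list(seq_so_far)
        seq_list[rbs_start - 1 : rbs_end] = list(RBS_SEQ)
        # frame safety inside F2: the RBS itself is stop-free in every
        # phase, but its first G can complete a TAG with the two
        # preceding bases; repair any boundary stop at its first base
        f2_s = genes["F2"][0]
        for i in range(f2_s - 1 + 3, genes["F2"][1] - 4, 3):
            if "".join(seq_list[i : i + 3]) in STOPS:
                seq_list[i] = "C"
        patched = "".join(seq_list)
        parts = [patched]
        elements["RBS_F3"] = (rbs_start, rbs_end, "+")

    # --- AT-rich central intergenic with CIS III and IV
    c_start = pos + 1
    third = params.center_intergenic // 3
    emit(_intergenic(rng, third, params.gc_center))
    if params.plant_elements:
        s, e = emit(_random_bases(rng, 16, 0.4))
        elements["CIS_III"] = (s, e, "+")
    emit(_intergenic(rng, third, params.gc_center))
    if params.plant_elements:
        s, e = emit(_random_bases(rng, 14, 0.4))
        elements["CIS_IV"] = (s, e, "+")
    emit(_intergenic(rng, third, params.gc_center))
    regions["center"] = (c_start, pos)

    # --- reverse block R7, R6, R5, R4 (left to right; reverse strand)
    r_start = pos + 1

    def emit_reverse_gene(label: str) -> None:
        n_aa = params.gene_aa[label]
        fwd = _gene_nt(rng, n_aa, params.gc_reverse)
        if label == "R6" and params.plant_elements:
            fwd = _plant_frameshift_signal(rng, fwd, elements_out)
        rc = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        s, e = emit(rc)
        genes[label] = (s, e, "-")
        if label == "R6" and params.plant_elements and elements_out:
            # map mRNA-local element coords onto genome (reverse strand)
            for name, (ls, le) in elements_out.items():
                elements[name] = (e - le + 1, e - ls + 1, "-")

    def emit_reverse_guard(label: str) -> None:
        # TTA immediately after a reverse gene's end is the in-frame
        # (reverse-strand) stop guarding that gene's start codon
        s, e = emit("TTA")
        elements[f"_guard_{label}"] = (s, e, "+")

    elements_out: dict[str, tuple[int, int]] = {}
    emit_reverse_gene("R7")
    emit_reverse_guard("R7")
    if params.plant_elements:
        emit(_intergenic(rng, 7, params.gc_reverse))
        s, e = emit(_random_bases(rng, 16, 0.45))
        elements["CIS_V"] = (s, e, "+")
        emit(_intergenic(rng, 10, params.gc_reverse))
    else:
        emit(_intergenic(rng, params.reverse_gap - 3, params.gc_reverse))
    emit_reverse_gene("R6")
    emit_reverse_guard("R6")
    emit(_intergenic(rng, params.reverse_gap - 3, params.gc_reverse))
    emit_reverse_gene("R5")
    emit_reverse_guard("R5")
    emit(_intergenic(rng, params.reverse_gap - 3, params.gc_reverse))
    emit_reverse_gene("R4")
    regions["R_block"] = (r_start, pos)

    # --- R4-proximal inverted repeat, centered -16..-25 upstream of R4
    # upstream of a reverse-strand gene = higher forward coordinates
    tail_len = params.terminal_intergenic
    tail = list(_intergenic(rng, tail_len, params.gc_reverse))
    tail[0:3] = list("TTA")  # reverse-frame stop guarding the R4 start
    elements["_guard_R4"] = (pos + 1, pos + 3, "+")
    if params.plant_elements:
        arm = "TTAAGC"  # 4-nt AT motif inside a 6-nt arm
        rc_arm = arm.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        loop = "ACG"
        ir = arm + loop + rc_arm
        # R4 start (5' on reverse strand) is at genome position genes
        # ["R4"][1]; center the IR ~20 nt upstream of it
        offset = 20 - len(ir) // 2  # tail-local start so center ≈ +20
        tail[offset : offset + len(ir)] = list(ir)
        ir_start = pos + 1 + offset
        elements["R4_PIR"] = (ir_start, ir_start + len(ir) - 1, "+")
    emit("".join(tail))

    residues = "".join(parts)
    seq = CircularSequence(id="ancestor", residues=residues)
    truth.genes["ancestor"] = genes
    truth.elements["ancestor"] = elements
    truth.regions["ancestor"] = regions
    return seq, truth


def _plant_frameshift_signal(
    rng: np.random.Generator, gene_fwd: str, out: dict
) -> str:
    """Insert slippery heptamer + hairpin into a gene's mRNA (local coords).

    ``gene_fwd`` is the coding (mRNA) sequence; the heptamer is placed
    at a codon boundary phase 2 (X_XXY_YYZ), the hairpin 5 nt further
    downstream.  Records mRNA-local 1-based intervals in ``out``.
    """
    hp = _hairpin_insert(rng)
    # place around 60% into the gene, at phase p % 3 == 2 (0-based)
    target = int(len(gene_fwd) * 0.6)
    p = target - (target % 3) + 2
    gap = "GCAGC"  # 5 nt, stop-free in frame context checked below
    block = SLIPPERY + gap + hp
    for shift in range(0, 60, 3):
        q = p + shift
        cand = gene_fwd[:q] + block + gene_fwd[q + len(block):]
        if len(cand) != len(gene_fwd):
            break
        inner = cand[3:-3]
        if not any(inner[i : i + 3] in STOPS for i in range(0, len(inner) - 2, 3)):
            out["slippery"] = (q + 1, q + 7)
            hp_s = q + 7 + len(gap) + 1
            out["hairpin"] = (hp_s, hp_s + len(hp) - 1)
            return cand
    raise SequenceError("could not plant a frame-safe slippery site")


# ---------------------------------------------------------------------------
# family evolution
# ---------------------------------------------------------------------------

def _default_tree(n: int) -> list[tuple[str, float, list]]:
    """Nested (name, branch, children) guide tree for up to 5 leaves."""
    x, y, z = DEFAULT_TREE["x"], DEFAULT_TREE["y"], DEFAULT_TREE["z"]
    leaves = ["A", "B", "C", "D", "E"][:n]
    if n == 2:
        return [("A", 0.5, []), ("B", 0.5, [])]
    if n == 3:
        return [("A", x, []), ("B", x, []), ("C", z, [])]
    if n == 4:
        return [
            ("", y, [("A", x, []), ("B", x, [])]),
            ("", y, [("C", x, []), ("D", x, [])]),
        ]
    return [
        ("", y, [("A", x, []), ("B", x, [])]),
        ("", y, [("C", x, []), ("D", x, [])]),
        ("E", z, []),
    ]


def _tree_newick(nodes: list) -> str:
    def fmt(node):
        name, bl, children = node
        if not children:
            return f"{name}:{bl}"
        return f"({','.join(fmt(c) for c in children)}):{bl}"

    return f"({','.join(fmt(n) for n in nodes)});"


def _mean_pairwise_path(nodes: list) -> float:
    # depth of each leaf + pairwise MRCA arithmetic on this tiny tree
    leaf_paths: dict[str, float] = {}

    def walk(node, acc, trail):
        name, bl, children = node
        if not children:
            leaf_paths[name] = acc + bl
            trails[name] = trail + [(id(node), bl)]
            return
        for c in children:
            walk(c, acc + bl, trail + [(id(node), bl)])

    trails: dict[str, list] = {}
    for n in nodes:
        walk(n, 0.0, [])
    labels = sorted(leaf_paths)
    total, count = 0.0, 0
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            shared = 0.0
            sa = {tid: bl for tid, bl in trails[a]}
            for tid, bl in trails[b]:
                if tid in sa:
                    shared += bl
            total += leaf_paths[a] + leaf_paths[b] - 2 * shared
            count += 1
    return total / count


def _jc_rate(p_observed: float) -> float:
    """Substitution distance giving the target observed p-distance."""
    return -0.75 * math.log(1 - 4 * p_observed / 3)


class _Lineage:
    """A sequence plus the map from ancestor positions to its own."""

    def __init__(self, residues: str):
        self.residues = residues
        self.anc_map = np.arange(len(residues), dtype=np.int64)  # anc->self

    def clone(self) -> "_Lineage":
        c = _Lineage(self.residues)
        c.anc_map = self.anc_map.copy()
        return c

    def map_interval(self, start: int, end: int) -> tuple[int, int] | None:
        """1-based ancestor interval -> 1-based own interval (or None)."""
        idx = self.anc_map[start - 1 : end]
        idx = idx[idx >= 0]
        if len(idx) == 0:
            return None
        return int(idx.min()) + 1, int(idx.max()) + 1


def _evolve_branch(
    lin: _Lineage,
    rng: np.random.Generator,
    branch: float,
    params: FamilyParams,
    anc_truth: SyntheticTruth,
) -> None:
    """Mutate a lineage in place along one branch."""
    regions = anc_truth.regions["ancestor"]
    genes = anc_truth.genes["ancestor"]
    elements = anc_truth.elements["ancestor"]
    L = len(lin.residues)
    seq = np.frombuffer(lin.residues.encode(), dtype=np.uint8).copy()

    # per-site substitution probability from region tier
    p_site = np.full(L, np.nan)
    d_f = _jc_rate(params.divergence_forward)
    d_r = _jc_rate(params.divergence_rest)
    own_region = {}
    for name, (s, e) in regions.items():
        m = lin.map_interval(s, e)
        if m:
            own_region[name] = m
    for name, m in own_region.items():
        tier = d_f if name in ("origin_intergenic", "F_block") else d_r
        p_site[m[0] - 1 : m[1]] = tier * branch
    p_site = np.nan_to_num(p_site, nan=d_r * branch)

    protected = np.zeros(L, dtype=bool)
    for name, (s, e, _strand) in elements.items():
        m = lin.map_interval(s, e)
        if m:
            protected[m[0] - 1 : m[1]] = True
    gene_spans = []
    for label, (s, e, strand) in genes.items():
        m = lin.map_interval(s, e)
        if m:
            gene_spans.append((label, m[0], m[1], strand))
            # protect start and stop codons (and thus the overlaps)
            protected[m[0] - 1 : m[0] + 2] = True
            protected[m[1] - 3 : m[1]] = True

    # substitutions
    hit = rng.random(L) < p_site
    hit &= ~protected
    for i in np.nonzero(hit)[0]:
        old = chr(seq[i])
        choices = [b for b in "ACGT" if b != old]
        seq[i] = ord(choices[rng.integers(3)])

    # revert substitutions that created in-frame stops inside genes
    text = seq.tobytes().decode()
    chars = list(text)
    orig = lin.residues
    for label, s, e, strand in gene_spans:
        sub = "".join(chars[s - 1 : e])
        mrna = sub if strand == "+" else _rc(sub)
        for c in range(1, len(mrna) // 3 - 1):
            if mrna[3 * c : 3 * c + 3] in STOPS:
                # revert the three codon positions to the parent bases
                if strand == "+":
                    lo = s - 1 + 3 * c
                    chars[lo : lo + 3] = list(orig[lo : lo + 3])
                else:
                    hi = e - 3 * c
                    chars[hi - 3 : hi] = list(orig[hi - 3 : hi])
    mutated = "".join(chars)

    # indels in unprotected intergenic sequence only; masks are
    # recomputed from the ancestor ledger after every event because
    # each indel shifts downstream coordinates
    lin.residues = mutated
    anc_map = lin.anc_map.copy()

    def free_positions() -> np.ndarray:
        Lc = len(lin.residues)
        keep = np.ones(Lc, dtype=bool)
        for coords in list(genes.values()) + list(elements.values()):
            s, e = coords[0], coords[1]
            m = lin.map_interval(s, e)
            if m:
                # pad by the max deletion span so a deletion starting
                # just left of a feature cannot eat into it
                keep[max(0, m[0] - 7) : min(Lc, m[1] + 6)] = False
        return np.nonzero(keep)[0]

    candidates = free_positions()
    n_events = rng.poisson(params.indel_rate * len(candidates) * branch)
    for _ in range(n_events):
        candidates = free_positions()
        if not len(candidates):
            break
        x = int(rng.choice(candidates))
        length = int(min(rng.geometric(1.0 / params.indel_mean_len), 6))
        if rng.random() < 0.5:  # deletion
            lin.residues = lin.residues[:x] + lin.residues[x + length :]
            lost = (anc_map >= x) & (anc_map < x + length)
            anc_map[lost] = -1
            anc_map[anc_map >= x + length] -= length
        else:  # insertion
            ins = _random_bases(rng, length, 0.5)
            lin.residues = lin.residues[:x] + ins + lin.residues[x:]
            anc_map[anc_map >= x] += length
        lin.anc_map = anc_map

    lin.anc_map = anc_map


def _rc(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def evolve_family(
    ancestor: CircularSequence,
    anc_truth: SyntheticTruth,
    params: FamilyParams | None = None,
    seed: int = 0,
) -> tuple[list[CircularSequence], SyntheticTruth]:
    """Evolve the ancestor into a family along the guide tree.

    Region-specific Jukes–Cantor substitutions reproduce the two
    divergence tiers; planted elements and start/stop codons are
    protected; substitutions creating in-frame stops are reverted so
    the gene complement survives.  Lineage-specific events (methylase
    insertion, R6 single-base deletion) are applied to the requested
    leaves and recorded in the truth ledger.
    """
    params = params or FamilyParams()
    rng = np.random.default_rng(seed)
    nodes = _default_tree(params.n_plasmids)
    truth = SyntheticTruth(
        genes=dict(anc_truth.genes),
        elements=dict(anc_truth.elements),
        regions=dict(anc_truth.regions),
        tree_newick=_tree_newick(nodes),
    )
    norm = _mean_pairwise_path(nodes)

    leaves: dict[str, _Lineage] = {}

    def walk(node, lin: _Lineage):
        name, bl, children = node
        child_lin = lin.clone()
        _evolve_branch(child_lin, rng, bl / norm, params, anc_truth)
        if not children:
            leaves[name] = child_lin
        for c in children:
            walk(c, child_lin)

    root = _Lineage(ancestor.residues)
    for n in nodes:
        walk(n, root)

    seqs: list[CircularSequence] = []
    anc_genes = anc_truth.genes["ancestor"]
    anc_elems = anc_truth.elements["ancestor"]
    anc_regions = anc_truth.regions["ancestor"]
    for name in sorted(leaves):
        lin = leaves[name]
        # lineage-specific events
        if params.insertion_lineage == name:
            _apply_insertion(lin, rng, params, anc_regions, truth, name)
        if params.pseudogene_lineage == name:
            _apply_r6_deletion(lin, rng, anc_genes, anc_elems, truth, name)
        pid = f"P_{name}"
        seqs.append(CircularSequence(id=pid, residues=lin.residues))
        truth.genes[pid] = {
            lab: (*m, strand)
            for lab, (s, e, strand) in anc_genes.items()
            if (m := lin.map_interval(s, e))
        }
        truth.elements[pid] = {
            nm: (*m, strand)
            for nm, (s, e, strand) in anc_elems.items()
            if (m := lin.map_interval(s, e))
        }
        truth.regions[pid] = {
            nm: m
            for nm, (s, e) in anc_regions.items()
            if (m := lin.map_interval(s, e))
        }

    # realized pairwise identity over shared ancestor positions
    names = sorted(leaves)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            la, lb = leaves[a], leaves[b]
            ok = (la.anc_map >= 0) & (lb.anc_map >= 0)
            xa = np.frombuffer(la.residues.encode(), dtype=np.uint8)
            xb = np.frombuffer(lb.residues.encode(), dtype=np.uint8)
            same = xa[la.anc_map[ok]] == xb[lb.anc_map[ok]]
            truth.realized_identity[(f"P_{a}", f"P_{b}")] = float(same.mean())
    return seqs, truth


def _apply_insertion(lin, rng, params, anc_regions, truth, name):
    """Insert an AT-rich methylase-like gene into the central region."""
    m = lin.map_interval(*anc_regions["center"])
    if m is None:
        return
    n_aa = max(60, int(params.gene_aa["F2"] * 0.8))
    gene = _gene_nt(rng, n_aa, 0.38)
    x = (m[0] + m[1]) // 2
    lin.residues = lin.residues[: x - 1] + gene + lin.residues[x - 1 :]
    lin.anc_map = np.where(
        lin.anc_map >= x - 1, lin.anc_map + len(gene), lin.anc_map
    )
    truth.events.setdefault(f"P_{name}", {})["insertion"] = (
        x,
        x + len(gene) - 1,
        "+",
    )


def _apply_r6_deletion(lin, rng, anc_genes, anc_elems, truth, name):
    """Delete one base inside R6, creating a premature in-frame stop."""
    s, e, strand = anc_genes["R6"]
    m = lin.map_interval(s, e)
    if m is None:
        return
    # delete in the middle third, away from the planted frameshift signal
    protected = []
    for nm in ("slippery", "hairpin"):
        if nm in anc_elems:
            pm = lin.map_interval(anc_elems[nm][0], anc_elems[nm][1])
            if pm:
                protected.append(pm)
    lo = m[0] + (m[1] - m[0]) // 3
    hi = m[0] + 2 * (m[1] - m[0]) // 3
    for _ in range(200):
        x = int(rng.integers(lo, hi))
        if all(not (ps <= x <= pe) for ps, pe in protected):
            break
    lin.residues = lin.residues[: x - 1] + lin.residues[x:]
    lin.anc_map = np.where(lin.anc_map == x - 1, -1, lin.anc_map)
    lin.anc_map = np.where(lin.anc_map >= x, lin.anc_map - 1, lin.anc_map)
    truth.events.setdefault(f"P_{name}", {})["r6_deletion"] = x


# ---------------------------------------------------------------------------
# reads and spacers
# ---------------------------------------------------------------------------

def simulate_reads(
    plasmid: CircularSequence,
    coverage: float,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "read",
) -> ReadSet:
    """Uniform circular shotgun reads from both strands.

    Per-base substitution errors at ``error_rate``; deterministic per
    seed.  Qualities are constant placeholders.
    """
    if coverage <= 0:
        raise SequenceError("coverage must be > 0")
    if read_len > plasmid.length:
        raise SequenceError("read length exceeds plasmid length")
    # separate streams so positions/strands are identical across error
    # rates for the same seed (errors overlay a fixed sampling)
    ss_pos, ss_err = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss_pos)
    erng = np.random.default_rng(ss_err)
    n_reads = int(round(coverage * plasmid.length / read_len))
    dbl = plasmid.residues + plasmid.residues
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, plasmid.length))
        s = dbl[start : start + read_len]
        if rng.random() < 0.5:
            s = _rc(s)
        if error_rate > 0:
            chars = list(s)
            errs = np.nonzero(erng.random(read_len) < error_rate)[0]
            for j in errs:
                chars[j] = "ACGT"[erng.integers(4)]
                while chars[j] == s[j]:
                    chars[j] = "ACGT"[erng.integers(4)]
            s = "".join(chars)
        reads.append((f"{id_prefix}_{i}", s, "I" * read_len))
    return ReadSet(
        reads=reads,
        source={"plasmid": plasmid.id, "coverage": coverage, "seed": seed},
    )


def make_spacer_set(
    plasmids: list[CircularSequence],
    truth: SyntheticTruth,
    n_true: int = 5,
    n_decoy: int = 20,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], dict]:
    """CRISPR-spacer test set: (id, sequence, DR) triples plus truth.

    True spacers are 30–40 nt substrings of annotated gene regions,
    mutated per base at ``mutation_rate``; decoys are random sequences
    of matched length and GC.  The DR string is carried as metadata the
    way spacer-extraction pipelines report it.
    """
    rng = np.random.default_rng(seed)
    dr = "GTTTCAGACGAACCAAGCTGGTGTTGAAGC"
    spacers = []
    truth_map: dict[str, dict] = {}
    gene_pool = []
    for pid in sorted(truth.genes):
        if pid == "ancestor" and len(truth.genes) > 1:
            continue
        seq = next((s for s in plasmids if s.id == pid), None)
        if seq is None:
            continue
        for label, (s, e, strand) in sorted(truth.genes[pid].items()):
            if e > s:  # skip origin-spanning for simplicity of extraction
                gene_pool.append((pid, label, s, e, strand, seq))
    if n_true > len(gene_pool):
        raise SequenceError("not enough gene space for requested true spacers")
    picks = rng.choice(len(gene_pool), size=n_true, replace=False)
    gc_pool = []
    for i, k in enumerate(picks):
        pid, label, s, e, strand, seq = gene_pool[int(k)]
        n = int(rng.integers(30, 41))
        lo = int(rng.integers(s, max(s + 1, e - n)))
        sub = seq.residues[lo - 1 : lo - 1 + n]
        if mutation_rate > 0:
            chars = list(sub)
            for j in np.nonzero(rng.random(n) < mutation_rate)[0]:
                old = chars[j]
                chars[j] = "ACGT"[rng.integers(4)]
                while chars[j] == old:
                    chars[j] = "ACGT"[rng.integers(4)]
            sub = "".join(chars)
        sid = f"true_{i}"
        spacers.append((sid, sub, dr))
        gc_pool.append((sub.count("G") + sub.count("C")) / n)
        truth_map[sid] = {
            "plasmid": pid, "gene": label, "start": lo,
            "end": lo + n - 1, "strand": strand,
        }
    mean_gc = float(np.mean(gc_pool)) if gc_pool else 0.5
    for i in range(n_decoy):
        n = int(rng.integers(30, 41))
        spacers.append((f"decoy_{i}", _random_bases(rng, n, mean_gc), dr))
    return spacers, truth_map
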