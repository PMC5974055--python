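"""Regulatory-element prediction: degenerate promoter scanning, RBS
search, inverted repeats, and conserved intergenic sequence (CIS)
discovery from a multiple alignment.

Haloarchaeal promoters follow the degenerate consensus SRnnRnnnTTWW
centered around -27/-28 relative to the A of the initiator codon, and
transcripts are largely leaderless, so a Shine–Dalgarno-like RBS
(GGAGGTGA) near a start codon is noteworthy rather than expected.
Degenerate IUPAC positions must match their base set exactly; ``n``
positions never count toward mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import (
    CircularSequence,
    Feature,
    SequenceError,
    reverse_complement,
    subsequence,
    wrap_position,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

RBS_CONSENSUS = "GGAGGTGA"
PROMOTER_CONSENSUS = "SRNNRNNNTTWW"


@dataclass
class MotifHit:
    """A located degenerate-motif match."""

    feature: Feature
    pattern_id: str
    mismatches: int
    offset_to_anchor: int | None = None

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
class InvertedRepeat:
    """Two arms of reverse-complementary sequence around a loop."""

    seq_id: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    arm_len: int
    loop_len: int
    mismatches: int
    at_motif_len: int


@dataclass
class CISRegion:
    """A conserved intergenic block across the aligned family."""

    col_start: int  # 0-based MSA columns, inclusive
    col_end: int
    mean_conservation: float
    label: str
    intervals: dict[str, tuple[int, int]]  # per-plasmid 1-based nt interval


# ---------------------------------------------------------------------------
# IUPAC scanning
# ---------------------------------------------------------------------------

def _pattern_matrix(pattern: str) -> np.ndarray:
    """(m, 5) bool matrix: allowed[i, base] for bases A,C,G,T,N."""
    allow = np.zeros((len(pattern), 5), dtype=bool)
    for i, ch in enumerate(pattern):
        up = ch.upper()
        if up not in IUPAC:
            raise SequenceError(f"invalid IUPAC letter {ch!r} in pattern")
        for b in IUPAC[up]:
            allow[i, _BASE_INDEX[b]] = True
        # an N in the pattern tolerates an N (or anything) in the sequence
        allow[i, 4] = up == "N"
    return allow


def _encode(s: str) -> np.ndarray:
    out = np.empty(len(s), dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(s.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def _local_to_genome(j: int, m: int, strand: str, length: int) -> tuple[int, int]:
    """Strand-local 0-based window [j, j+m-1] -> genome (start, end), 1-based.

    The returned interval walked forward (wrapping) and reverse-
    complemented when ``strand == '-'`` reproduces the matched window.
    """
    if strand == "+":
        return wrap_position(j + 1, length), wrap_position(j + m, length)
    return (
        wrap_position(length - (j + m - 1), length),
        wrap_position(length - j, length),
    )


def scan_iupac(
    seq: CircularSequence,
    pattern: str,
    strands: str = "both",
    max_mismatch: int = 0,
    pattern_id: str | None = None,
) -> list[MotifHit]:
    """All (possibly overlapping) degenerate-pattern matches.

    Mismatches are counted only at non-N pattern positions.  Circular
    sequences are scanned across the origin.  ``strands`` is ``"+"``,
    ``"-"`` or ``"both"``.
    """
    allow = _pattern_matrix(pattern)
    m = len(pattern)
    if m > seq.length:
        raise SequenceError("pattern longer than sequence")
    strand_list = ["+", "-"] if strands == "both" else [strands]
    pid = pattern_id or pattern
    hits: list[MotifHit] = []
    for strand in strand_list:
        if strand not in ("+", "-"):
            raise SequenceError(f"invalid strand spec {strand!r}")
        s = seq.residues if strand == "+" else reverse_complement(seq.residues)
        if seq.is_circular:
            s = s + s[: m - 1]
        enc = _encode(s)
        windows = np.lib.stride_tricks.sliding_window_view(enc, m)
        ok = allow[np.arange(m)[None, :], windows]
        mism = (~ok).sum(axis=1)
        for j in np.nonzero(mism <= max_mismatch)[0]:
            start, end = _local_to_genome(int(j), m, strand, seq.length)
            hits.append(
                MotifHit(
                    feature=Feature(
                        seq_id=seq.id,
                        start=start,
                        end=end,
                        strand=strand,
                        type="motif",
                    ),
                    pattern_id=pid,
                    mismatches=int(mism[j]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def iupac_match_probability(pattern: str, gc: float) -> float:
    """Per-position match probability under an i.i.d. base model.

    Bases are drawn with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2; the
    probability is the product over non-N pattern positions of the
    summed base probabilities in each IUPAC set.
    """
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    prob = 1.0
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise SequenceError(f"invalid IUPAC letter {ch!r}")
        prob *= sum(p[b] for b in IUPAC[ch])
    return prob


# ---------------------------------------------------------------------------
# RBS
# ---------------------------------------------------------------------------

def _gene_5prime_local(gene: Feature, length: int) -> int:
    """0-based strand-local position of the gene's first coding base."""
    if gene.strand == "+":
        return gene.start - 1
    return length - gene.end


def find_rbs(
    seq: CircularSequence,
    gene: Feature,
    consensus: str = RBS_CONSENSUS,
    max_mismatch: int = 1,
    search_window: tuple[int, int] = (3, 12),
) -> MotifHit | None:
    """Best RBS-like match upstream of a gene start, or None.

    The offset is the number of nt strictly between the motif's 3' end
    and the first base of the start codon; the search covers offsets
    ``search_window[0]..search_window[1]``.  Best = fewest mismatches,
    then smallest offset.
    """
    L = seq.length
    m = len(consensus)
    s = seq.residues if gene.strand == "+" else reverse_complement(seq.residues)
    if seq.is_circular:
        ext = s + s
    else:
        ext = s
    g5 = _gene_5prime_local(gene, L)
    best: tuple[int, int] | None = None  # (mismatches, offset)
    cons = consensus.upper()
    for off in range(search_window[0], search_window[1] + 1):
        j = g5 - off - m
        if seq.is_circular:
            j %= L
        elif j < 0:
            continue
        window = ext[j : j + m]
        if len(window) < m:
            continue
        mism = sum(
            1
            for a, b in zip(cons, window)
            if b not in IUPAC[a] and a != "N"
        )
        if mism <= max_mismatch and (best is None or (mism, off) < best):
            best = (mism, off)
            best_j = j
    if best is None:
        return None
    mism, off = best
    start, end = _local_to_genome(best_j, m, gene.strand, L)
    return MotifHit(
        feature=Feature(
            seq_id=seq.id,
            start=start,
            end=end,
            strand=gene.strand,
            type="motif",
            attributes={"matched": ext[best_j : best_j + m]},
        ),
        pattern_id=consensus,
        mismatches=mism,
        offset_to_anchor=off,
    )


# ---------------------------------------------------------------------------
# inverted repeats
# ---------------------------------------------------------------------------

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _longest_at_run(s: str) -> int:
    best = run = 0
    for ch in s:
        run = run + 1 if ch in "ATW" else 0
        best = max(best, run)
    return best


def find_inverted_repeats(
    seq: CircularSequence,
    start: int = 1,
    end: int | None = None,
    min_arm: int = 4,
    max_loop: int = 12,
    max_mismatch: int = 0,
) -> list[InvertedRepeat]:
    """Maximal inverted repeats within a region.

    For every candidate center (loop of 0..``max_loop`` nt) arms are
    extended outward while the mismatch budget holds; maximal extensions
    with arm >= ``min_arm`` are reported, sorted by arm length then
    position.  Coordinates are genome 1-based (the region may wrap).
    """
    if end is None:
        end = seq.length
    region = subsequence(seq, start, end, "+")
    n = len(region)
    results: list[InvertedRepeat] = []
    seen: set[tuple[int, int, int]] = set()
    for loop in range(0, max_loop + 1):
        for left_end in range(n - loop - 1):  # 0-based last index of left arm
            right_start = left_end + loop + 1
            arm = 0
            mism = 0
            i, j = left_end, right_start
            last_valid = None
            while i >= 0 and j < n:
                if _COMPL.get(region[i]) == region[j] and region[i] != "N":
                    pass
                else:
                    mism += 1
                    if mism > max_mismatch:
                        break
                arm += 1
                if arm >= min_arm:
                    last_valid = (i, arm, mism)
                i -= 1
                j += 1
            if last_valid is None:
                continue
            i0, arm, mism = last_valid
            key = (left_end, loop, arm)
            if key in seen:
                continue
            seen.add(key)
            left = region[i0 : left_end + 1]
            results.append(
                InvertedRepeat(
                    seq_id=seq.id,
                    left_start=wrap_position(start + i0, seq.length),
                    left_end=wrap_position(start + left_end, seq.length),
                    right_start=wrap_position(start + right_start, seq.length),
                    right_end=wrap_position(
                        start + right_start + arm - 1, seq.length
                    ),
                    arm_len=arm,
                    loop_len=loop,
                    mismatches=mism,
                    at_motif_len=_longest_at_run(left),
                )
            )
    results.sort(key=lambda r: (-r.arm_len, r.left_start, r.loop_len))
    return results


# ---------------------------------------------------------------------------
# conserved intergenic sequences
# ---------------------------------------------------------------------------

def _column_positions(row: str) -> np.ndarray:
    """1-based ungapped position per MSA column (0 where the row has a gap)."""
    out = np.zeros(len(row), dtype=np.int64)
    pos = 0
    for c, ch in enumerate(row):
        if ch != "-":
            pos += 1
            out[c] = pos
    return out


def _genic_mask(row: str, genes: list[Feature], length: int) -> np.ndarray:
    pos = _column_positions(row)
    genic = np.zeros(len(row), dtype=bool)
    for g in genes:
        if g.end >= g.start:
            sel = (pos >= g.start) & (pos <= g.end)
        else:  # origin-spanning gene
            sel = (pos >= g.start) | ((pos >= 1) & (pos <= g.end))
        genic |= sel
    return genic


def column_conservation(rows: list[str]) -> np.ndarray:
    """Per-column fraction of rows agreeing with the column consensus."""
    arr = np.array([list(r) for r in rows])
    n, ncols = arr.shape
    cons = np.empty(ncols)
    for c in range(ncols):
        col = arr[:, c]
        bases = col[col != "-"]
        if len(bases) == 0:
            cons[c] = 0.0
            continue
        _, counts = np.unique(bases, return_counts=True)
        cons[c] = counts.max() / n
    return cons


def detect_cis(
    ids: list[str],
    rows: list[str],
    gene_annotations: dict[str, list[Feature]],
    min_len: int = 12,
    min_conservation: float = 0.9,
) -> list[CISRegion]:
    """Conserved intergenic blocks across >= 3 aligned plasmids.

    A candidate is a maximal run of >= ``min_len`` consecutive columns
    that are intergenic in every plasmid, with every column's
    conservation (fraction of plasmids agreeing with the column
    consensus) >= ``min_conservation``; a single intergenic stretch can
    therefore yield several islands.  Candidates are labeled CIS I,
    II, ... in positional order (the family's historical numbering
    follows the same left-to-right convention).
    """
    if len(rows) < 3:
        raise SequenceError("CIS detection needs >= 3 plasmids")
    lengths = {i: len(r.replace("-", "")) for i, r in zip(ids, rows)}
    genic_any = np.zeros(len(rows[0]), dtype=bool)
    for pid, row in zip(ids, rows):
        genic_any |= _genic_mask(row, gene_annotations.get(pid, []), lengths[pid])
    intergenic = ~genic_any
    if not intergenic.any():
        return []
    cons = column_conservation(rows)
    good = intergenic & (cons >= min_conservation)

    regions: list[CISRegion] = []
    ncols = len(rows[0])
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    c = 0
    while c < ncols:
        if not good[c]:
            c += 1
            continue
        d = c
        while d + 1 < ncols and good[d + 1]:
            d += 1
        if d - c + 1 >= min_len:
            intervals = {}
            for pid, row in zip(ids, rows):
                pos = _column_positions(row)
                inside = pos[c : d + 1]
                inside = inside[inside > 0]
                if len(inside):
                    intervals[pid] = (int(inside.min()), int(inside.max()))
            regions.append(
                CISRegion(
                    col_start=c,
                    col_end=d,
                    mean_conservation=float(cons[c : d + 1].mean()),
                    label="",
                    intervals=intervals,
                )
            )
        c = d + 1
    for i, r in enumerate(regions):
        r.label = f"CIS {roman[i]}" if i < len(roman) else f"CIS {i + 1}"
    return regions


# ---------------------------------------------------------------------------
# positional promoter filtering
# ---------------------------------------------------------------------------

def _signed_offset(p: float, gene: Feature, length: int) -> float:
    """Offset of genome position p relative to the gene's initiator A,
    measured 5'->3' on the gene strand; negative = upstream."""
    if gene.strand == "+":
        delta = p - gene.start
    else:
        delta = gene.end - p
    # map onto (-length/2, length/2] circularly
    delta = (delta + length / 2) % length - length / 2
    return delta


def promoter_positional_filter(
    hits: list[MotifHit],
    genes: list[Feature],
    center_range: tuple[float, float] = (-30, -20),
    seq_length: int | None = None,
) -> list[MotifHit]:
    """Keep hits whose motif center lies upstream of some gene start.

    A hit survives when its center offset (on the gene strand, negative
    upstream of the initiator A) falls inside ``center_range`` for a
    gene on the same strand; the gene is recorded in the hit feature's
    ``gene`` attribute.
    """
    lo, hi = center_range
    kept = []
    for h in hits:
        L = seq_length or max(g.end for g in genes)
        if h.feature.end >= h.feature.start:
            center = (h.feature.start + h.feature.end) / 2
        else:
            n = (h.feature.end - h.feature.start) % L + 1
            center = wrap_position(int(h.feature.start + n // 2), L)
        for g in genes:
            if g.strand != h.strand:
                continue
            off = _signed_offset(center, g, L)
            if lo <= off <= hi:
                h.feature.attributes["gene"] = g.attributes.get("ID", "") or (
                    f"{g.seq_id}:{g.start}-{g.end}{g.strand}"
                )
                h.offset_to_anchor = int(round(off))
                kept.append(h)
                break
    return kept
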