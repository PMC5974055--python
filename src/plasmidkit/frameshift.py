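"""-1 programmed ribosomal frameshift (PRF) signature detection.

A -1 PRF site consists of a "slippery" heptamer X_XXY_YYZ — where the
P- and A-site tRNAs can re-pair after the ribosome slips back one
nucleotide — followed 2–12 nt downstream by a stable RNA stem-loop that
stalls the ribosome over the heptamer.  An interrupted CDS (internal
stop) whose frame is restored by a single base insertion, together with
such a signature, is the classic evidence for either a pseudogene or a
translationally recoded gene.

The hairpin free energy is a hairpin-only nearest-neighbor model:
Watson–Crick stack energies (Turner-style values at 37 °C), approximate
constants for GU-containing stacks, hairpin-loop initiation penalties
with a logarithmic extrapolation beyond 9 nt, and a terminal AU/GU
penalty.  It scores a single contiguous stem — full secondary-structure
prediction is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

from .seqio import (
    CircularSequence,
    Feature,
    SequenceError,
    subsequence,
    wrap_position,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Watson-Crick nearest-neighbor stacks, kcal/mol at 37 C; key =
# (outer pair, inner pair) with pairs written (5' arm base, 3' arm base)
WC_STACKS = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("AU", "GC"): -2.08,
    ("AU", "CG"): -2.24, ("UA", "AU"): -1.33, ("UA", "UA"): -0.93,
    ("UA", "GC"): -2.11, ("UA", "CG"): -2.35, ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24, ("GC", "GC"): -3.26, ("GC", "CG"): -3.42,
    ("CG", "AU"): -2.11, ("CG", "UA"): -2.08, ("CG", "GC"): -2.36,
    ("CG", "CG"): -3.26,
}
GU_STACK_ONE = -1.2   # stack containing one GU pair (approximate)
GU_STACK_TWO = -0.5   # stack of two GU pairs (approximate)

HAIRPIN_LOOP = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
LOOP_EXTRAPOLATION = 1.078  # 1.75 * RT at 37 C, kcal/mol
TERMINAL_AU_PENALTY = 0.45

VALID_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}


@dataclass
class Hairpin:
    """A single stem-loop with its nearest-neighbor free energy."""

    stem_pairs: list[tuple[int, int]]  # 0-based indices in the subsequence
    loop: tuple[int, int]              # 0-based inclusive loop interval
    dg: float                          # kcal/mol, negative = stable
    interval: tuple[int, int]          # 0-based inclusive hairpin extent


@dataclass
class SlipperySite:
    """A slippery heptamer with its downstream hairpin, if any."""

    start: int          # genome 1-based, forward-walk interval
    end: int
    strand: str
    heptamer: str
    pattern_class: str  # e.g. "A_AAA_AAC"
    deviations: int
    hairpin_distance: int | None
    hairpin: Hairpin | None


# ---------------------------------------------------------------------------
# hairpin free energy
# ---------------------------------------------------------------------------

def _to_rna(s: str) -> str:
    return s.upper().replace("T", "U")


def _pair(a: str, b: str) -> str | None:
    p = a + b
    return p if p in VALID_PAIRS else None


def _stack_energy(outer: str, inner: str) -> float:
    outer_gu = outer in ("GU", "UG")
    inner_gu = inner in ("GU", "UG")
    if outer_gu and inner_gu:
        return GU_STACK_TWO
    if outer_gu or inner_gu:
        return GU_STACK_ONE
    return WC_STACKS[(outer, inner)]


def _loop_penalty(n: int) -> float:
    if n < 3:
        return float("inf")
    if n in HAIRPIN_LOOP:
        return HAIRPIN_LOOP[n]
    return HAIRPIN_LOOP[9] + LOOP_EXTRAPOLATION * log(n / 9)


def hairpin_candidates(rna: str):
    """Yield (pairs, loop, dg) for every contiguous-stem hairpin."""
    n = len(rna)
    for i in range(n):
        for j in range(i + 4, n):  # at least 1 pair + 3 loop
            outer = _pair(rna[i], rna[j])
            if outer is None:
                continue
            pairs = [(i, j)]
            dg_stack = 0.0
            t = 1
            while i + t < j - t:
                p = _pair(rna[i + t], rna[j - t])
                if p is None:
                    break
                dg_stack += _stack_energy(
                    _pair(rna[i + t - 1], rna[j - t + 1]), p
                )
                pairs.append((i + t, j - t))
                loop_len = (j - t) - (i + t) - 1
                if loop_len >= 3:
                    dg = dg_stack + _loop_penalty(loop_len)
                    if outer in ("AU", "UA", "GU", "UG"):
                        dg += TERMINAL_AU_PENALTY
                    yield list(pairs), (i + t + 1, j - t - 1), dg
                t += 1


def hairpin_energy(sequence: str) -> Hairpin | None:
    """Best (lowest ΔG) single contiguous-stem hairpin, or None.

    ``sequence`` may be DNA or RNA, 10–200 nt.  Returns None when no
    decomposition achieves ΔG < 0 (e.g. homopolymers cannot pair).
    """
    if not 10 <= len(sequence) <= 200:
        raise SequenceError("hairpin search requires 10..200 nt")
    rna = _to_rna(sequence)
    best: Hairpin | None = None
    for pairs, loop, dg in hairpin_candidates(rna):
        if dg < 0 and (best is None or dg < best.dg):
            best = Hairpin(
                stem_pairs=pairs,
                loop=loop,
                dg=dg,
                interval=(pairs[0][0], pairs[0][1]),
            )
    return best


# ---------------------------------------------------------------------------
# slippery sites
# ---------------------------------------------------------------------------

def classify_heptamer(h: str, forbid_z: str = "G") -> int | None:
    """Deviations of a heptamer from X_XXY_YYZ, or None if not scorable.

    Constraints: N1=N2=N3 (X), N4=N5=N6 (Y), Y in {A,T/U},
    Z != ``forbid_z``.  Each violated constraint counts one deviation.
    """
    if len(h) != 7:
        return None
    dev = 0
    x, y, z = h[0], h[3], h[6]
    dev += (h[1] != x) + (h[2] != x)
    dev += (h[4] != y) + (h[5] != y)
    if y not in "ATU":
        dev += 1
    if forbid_z and z == forbid_z:
        dev += 1
    return dev


def find_slippery_sites(
    seq: CircularSequence,
    strand: str,
    frame_anchor: int,
    max_deviations: int = 1,
    hairpin_gap: tuple[int, int] = (2, 12),
    hairpin_window: int = 40,
    forbid_z: str = "G",
) -> list[SlipperySite]:
    """Scan a CDS frame for slippery heptamers with downstream hairpins.

    ``frame_anchor`` is the genome 1-based position of the first base of
    the CDS (its 5' end on the coding strand); heptamers are reported
    only in the phase where slippage re-pairs codons (X_XXY_YYZ with the
    codon boundary after X).  Each site is paired with the best hairpin
    whose 5' end lies ``hairpin_gap`` nt downstream of the heptamer.
    """
    L = seq.length
    mrna = subsequence(seq, 1, L, "+")
    if strand == "-":
        mrna = subsequence(seq, 1, L, "-")
    # strand-local 0-based position of the CDS start
    if strand == "+":
        a0 = frame_anchor - 1
    else:
        a0 = L - frame_anchor
    ext = mrna + mrna if seq.is_circular else mrna
    sites: list[SlipperySite] = []
    for p in range(L):
        if (p - a0) % 3 != 2:
            continue
        hept = ext[p : p + 7]
        if len(hept) < 7:
            continue
        dev = classify_heptamer(hept, forbid_z=forbid_z)
        if dev is None or dev > max_deviations:
            continue
        best_hp, best_d = None, None
        for d in range(hairpin_gap[0], hairpin_gap[1] + 1):
            lo = p + 7 + d
            window = ext[lo : lo + hairpin_window]
            if len(window) < 10:
                continue
            hp = hairpin_energy(window)
            if hp is not None and hp.stem_pairs[0][0] == 0:
                # anchor: hairpin must begin where the gap says it does
                if best_hp is None or hp.dg < best_hp.dg:
                    best_hp, best_d = hp, d
        if strand == "+":
            g_start = wrap_position(p + 1, L)
            g_end = wrap_position(p + 7, L)
        else:
            g_start = wrap_position(L - (p + 6), L)
            g_end = wrap_position(L - p, L)
        sites.append(
            SlipperySite(
                start=g_start,
                end=g_end,
                strand=strand,
                heptamer=hept,
                pattern_class=f"{hept[0]}_{hept[1:4]}_{hept[4:7]}",
                deviations=dev,
                hairpin_distance=best_d,
                hairpin=best_hp,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# ORF rescue by single-base insertion
# ---------------------------------------------------------------------------

def internal_stops(mrna: str) -> list[int]:
    """0-based codon indices of in-frame stops before the final codon."""
    stops = []
    ncod = len(mrna) // 3
    for c in range(ncod - 1):
        if mrna[3 * c : 3 * c + 3] in STOP_CODONS:
            stops.append(c)
    return stops


def _first_stop_codon(s: str) -> int | None:
    for c in range(len(s) // 3):
        if s[3 * c : 3 * c + 3] in STOP_CODONS:
            return c
    return None


def rescue_orf_by_insertion(
    seq: CircularSequence,
    cds_start: int,
    cds_end: int,
    strand: str,
    consensus_aa: int | None = None,
    length_tolerance: float = 0.10,
) -> list[tuple[int, int]]:
    """Single-base insertions that restore an interrupted CDS.

    The CDS interval (inclusive, stop codon included) must contain an
    in-frame internal stop; otherwise the result is empty.  Every
    insertion position x base is tested; reported are mRNA-local 1-based
    positions (insertion after that base) where the repaired sequence
    translates to its final codon without internal stops and the
    restored protein length is within ``length_tolerance`` of
    ``consensus_aa`` (default: the interval's own codon count).

    Returns a sorted list of (position, restored protein length aa).
    """
    mrna = subsequence(seq, cds_start, cds_end, strand)
    stops = internal_stops(mrna)
    if not stops:
        return []
    first_stop = stops[0]
    target = consensus_aa if consensus_aa is not None else (len(mrna) + 1) // 3 - 1
    lo_len = target * (1 - length_tolerance)
    hi_len = target * (1 + length_tolerance)
    found: dict[int, int] = {}
    # insertions after the first internal stop cannot remove it
    limit = min(len(mrna), 3 * first_stop + 3)
    for pos in range(0, limit + 1):  # insert after mRNA position pos
        for base in "ACGT":
            cand = mrna[:pos] + base + mrna[pos:]
            stop = _first_stop_codon(cand)
            if stop is None:
                continue
            # end-to-end: the first stop is the final complete codon
            if stop != len(cand) // 3 - 1:
                continue
            if lo_len <= stop <= hi_len:
                prev = found.get(pos)
                if prev is None or stop > prev:
                    found[pos] = stop
    return sorted(found.items())
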