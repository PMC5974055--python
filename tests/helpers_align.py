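"""Exhaustive alignment oracles for small instances.

Enumerates every monotone matching between two sequences and scores it
directly (substitutions plus affine gap costs for the unmatched runs).
This is exponential-time by construction and entirely independent of
any dynamic-programming alignment implementation, so it serves as the
ground-truth optimum on instances of up to ~12 residues.
"""

from __future__ import annotations


def _gap(length: int, open_: float, extend: float) -> float:
    """Affine cost (negative) of a gap of the given length; 0 if empty."""
    return 0.0 if length == 0 else -(open_ + extend * length)


def best_global_score(a, b, sub, open_: float, extend: float) -> float:
    """Optimal global alignment score by exhaustive matching enumeration.

    ``sub(x, y)`` returns the substitution score.  A gap of length L
    costs ``open_ + extend * L``.
    """
    m, n = len(a), len(b)
    best = [float("-inf")]

    def rec(pi: int, pj: int, acc: float) -> None:
        end = acc + _gap(m - pi, open_, extend) + _gap(n - pj, open_, extend)
        if end > best[0]:
            best[0] = end
        for p in range(pi, m):
            gap_a = _gap(p - pi, open_, extend)
            for q in range(pj, n):
                rec(
                    p + 1,
                    q + 1,
                    acc + gap_a + _gap(q - pj, open_, extend) + sub(a[p], b[q]),
                )

    rec(0, 0, 0.0)
    return best[0]


def best_local_score(a, b, sub, open_: float, extend: float) -> float:
    """Optimal local alignment score (terminal gaps free, empty = 0)."""
    m, n = len(a), len(b)
    best = [0.0]

    def rec(pi: int, pj: int, acc: float, started: bool) -> None:
        if acc > best[0]:
            best[0] = acc
        for p in range(pi, m):
            for q in range(pj, n):
                if started:
                    g = _gap(p - pi, open_, extend) + _gap(q - pj, open_, extend)
                else:
                    g = 0.0
                rec(p + 1, q + 1, acc + g + sub(a[p], b[q]), True)

    rec(0, 0, 0.0, False)
    return best[0]


def nt_sub(match: float = 1.0, mismatch: float = -1.0):
    def sub(x, y):
        return match if x == y else mismatch

    return sub


def blosum62_sub():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")

    def sub(x, y):
        return float(mat[x, y])

    return sub
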