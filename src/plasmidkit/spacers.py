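"""CRISPR spacer vs plasmid matching.

Spacers are fragments of invading DNA stored in host CRISPR arrays;
matches between spacer collections and a plasmid family indicate that
the plasmids (or close relatives) have invaded those hosts.  Matching
is seed-and-extend local alignment with BLASTN-like scoring on both
strands of each circular plasmid; matches can additionally be compared
at the protein level by translating the plasmid interval in an
annotated gene's frame against the spacer's best reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Seq import Seq

from .seqio import CircularSequence, SequenceError, subsequence, wrap_position
from .annotate import GeneModel

DEFAULT_SCORES = {"match": 2.0, "mismatch": -3.0, "open": -5.0, "extend": -2.0}
SEED_WORD = 8
DEFAULT_MIN_CORE = 25       # matched-core columns required of the seed hit
DEFAULT_MIN_IDENTITY = 70.0  # percent over the full-spacer alignment


@dataclass
class SpacerMatch:
    """A local alignment between a spacer and a plasmid."""

    spacer_id: str
    plasmid_id: str
    start: int          # genome 1-based, forward-walk interval
    end: int
    strand: str         # strand of the plasmid matched by the spacer as given
    identity: float     # percent identical over alignment columns
    length: int         # alignment columns
    aligned_spacer: str
    aligned_plasmid: str
    score: float
    dr: str | None = None
    translations: tuple[str, str] | None = None
    attributes: dict = field(default_factory=dict)


def read_spacer_fasta(path: str | Path) -> list[tuple[str, str, str | None]]:
    """Read spacers as (id, sequence, DR) from FASTA with ``DR=`` tags."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        dr = None
        for token in rec.description.split():
            if token.startswith("DR="):
                dr = token[3:]
        out.append((rec.id, str(rec.seq).upper(), dr))
    if not out:
        raise SequenceError(f"no spacers in {path}")
    return out


def _local_aligner(scores: dict | None = None) -> Align.PairwiseAligner:
    s = dict(DEFAULT_SCORES)
    if scores:
        s.update(scores)
    aligner = Align.PairwiseAligner()
    aligner.match_score = s["match"]
    aligner.mismatch_score = s["mismatch"]
    aligner.open_gap_score = s["open"] + s["extend"]
    aligner.extend_gap_score = s["extend"]
    aligner.mode = "local"
    return aligner


def _has_seed(spacer: str, target: str, word: int = SEED_WORD) -> bool:
    words = {spacer[i : i + word] for i in range(len(spacer) - word + 1)}
    return any(target[i : i + word] in words for i in range(len(target) - word + 1))


def _global_aligner(scores: dict | None = None) -> Align.PairwiseAligner:
    a = _local_aligner(scores)
    a.mode = "global"
    return a


def match_spacers(
    spacers: list[tuple[str, str, str | None]],
    plasmids: list[CircularSequence],
    min_len: int = DEFAULT_MIN_CORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    scores: dict | None = None,
) -> list[SpacerMatch]:
    """Best qualifying protospacer match of each spacer on each plasmid.

    A word-``8`` seed gates a (C-implemented) local alignment on both
    strands of the doubled circular sequence, so matches may cross the
    origin.  The local core must span >= ``min_len`` columns; the match
    is then widened to the full spacer against the implied plasmid
    window (the protospacer convention) and kept when the full-length
    identity reaches ``min_identity`` percent.
    """
    aligner = _local_aligner(scores)
    nw = _global_aligner(scores)
    results: list[SpacerMatch] = []
    for plasmid in plasmids:
        dbl = (
            plasmid.residues + plasmid.residues[:100]
            if plasmid.is_circular
            else plasmid.residues
        )
        for sid, sp, dr in spacers:
            if not 15 <= len(sp) <= 80:
                raise SequenceError(f"spacer {sid!r} length out of range")
            best = None
            for strand, query in (("+", sp), ("-", str(Seq(sp).reverse_complement()))):
                if not _has_seed(query, dbl):
                    continue
                alns = aligner.align(query, dbl)
                if len(alns) == 0 or alns[0].score <= 0:
                    continue
                aln = alns[0]
                ncols = len(str(aln[0]))
                if ncols < min(min_len, len(query)):
                    continue
                q_lo = int(aln.aligned[0][0][0])
                q_hi = int(aln.aligned[0][-1][1])
                t_lo = int(aln.aligned[1][0][0])
                t_hi = int(aln.aligned[1][-1][1])
                # widen to the full spacer (protospacer convention)
                w_lo = max(0, t_lo - q_lo)
                w_hi = min(len(dbl), t_hi + (len(query) - q_hi))
                window = dbl[w_lo:w_hi]
                full = nw.align(query, window)[0]
                rq, rt = str(full[0]), str(full[1])
                n_id = sum(1 for a, b in zip(rq, rt) if a == b and a != "-")
                ident = 100.0 * n_id / len(rq)
                if ident < min_identity:
                    continue
                cand = SpacerMatch(
                    spacer_id=sid,
                    plasmid_id=plasmid.id,
                    start=wrap_position(w_lo + 1, plasmid.length),
                    end=wrap_position(w_hi, plasmid.length),
                    strand=strand,
                    identity=ident,
                    length=len(rq),
                    aligned_spacer=rq,
                    aligned_plasmid=rt,
                    score=float(aln.score),
                    dr=dr,
                )
                if best is None or cand.score > best.score:
                    best = cand
            if best is not None:
                results.append(best)
    results.sort(key=lambda m: (-m.score, m.spacer_id, m.plasmid_id))
    return results


# ---------------------------------------------------------------------------
# translated comparison
# ---------------------------------------------------------------------------

def _translate(nt: str) -> str:
    """Translate, rendering stop codons as ``*`` (amber/ochre/opal)."""
    ncod = len(nt) // 3
    return str(Seq(nt[: 3 * ncod]).translate(table=11)).replace("*", "*")


def translate_compare(
    match: SpacerMatch,
    gene: GeneModel,
    plasmid: CircularSequence,
    spacer_seq: str,
) -> tuple[str, str, int]:
    """Compare a spacer and its plasmid target at the protein level.

    The plasmid interval is widened to codon boundaries of ``gene`` and
    translated in the gene's frame; the spacer is translated in the
    frame (of six) maximizing identical residues against it.  Stop
    codons render as ``*``.  Returns (spacer_aa, plasmid_aa,
    n_identical).
    """
    g = gene.feature
    L = plasmid.length
    # positions of the match interval along the gene's coding strand
    if g.strand == "+":
        off_start = (match.start - g.start) % L
        off_end = (match.end - g.start) % L
    else:
        off_start = (g.end - match.end) % L
        off_end = (g.end - match.start) % L
    if off_end < off_start:
        raise SequenceError("match does not lie within the gene")
    cod_lo = off_start - off_start % 3
    cod_hi = off_end + (2 - off_end % 3)
    if g.strand == "+":
        nt = subsequence(
            plasmid,
            wrap_position(g.start + cod_lo, L),
            wrap_position(g.start + cod_hi, L),
            "+",
        )
    else:
        nt = subsequence(
            plasmid,
            wrap_position(g.end - cod_hi, L),
            wrap_position(g.end - cod_lo, L),
            "-",
        )
    plasmid_aa = _translate(nt)

    frames = []
    rc = str(Seq(spacer_seq).reverse_complement())
    for src in (spacer_seq, rc):
        for f in range(3):
            frames.append(_translate(src[f:]))
    flag = len(match.aligned_spacer.replace("-", "")) % 3 != 0

    def n_same(a: str, b: str) -> int:
        return max(
            sum(1 for x, y in zip(a[i:], b) if x == y)
            for i in range(max(1, len(a) - len(b) + 1))
        ) if len(a) >= len(b) else n_same_rev(a, b)

    def n_same_rev(a: str, b: str) -> int:
        return max(
            sum(1 for x, y in zip(a, b[i:]) if x == y)
            for i in range(max(1, len(b) - len(a) + 1))
        )

    best_frame = max(frames, key=lambda fr: n_same(fr, plasmid_aa))
    ident = n_same(best_frame, plasmid_aa)
    if flag:
        match.attributes["frameshifted"] = True
    match.translations = (best_frame, plasmid_aa)
    return best_frame, plasmid_aa, ident
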