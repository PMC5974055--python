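"""Sequence and annotation I/O, plus circular-coordinate arithmetic.

Small haloarchaeal plasmids are circular molecules of a few kilobases.
Every downstream analysis (ORF calling, motif scanning, alignment,
assembly closure) has to be correct across the arbitrary point at which
the deposited sequence was linearized, so the coordinate conventions
live here and everything else imports them:

* coordinates are 1-based and inclusive;
* on a circular sequence a feature may span the origin, in which case
  ``end < start`` and the feature wraps through position ``length`` to 1;
* rotating a circular sequence is a pure re-linearization — it changes
  coordinates but no biological content.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")

FEATURE_TYPES = {
    "CDS",
    "motif",
    "CIS",
    "inverted_repeat",
    "slippery_site",
    "region",
}

FAMILY_LABELS = {
    "F1", "F2", "F3", "F3.1", "F3.2", "R4", "R5", "R6", "R7", "other",
}


class SequenceError(ValueError):
    """Raised for malformed sequences or illegal coordinate requests."""


@dataclass(frozen=True)
class CircularSequence:
    """An immutable DNA record with explicit topology.

    Parameters
    ----------
    id:
        Record identifier (FASTA header word).
    residues:
        Uppercase DNA over ``{A, C, G, T, N}``.
    topology:
        ``"circular"`` (default for plasmids) or ``"linear"``.
    """

    id: str
    residues: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise SequenceError(
                f"record {self.id!r}: topology must be circular or linear"
            )
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.residues, start=1) if c in bad
            )
            raise SequenceError(
                f"record {self.id!r}: illegal residue "
                f"{self.residues[pos - 1]!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Feature:
    """A stranded interval on a (possibly circular) sequence.

    ``start``/``end`` are 1-based inclusive; on circular sequences
    ``end < start`` denotes an origin-spanning feature.  ``family``
    carries the gene-family label (F1–F3, R4–R7, …) where known.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    type: str
    family: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SequenceError(f"invalid strand {self.strand!r}")
        if self.type not in FEATURE_TYPES:
            raise SequenceError(f"invalid feature type {self.type!r}")
        if self.family is not None and self.family not in FAMILY_LABELS:
            raise SequenceError(f"invalid family label {self.family!r}")
        if self.start < 1 or self.end < 1:
            raise SequenceError(
                f"coordinates must be >= 1, got {self.start}..{self.end}"
            )

    def length_on(self, seq: CircularSequence) -> int:
        """Feature length in nt, wrapping through the origin if needed."""
        return interval_length(self.start, self.end, seq.length)

    def spans_origin(self) -> bool:
        return self.end < self.start


# ---------------------------------------------------------------------------
# circular coordinate arithmetic
# ---------------------------------------------------------------------------

def interval_length(start: int, end: int, seq_length: int) -> int:
    """Length of the 1-based inclusive interval, wrapping when end < start.

    Never returns 0: an interval with ``end == start - 1 (mod length)``
    is interpreted as the full circle.
    """
    n = (end - start) % seq_length + 1
    return n


def wrap_position(pos: int, seq_length: int) -> int:
    """Map an arbitrary integer onto 1..seq_length circularly."""
    return (pos - 1) % seq_length + 1


def reverse_complement(s: str) -> str:
    return str(Seq(s).reverse_complement())


def subsequence(
    seq: CircularSequence, start: int, end: int, strand: str = "+"
) -> str:
    """Extract the inclusive interval ``start..end``; ``-`` reverse-complements.

    On circular sequences ``end < start`` wraps through the origin.
    Requesting a wrap on a linear sequence is an error.
    """
    if not (1 <= start <= seq.length and 1 <= end <= seq.length):
        raise SequenceError(
            f"coordinates {start}..{end} outside 1..{seq.length} "
            f"for record {seq.id!r}"
        )
    if end >= start:
        s = seq.residues[start - 1 : end]
    else:
        if not seq.is_circular:
            raise SequenceError(
                f"origin wrap {start}..{end} requested on linear "
                f"record {seq.id!r}"
            )
        s = seq.residues[start - 1 :] + seq.residues[:end]
    if strand == "-":
        s = reverse_complement(s)
    elif strand != "+":
        raise SequenceError(f"invalid strand {strand!r}")
    return s


def rotate(seq: CircularSequence, new_origin: int) -> CircularSequence:
    """Re-linearize a circular sequence so it begins at ``new_origin``."""
    if not seq.is_circular:
        raise SequenceError(f"cannot rotate linear record {seq.id!r}")
    k = wrap_position(new_origin, seq.length)
    if k == 1:
        return seq
    return replace(seq, residues=seq.residues[k - 1 :] + seq.residues[: k - 1])


def rotate_coordinate(pos: int, new_origin: int, seq_length: int) -> int:
    """Where position ``pos`` lands after ``rotate(seq, new_origin)``."""
    return wrap_position(pos - new_origin + 1, seq_length)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[CircularSequence]:
    """Read FASTA records as :class:`CircularSequence`.

    Topology is taken from a ``topology=circular|linear`` keyword in the
    header description and defaults to circular (every replicon in a
    plasmid family study is circular).  Lowercase input is uppercased.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topology = "circular"
        for token in rec.description.split():
            if token.startswith("topology="):
                topology = token.split("=", 1)[1]
        records.append(
            CircularSequence(
                id=rec.id, residues=str(rec.seq).upper(), topology=topology
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(
    seqs: Iterable[CircularSequence], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id} topology={s.topology}\n")
            for i in range(0, s.length, width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def _gff_attributes(feature: Feature, feat_id: str) -> str:
    parts = [f"ID={feat_id}"]
    if feature.family is not None:
        parts.append(f"family={feature.family}")
    for k, v in sorted(feature.attributes.items()):
        parts.append(f"{k}={v}")
    return ";".join(parts)


def write_gff3(
    features: Sequence[Feature],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
) -> None:
    """Write features as GFF3.

    Origin-spanning features follow the standard circular-genome
    convention: two location lines sharing one ``ID`` attribute.
    ``seq_lengths`` enables coordinate validation and region pragmas.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seq_lengths:
            for sid, n in seq_lengths.items():
                fh.write(f"##sequence-region {sid} 1 {n}\n")
        for i, f in enumerate(features, start=1):
            if seq_lengths is not None and f.seq_id in seq_lengths:
                n = seq_lengths[f.seq_id]
                if f.start > n or f.end > n:
                    raise SequenceError(
                        f"feature {f.start}..{f.end} outside sequence "
                        f"{f.seq_id!r} of length {n}"
                    )
            feat_id = f.attributes.get("ID", f"feat{i}")
            attrs = _gff_attributes(f, feat_id)
            phase = "0" if f.type == "CDS" else "."
            if f.spans_origin():
                if seq_lengths is None or f.seq_id not in seq_lengths:
                    raise SequenceError(
                        "origin-spanning feature requires seq_lengths for "
                        f"record {f.seq_id!r}"
                    )
                n = seq_lengths[f.seq_id]
                rows = [(f.start, n), (1, f.end)]
            else:
                rows = [(f.start, f.end)]
            for s, e in rows:
                fh.write(
                    "\t".join(
                        [
                            f.seq_id,
                            "plasmidkit",
                            f.type,
                            str(s),
                            str(e),
                            ".",
                            f.strand,
                            phase,
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path) -> list[Feature]:
    """Read GFF3 written by :func:`write_gff3`.

    Two-part features sharing an ID are merged back into one
    origin-spanning :class:`Feature`.
    """
    rows: list[tuple[str, str, int, int, str, dict]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise SequenceError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            for item in cols[8].split(";"):
                if item:
                    k, _, v = item.partition("=")
                    attrs[k] = v
            rows.append((cols[0], cols[2], int(cols[3]), int(cols[4]), cols[6], attrs))

    features: list[Feature] = []
    by_id: dict[tuple[str, str], list[int]] = {}
    for seq_id, ftype, start, end, strand, attrs in rows:
        key = (seq_id, attrs.get("ID", ""))
        family = attrs.pop("family", None)
        fid = attrs.pop("ID", None)
        if key in by_id and fid is not None:
            # second half of an origin-spanning feature: starts at 1
            idx = by_id[key][0]
            prev = features[idx]
            features[idx] = replace(prev, end=end)
            continue
        if fid is not None:
            attrs["ID"] = fid
        f = Feature(
            seq_id=seq_id,
            start=start,
            end=end,
            strand=strand,
            type=ftype,
            family=family,
            attributes=attrs,
        )
        by_id.setdefault(key, []).append(len(features))
        features.append(f)
    return features


# ---------------------------------------------------------------------------
# newick / TSV
# ---------------------------------------------------------------------------

def write_newick(newick: str, path: str | Path) -> None:
    """Write a newick string (already serialized by compare.nj_tree)."""
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    with open(path, "w") as fh:
        fh.write(text + "\n")


def write_tsv(rows: Iterable[dict], path: str | Path) -> None:
    """Write homogeneous dict rows as a TSV table with a header."""
    rows = list(rows)
    with open(path, "w", newline="") as fh:
        if not rows:
            return
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
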