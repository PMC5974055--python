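"""End-to-end orchestration of the plasmid-family analyses.

Runs, over a set of circular plasmid FASTA records: summary statistics,
pairwise identity + NJ tree with bootstrap, gene annotation with family
labels, protein statistics, compositional segmentation, regulatory
motif / CIS / inverted-repeat / frameshift-signal prediction, optional
CRISPR-spacer matching and optional read-recruitment assembly.  Every
stage writes plain-text artifacts (TSV/GFF3/newick/JSON) into the
output directory; re-running with the same config and seed reproduces
them byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotate, compare, composition, frameshift, motifs, recruit, spacers, seqio

log = logging.getLogger("plasmidkit")


@dataclass
class RunConfig:
    """Inputs, output directory, per-stage parameters and toggles."""

    fasta: str | Path | None = None
    spacer_fasta: str | Path | None = None
    reads_fastq: str | Path | None = None
    outdir: str | Path = "plasmidkit_out"
    seed: int = 0
    bootstrap_n: int = 100
    min_aa: int = 30
    promoter_pattern: str = motifs.PROMOTER_CONSENSUS
    promoter_center_range: tuple[float, float] = (-30.0, -20.0)
    rbs_consensus: str = motifs.RBS_CONSENSUS
    ir_window_upstream: int = 60
    cis_min_len: int = 12
    cis_min_conservation: float = 0.9
    assembly_k: int = 31
    stages: dict = field(
        default_factory=lambda: {
            "summary": True,
            "compare": True,
            "annotate": True,
            "composition": True,
            "motifs": True,
            "frameshift": True,
            "spacers": True,
            "recruit": True,
        }
    )


def _read_fastq(path: str | Path):
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append((rec.id, str(rec.seq).upper(), None))
    from .synthdata import ReadSet

    return ReadSet(reads=reads, source={"path": str(path)})


def run_all(
    config: RunConfig, sequences: list[seqio.CircularSequence] | None = None
) -> dict:
    """Execute all enabled stages; returns the report bundle.

    ``sequences`` may be passed directly (e.g. generated in memory);
    otherwise ``config.fasta`` is read.  Raises on stage failure after
    preserving partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"outputs": {}, "stages": {}}
    if sequences is None:
        if config.fasta is None:
            raise seqio.SequenceError("no input sequences")
        sequences = seqio.read_fasta(config.fasta)
    seqs = sequences
    stage = "summary"
    try:
        # ------------------------------------------------ summary (Table 1)
        if config.stages.get("summary", True):
            log.info("stage summary: %d plasmids", len(seqs))
            rows = [
                {
                    "id": s.id,
                    "length_nt": s.length,
                    "gc_percent": round(composition.region_gc(s), 1),
                }
                for s in seqs
            ]
            p = outdir / "summary.tsv"
            seqio.write_tsv(rows, p)
            report["outputs"]["summary"] = str(p)
            report["stages"]["summary"] = rows

        # ------------------------------------------------ annotation
        genes_by_plasmid: dict[str, list[annotate.GeneModel]] = {}
        family: annotate.FamilyAssignment | None = None
        stage = "annotate"
        if config.stages.get("annotate", True):
            log.info("stage annotate: ORF calling (min_aa=%d)", config.min_aa)
            for s in seqs:
                genes_by_plasmid[s.id] = annotate.find_orfs(s, min_aa=config.min_aa)
            if len(seqs) >= 2:
                family = annotate.assign_families(genes_by_plasmid)
            feats = []
            for s in seqs:
                for g in genes_by_plasmid[s.id]:
                    feats.append(g.feature)
            p = outdir / "annotation.gff3"
            seqio.write_gff3(
                feats, p, seq_lengths={s.id: s.length for s in seqs}
            )
            report["outputs"]["annotation"] = str(p)
            # Table-3-style protein table per family
            if family is not None:
                rows = _protein_table(family)
                p = outdir / "protein_families.tsv"
                seqio.write_tsv(rows, p)
                report["outputs"]["protein_families"] = str(p)
                report["stages"]["protein_families"] = rows
                anchors = {}
                for pid, labeled in family.assignments.items():
                    for lab, g in labeled:
                        if lab == "F1":
                            anchors[pid] = g.start
                report["stages"]["origin_anchor_f1"] = anchors

        # ------------------------------------------------ comparison
        stage = "compare"
        msa_ids = msa_rows = None
        if config.stages.get("compare", True) and len(seqs) >= 2:
            log.info("stage compare: all-pairs circular alignment")
            labels, dmat, alns = compare.distance_matrix(seqs)
            idmat = 100.0 * (1.0 - dmat)
            rows = []
            for i, a in enumerate(labels):
                row = {"id": a}
                for j, b in enumerate(labels):
                    row[b] = round(float(idmat[i, j]), 2)
                rows.append(row)
            p = outdir / "identity_matrix.tsv"
            seqio.write_tsv(rows, p)
            report["outputs"]["identity_matrix"] = str(p)
            pair_ids = idmat[np.triu_indices(len(labels), k=1)]
            report["stages"]["mean_pairwise_identity"] = float(pair_ids.mean())
            win_rows = []
            for aln in alns:
                for center, ident in aln.window_identity:
                    win_rows.append(
                        {
                            "pair": f"{aln.id_a}|{aln.id_b}",
                            "center_nt": center,
                            "identity": round(ident, 2),
                        }
                    )
            seqio.write_tsv(win_rows, outdir / "window_identity.tsv")
            if len(seqs) >= 3:
                log.info(
                    "stage compare: MSA + NJ bootstrap (n=%d, seed=%d)",
                    config.bootstrap_n,
                    config.seed,
                )
                msa_ids, msa_rows, _off = compare.progressive_msa(seqs)
                tree = compare.bootstrap_nj(
                    msa_ids,
                    msa_rows,
                    n_replicates=config.bootstrap_n,
                    seed=config.seed,
                )
                p = outdir / "tree.nwk"
                seqio.write_newick(tree.newick(), p)
                report["outputs"]["tree"] = str(p)
                report["stages"]["tree_newick"] = tree.newick()

        # ------------------------------------------------ composition
        stage = "composition"
        if config.stages.get("composition", True):
            log.info("stage composition: GC profile segmentation")
            seg_rows = []
            for s in seqs:
                if s.length >= 1000:
                    prof = composition.gc_profile_segment(s, seed=config.seed)
                    for seg in prof.segments:
                        seg_rows.append(
                            {
                                "id": s.id,
                                "start": seg[0],
                                "end": seg[1],
                                "gc_percent": round(seg[2], 1),
                            }
                        )
            p = outdir / "gc_segments.tsv"
            seqio.write_tsv(seg_rows, p)
            report["outputs"]["gc_segments"] = str(p)
            report["stages"]["gc_segments"] = seg_rows

        # ------------------------------------------------ motifs
        stage = "motifs"
        if config.stages.get("motifs", True):
            log.info("stage motifs: promoter/RBS/IR/CIS")
            motif_rows = []
            for s in seqs:
                hits = motifs.scan_iupac(
                    s, config.promoter_pattern, strands="both"
                )
                motif_rows.append({"id": s.id, "promoter_sites": len(hits)})
            report["stages"]["promoter_counts"] = motif_rows
            rbs_rows = []
            ir_rows = []
            if genes_by_plasmid and family is not None:
                for s in seqs:
                    for lab, g in family.assignments.get(s.id, []):
                        if lab == "F3":
                            hit = motifs.find_rbs(
                                s, g.feature, consensus=config.rbs_consensus
                            )
                            if hit:
                                rbs_rows.append(
                                    {
                                        "id": s.id,
                                        "gene": lab,
                                        "motif": hit.feature.attributes.get(
                                            "matched", ""
                                        ),
                                        "offset_nt": hit.offset_to_anchor,
                                        "mismatches": hit.mismatches,
                                    }
                                )
                        if lab == "R4":
                            w = config.ir_window_upstream
                            # upstream of a reverse-strand gene = after end
                            irs = motifs.find_inverted_repeats(
                                s,
                                start=g.end + 1,
                                end=min(s.length, g.end + w),
                                min_arm=4,
                                max_loop=12,
                            )
                            for ir in irs[:3]:
                                ir_rows.append(
                                    {
                                        "id": s.id,
                                        "left": f"{ir.left_start}-{ir.left_end}",
                                        "right": f"{ir.right_start}-{ir.right_end}",
                                        "arm": ir.arm_len,
                                        "loop": ir.loop_len,
                                        "at_motif": ir.at_motif_len,
                                    }
                                )
            seqio.write_tsv(rbs_rows, outdir / "rbs_hits.tsv")
            seqio.write_tsv(ir_rows, outdir / "inverted_repeats.tsv")
            report["stages"]["rbs_hits"] = rbs_rows
            report["stages"]["inverted_repeats"] = ir_rows
            if msa_rows is not None and genes_by_plasmid:
                feats = {
                    pid: [g.feature for g in gl]
                    for pid, gl in genes_by_plasmid.items()
                }
                cis = motifs.detect_cis(
                    msa_ids,
                    msa_rows,
                    feats,
                    min_len=config.cis_min_len,
                    min_conservation=config.cis_min_conservation,
                )
                cis_rows = [
                    {
                        "label": r.label,
                        "cols": f"{r.col_start}-{r.col_end}",
                        "conservation": round(r.mean_conservation, 3),
                    }
                    for r in cis
                ]
                seqio.write_tsv(cis_rows, outdir / "cis_regions.tsv")
                report["stages"]["cis_regions"] = cis_rows

        # ------------------------------------------------ frameshift
        stage = "frameshift"
        if config.stages.get("frameshift", True) and genes_by_plasmid:
            log.info("stage frameshift: slippery-site scan in reverse block")
            fs_rows = []
            for s in seqs:
                pool = (
                    family.assignments.get(s.id, [])
                    if family is not None
                    else [("CDS", g) for g in genes_by_plasmid.get(s.id, [])]
                )
                for lab, g in pool:
                    if not lab.startswith("R"):
                        continue
                    anchor = g.end if g.strand == "-" else g.start
                    sites = frameshift.find_slippery_sites(
                        s, g.strand, anchor, max_deviations=0
                    )
                    for site in sites:
                        if site.hairpin is None or site.hairpin.dg > -8.0:
                            continue
                        fs_rows.append(
                            {
                                "id": s.id,
                                "gene": lab,
                                "heptamer": site.heptamer,
                                "start": site.start,
                                "end": site.end,
                                "hairpin_dg": round(site.hairpin.dg, 1),
                            }
                        )
            seqio.write_tsv(fs_rows, outdir / "frameshift_sites.tsv")
            report["stages"]["frameshift_sites"] = fs_rows

        # ------------------------------------------------ spacers
        stage = "spacers"
        if config.stages.get("spacers", True) and config.spacer_fasta:
            log.info("stage spacers: matching against plasmids")
            sp = spacers.read_spacer_fasta(config.spacer_fasta)
            matches = spacers.match_spacers(sp, seqs)
            rows = [
                {
                    "spacer": m.spacer_id,
                    "plasmid": m.plasmid_id,
                    "interval": f"{m.start}-{m.end}",
                    "strand": m.strand,
                    "identity": round(m.identity, 1),
                    "dr": m.dr or "",
                }
                for m in matches
            ]
            seqio.write_tsv(rows, outdir / "spacer_matches.tsv")
            report["stages"]["spacer_matches"] = rows

        # ------------------------------------------------ recruitment
        stage = "recruit"
        if config.stages.get("recruit", True) and config.reads_fastq:
            log.info("stage recruit: iterative closure (k=%d)", config.assembly_k)
            reads = _read_fastq(config.reads_fastq)
            state = recruit.iterative_closure(
                reads, seqs[0], k=config.assembly_k
            )
            seqio.write_tsv(state.rounds, outdir / "recruitment_rounds.tsv")
            if state.final is not None:
                seqio.write_fasta([state.final], outdir / "assembled.fasta")
            report["stages"]["recruitment"] = {
                "closed": state.closed,
                "rounds": state.rounds,
            }
    except Exception:
        log.exception("stage %r failed; partial outputs kept in %s", stage, outdir)
        raise

    meta = {
        "seed": config.seed,
        "n_plasmids": len(seqs),
        "bootstrap_n": config.bootstrap_n,
        "stages": {k: bool(v) for k, v in config.stages.items()},
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump({**meta, "report_keys": sorted(report["stages"])}, fh, indent=2)
    return report


def _protein_table(family: annotate.FamilyAssignment) -> list[dict]:
    by_label: dict[str, list] = {}
    for pid, labeled in family.assignments.items():
        for lab, g in labeled:
            by_label.setdefault(lab, []).append(g)
    rows = []
    order = ["F1", "F2", "F3", "F3.1", "F3.2", "R7", "R6", "R5", "R4", "other"]
    for lab in order:
        if lab not in by_label or lab == "other":
            continue
        gs = by_label[lab]
        lengths = [len(g.protein) for g in gs]
        pis = [annotate.protein_stats(g.protein)[1] for g in gs]
        idents = []
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                idents.append(
                    annotate.pairwise_protein_identity(
                        gs[i].protein, gs[j].protein
                    )
                )
        rows.append(
            {
                "family": lab,
                "n": len(gs),
                "aa_min": min(lengths),
                "aa_max": max(lengths),
                "aa_mean": round(float(np.mean(lengths)), 1),
                "identity_min": round(min(idents), 1) if idents else "",
                "identity_max": round(max(idents), 1) if idents else "",
                "identity_mean": round(float(np.mean(idents)), 1) if idents else "",
                "pi_min": round(min(pis), 2),
                "pi_max": round(max(pis), 2),
                "pi_mean": round(float(np.mean(pis)), 2),
            }
        )
    return rows
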