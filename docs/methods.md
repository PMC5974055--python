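# Methods

This note documents the models and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates and circularity

All coordinates are 1-based inclusive. Circular sequences wrap: an
interval with `end < start` runs through the origin, and a feature's
length is `(end − start) mod L + 1`, never zero. Rotation is pure
re-linearization; ORF sets, motif hits and alignments are expected to
be rotation-invariant (or covariant in coordinates), and property tests
enforce this. Minus-strand features use the forward-walk convention:
`subsequence(seq, start, end, "−")` yields the mRNA.

## Pairwise and multiple alignment

Deposited circular replicons are linearized at arbitrary points, so
pairwise comparison first recovers the relative rotation by a k-mer
(k = 12) offset vote — each shared k-mer votes for `(j − i) mod L` —
smoothed over ±2 offsets to absorb indel smearing, then takes the raw
vote peak inside that window. Global alignment then uses affine-gap
dynamic programming (Biopython's C `PairwiseAligner`) with match +1,
mismatch −1 and gap cost `5 + L` for a gap of length L (the package's
convention throughout is `open + extend·L`). Identity is identical
columns over all alignment columns, gap columns counting against it.
Protein identity uses BLOSUM62 with gap cost `11 + L`, identical
columns over the span between the first and last aligned residue pair
(terminal overhangs excluded, internal gaps included); this convention
is configurable since different aligners print different numbers for
the same pair.

The multiple alignment is progressive: pairwise distances give a
closest-pair-first merge order, and profiles are merged by aligning
their column-majority consensus sequences and propagating the gap
pattern to all member rows. This consensus-profile scheme trades a
little accuracy against full profile–profile scoring for simplicity
and speed; at the family's 61–79% identity the region-similarity and
conservation measures derived from it are stable. Exhaustive
enumeration of all monotone matchings is the test oracle for the DP on
instances up to 12 residues.

## Distances, trees, bootstrap

Distances are `1 − identity` (pairwise p-distances from MSA rows drop
columns where either row is gapped). Neighbor joining is the canonical
Saitou–Nei Q-matrix algorithm; negative branch lengths are clamped to
zero. Bootstrap resamples MSA columns with replacement (default 100
replicates, seeded), support being the fraction of replicate trees
containing each bipartition of the full-data tree. On additive
matrices NJ reproduces all path lengths exactly, which the tests use
as a closed-form oracle, alongside a cross-check against dendropy's
independent NJ implementation.

## GC profile segmentation

The segmentation statistic is the mean-detrended cumulative GC excess
`c(i)`. Detection uses recursive binary segmentation: an interval is
split when the maximum excursion of `c` from the chord joining the
interval's endpoints exceeds a permutation threshold. The threshold is
calibrated by shuffling the sequence's own residues (default 100
permutations) and taking a conservative upper-5% order statistic (rank
`⌈0.95(m+1)⌉ + 2`), so a homogeneous sequence triggers a breakpoint in
under 5% of runs; sub-intervals reuse the full-length threshold scaled
by √(n/L), the Brownian-bridge scaling of the null maximum. Once an
interval is accepted for splitting, the breakpoint is *localized* by
the increment-likelihood maximum — the per-base GC indicators are
i.i.d. within a segment, so the cumulative curve is a random walk with
piecewise drift and the profile likelihood of a drift change at k
reduces to maximizing `(c_k−c_lo)²/(k−lo) + (c_hi−c_k)²/(hi−k)`. A
final coordinate-descent sweep re-estimates each breakpoint over the
span between its neighbors. Excursion detection plus likelihood
localization outperforms either statistic used alone: the standardized
likelihood statistic is edge-heavy under the null (weak detection),
while the excursion argmax wanders with random-walk noise (poor
localization). With the family's compositional contrasts (~55% / ~42%
/ ~51% GC) boundary localization to ±150 nt succeeds in ≈ 94% of
simulated plasmids; the residual failures are intrinsic — the 42→51%
boundary carries limited information per base — not estimator slack.

## ORF calling and family labels

ORFs are called on both strands of the doubled sequence (circular
wrap), grouped by stop codon; the longest start (ATG/GTG; TTG excluded
by default because haloarchaeal leaderless transcripts overwhelmingly
initiate at ATG, with GTG reserved for poorly expressed genes) is
reported with nested alternatives as attributes. `min_aa` defaults
to 30. Before family clustering, each plasmid's list is reduced to a
longest-first non-overlapping tiling (overlaps ≤ 30 nt allowed so
operon stop/start junctions survive), which removes the short spurious
ORFs that litter random sequence. Families are connected components of
reciprocal-best protein-identity links (≥ 30% identity over ≥ 60% of
the shorter protein). Because the most diverged members of a real
family can fall below any such threshold (reverse-block proteins range
down to ~17% identity), fragmented clusters with disjoint plasmid
sets, the same strand, compatible mean protein lengths (ratio ≥ 0.6)
and mean fractional positions within 0.04 of each other are merged —
the family is collinear, so position is the correct completion signal.
Major labels (F1–F3 forward, R7–R4 reverse, left to right) go to the
clusters with the largest total protein content, ordered by position;
dotted minor labels (F3.1, F3.2) go positionally to what remains
downstream; everything else is `other` (e.g. a strain-specific
methylase insertion).

Isoelectric points use Henderson–Hasselbalch charge summation with
EMBOSS pKa values (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5,
D 3.9, E 4.1, C 8.5, Y 10.1) and bisection to |charge| < 1e−4. pI is
pKa-table-dependent (Biopython's Bjellqvist table differs by a few
tenths), so printed pI values are treated as approximate.

## Regulatory elements

The IUPAC scanner matches degenerate patterns on both strands across
the origin; `n` positions never count as mismatches, degenerate sets
must match exactly (default `max_mismatch = 0` for the promoter
consensus — the tolerance is not standardized, so it is a parameter).
The closed-form background rate under an i.i.d. base model (product of
per-position set probabilities) is the calibration oracle. Promoter
hits are kept at scan time and filtered positionally afterwards
(center within −30..−20 of an initiator on the gene strand, matching
the −27/−28 centering of haloarchaeal promoters). The RBS search
reports the best (fewest mismatches, then nearest) match to
`GGAGGTGA` with up to one mismatch, 3–12 nt upstream; the offset
convention is the count of nucleotides strictly between the motif's 3′
end and the start codon's first base, which makes "4 nt upstream"
print as 4. Inverted repeats are maximal outward arm extensions around
every candidate loop (0–12 nt), with the AT-motif length being the
longest A/T run within the arm. CIS regions are maximal runs (≥ 12
columns) of MSA columns that are intergenic in every plasmid with
per-column conservation (fraction of rows agreeing with the column
consensus) ≥ 0.9, labeled CIS I, II, … left to right.

## Frameshift signatures

Slippery sites are heptamers `X_XXY_YYZ` (N1=N2=N3, N4=N5=N6, Y ∈
{A,U}, Z ≠ G; each violated constraint counts one deviation, default
tolerance 1) in the phase where the codon boundary follows X. Each
site is paired with the best hairpin beginning 2–12 nt downstream.
Hairpin free energy is a hairpin-only nearest-neighbor model:
Watson–Crick stack energies (Turner-style 37 °C values), fixed
approximate constants for GU-containing stacks (−1.2 one GU, −0.5
two), hairpin-loop initiation penalties with `1.078·ln(n/9)`
extrapolation beyond 9 nt, and +0.45 for an AU/GU closing pair. The
model scores one contiguous stem — no bulges, multiloops or dangles —
so it runs ~1.5–2.5 kcal/mol less negative than full secondary-
structure folders; a loose cross-check against RNAfold (±4 kcal/mol)
and exact agreement with brute-force stem enumeration are both tested.
Insertion rescue tries all four bases at every position up to the
first in-frame stop and reports positions whose repaired sequence
translates end-to-end with a length within ±10% of the family
consensus; a deletion inside a homopolymer run is only localizable to
the run, which is how the tests score it.

## Spacer matching

Protospacer search is seed (word 8) gated local alignment with
BLASTN-like scores (+2/−3, gap 5 + 2L) on both strands of the doubled
circle. Because local alignment trims to the best-scoring core while
published spacer alignments display the full spacer, the matched core
(≥ 25 columns) is widened to a full-spacer semi-global alignment
against the implied window, and the reported identity (threshold 70%)
is computed over that. These defaults were calibrated on the
generator: they admit full-length matches at the ~75–80% identity of
published spacer hits while random 30–40-mers against a 6-kb family
match in ≈ 0–1% of cases. Translated comparison renders stops as `*`
and picks the spacer frame (of six) maximizing identical residues
against the gene-frame translation of the widened interval.

## Recruitment and closure

Recruitment is seed-voted overlap alignment: shared 15-mers vote for a
read offset, and the implied overlapping spans are verified by edlib
edit-distance identity (default ≥ 90%). Against a circular reference
the whole read must align (coverage ≥ 0.8); against a linear contig a
read may overhang either end with ≥ 25 nt anchored — this dovetail
rule is what lets iterative rounds extend contigs into flanking
sequence, mirroring how conserved blocks seed recruitment from a
diverged relative and the assembly then walks outward. Assembly is a
de Bruijn graph over read k-mers (default k = 31, both orientations);
k-mers below an adaptive cutoff — `max(2, min(3, 0.2·median))` of the
multiplicities among k-mers seen at least twice, since singleton error
k-mers dominate the distinct-k-mer multiset — are pruned, and maximal
non-branching paths become unitigs (one per reverse-complement pair).
Closure is declared when the longest contig's ends share an exact
k−1 overlap, which is trimmed; the final circle is oriented by shared
k-mer count against the seed reference. The loop stops after
`max_rounds` (default 40; extension proceeds ~2×(read length −
overlap) per round) or two rounds without growth. Consensus accuracy
relies on the coverage-pruned graph rather than a separate pileup
polishing step; with error-free reads reconstruction is exact, which
the tests assert up to rotation.

## The synthetic generator

`generate_ancestor` builds a ~6.2-kb circular plasmid: origin
intergenic region with two conserved islands (the second carrying an
overlapping, oppositely oriented promoter pair whose forward member
centers ~26 nt upstream of F1), the F1→F2→F3 operon with `TGATG`
stop/start overlaps and the `GGAGGCGA` RBS 4 nt upstream of F3, an
AT-rich central region with two more islands, the R7..R4 reverse block
(30-nt gaps, one island in the R7/R6 gap, slippery heptamer + GC
hairpin inside R6), and an R4-proximal inverted repeat with a 4-nt AT
motif centered ~20 nt upstream of the R4 start. Region GC targets
(0.55 / 0.42 / 0.51) are hit by iteratively retuned sampling (±1–2
points, matching the narrow published bands). Intergenic sequence is
"stop-salted": any 60-nt stop-free stretch in any of the six frames
gets a stop injected, because real intergenic DNA between dense gene
blocks does not harbor gene-sized spurious ORFs, and without this the
longest-ORF convention is dominated by artifacts. Small guard elements
(in-frame stops just upstream of each planted start, plus a junction
codon that cannot extend into an upstream ATG/GTG) make the planted
gene models exactly recoverable; guards are recorded with `_guard_`
names and protected like other elements.

`evolve_family` walks a fixed guide tree `((A,B),(C,D),E)` (branch
lengths normalized so the mean pairwise path is 1) applying per-site
Jukes–Cantor substitutions at region-specific rates chosen by
inverting the JC formula from the target observed distances (0.16 in
the forward tier, 0.46 elsewhere — the two-tier ~84%/~54% structure,
family mean inside 61–79%). Planted elements and start/stop codons are
protected; substitutions that create in-frame stops are reverted to
the parent codon; indels (geometric length, mean 3, capped at 6)
occur only in unprotected intergenic sequence, with coordinate maps
from the ancestor maintained per lineage so every truth coordinate
remains exact. Optional lineage events: an AT-rich methylase-like gene
inserted into one leaf's central region, and a single-base deletion
inside one leaf's R6 creating a premature stop (the pseudogene /
frameshift scenario). Reads are uniform circular shotgun draws with
i.i.d. substitution errors; read positions derive from a stream
separate from the error stream so the same seed gives the same
sampling at any error rate.

What the generator does *not* emulate: real indel processes inside
genes, codon-usage and amino-acid-level selection (outside stop
protection), quality-score error profiles, repeat structure, and
metavirome community complexity beyond random decoy replicons. Tests
passing on this generator therefore demonstrate correctness of the
algorithms under the family's composition/divergence structure, not
robustness to every artifact of real sequencing data.

## Problem sizes

The default ancestor is full scale (~6.2 kb). Repeated-simulation
statistics use proportionally scaled families (`FamilyParams.scaled`,
gene floor 52 aa) so that hundreds of replicates stay cheap: tree
recovery uses ~2.2-kb families, CIS recovery ~3.2-kb families;
segmentation statistics always use full-size plasmids. The scaled
floor exists because reverse-block genes shrunk to ~36 aa become
indistinguishable from background ORFs at the family's divergence —
at that size the labeling problem is genuinely ill-posed.

## Known limitations

* The hairpin model is hairpin-only; reported ΔG values are 1.5–2.5
  kcal/mol less negative than full folders and should be read with
  that parameter dependence in mind.
* Consensus-based progressive MSA can misplace gaps in low-identity
  regions; region similarities carry ~±2-point method dependence.
* Family labeling assumes a collinear family; rearranged plasmids
  would need the synteny-merge step disabled.
* The segmentation's ±150-nt localization is near the information
  limit for single-digit GC contrasts; weaker contrasts will localize
  proportionally worse.
* CRISPR spacer extraction from raw metagenomes is out of scope; the
  matcher consumes spacer FASTA (with optional `DR=` header metadata).
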