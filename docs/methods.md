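# Methods

`cladecore` re-implements, as a tested library, the comparative-genomics
toolchain used in bacterial genome papers of the finished-chromosome era:
threshold-based reciprocal orthology and core/unique proteome set algebra
across genomes and genome groups, genome-landscape statistics (GC content,
GC skew and the replication axis, deviant-GC islands, feature censuses,
motif scans), synteny dotplots with inversion detection, and the
microarray differential-expression chain (Grubbs outlier removal,
replicate averaging, Cyber-T, a joint fold-change/p filter).  Because no
public data accompanies the workflow, a synthetic-genome generator with
planted ground truth is a first-class component: every analysis stage is
validated by recovering structure the generator planted.

## Coordinates and data model

All coordinates are 1-based inclusive (GFF3/GenBank convention); any
half-open export (BED-like TSV) converts at the boundary.  Genomes are
single circular chromosomes; a feature may wrap the origin only when
flagged, with span `L - start + 1 + end`.  IS-relatedness is an
annotation property — a `mobile_element` type, an explicit attribute, or
a product matching `transposase` / `insertion sequence` / an `IS<n>`
family name — never a sequence classifier.  `N` is allowed in DNA and `X`
in protein; both are excluded from GC and identity numerators.

## Pairwise protein alignment

The comparison engine is an affine-gap Smith–Waterman (Gotoh) kernel,
numba-compiled, scoring with BLOSUM62 and gap costs 11 + 1 per residue
(common protein-search defaults; the workflow this emulates used blastp
without stated parameters).  Identity is identical-residue columns over
all alignment columns, gap columns included in the denominator; `X` never
counts as identical.  Coverage is the aligned span over the full length,
computed for query and subject separately.

The kernel is deterministic by construction: diagonal moves are preferred
over gaps in the subject over gaps in the query, gap opening over
extension, and the traceback starts at the first maximal cell in
row-major order.  This pins down a unique path among co-optimal
alignments, so an independent plain-Python full-matrix DP with the same
conventions reproduces score, identity and coverage exactly (a property
the test suite checks on random pairs).  Identity is direction-symmetric
whenever the optimum is unique — in practice, for all homologous pairs;
unrelated sequences can have co-optimal junk alignments whose identities
differ between directions, where only the score is symmetric (blastp
behaves the same way).

All-vs-all tractability comes from k-mer candidate seeding (k = 4).
`seed_candidates` defaults to 2 shared k-mers; the graph builder uses 3,
which at the simulated study divergence (~50% identity, ~300-residue
proteins, ≈18 expected conserved 4-mers) retains every planted pair
while cutting random candidates roughly threefold.  Exhaustive mode
bypasses seeding entirely and is the guaranteed superset.

## Orthology and the core/unique algebra

Two proteins are orthologs when they are reciprocal best hits (default;
an any-hit mode relaxes reciprocity for sensitivity analysis) and the
alignment has identity >= 0.30 with coverage >= 0.80 **of both
sequences** — the stricter, order-independent reading of "80% of the
sequence length".  A core family is a clique over the multipartite
ortholog graph containing exactly one protein per genome (the
all-pairwise-combinations rule).  A protein claimed by several qualifying
cliques goes to the clique with the highest mean pairwise identity;
losers are dropped and recorded.  Unique proteins have no qualifying
ortholog in any comparator.  IS elements and pseudogenes are excluded
only where the emulated workflow excluded them (the ortholog-fraction
statistic); raw unique counts keep all CDS.

Group operations act on family *representatives* (longest member, ties
lexicographic): `compare_group_cores` counts families whose
representative has a reciprocal qualifying ortholog among the other
group's representatives; `multi_group_shared` intersects that relation
across groups; `group_unique_core` declares a family unique when no
pooled foreign representative yields even a one-directional qualifying
hit (absence of evidence must be absence of *any* hit, so reciprocity is
deliberately not required there).  A single-genome group degenerates to
one family per protein.

## Genome statistics

* **GC content** is 100·(G+C)/(A+C+G+T) over the range.
* **Censuses** use "all coding sequences" = CDS + pseudogenes as the
  denominator for pseudogene/transposase shares — the only denominator
  that reproduces the published 4.3%/4.2% pair from 85 and 83 counts.
  Coding density is reported both as the union of CDS spans over genome
  length and in "summary mode" (count x mean length / genome length),
  which is what genome tables print.
* **Replication axis.**  The cumulative windowed skew (10 kb windows,
  1 kb step) is minimal at the origin and maximal at the terminus for
  G-rich leading strands.  The implementation fits the circular skew
  series with a two-arc (replichore) least-squares segmentation; the
  fitted breakpoints equal the cumulative extrema in the noiseless case
  but do not wander along flat cumulative-curve tops when the local skew
  is weak.  Flat skew raises a degenerate-axis error; weak separation
  (below half the window noise) warns.  Strand classification (leading /
  lagging) is by feature midpoint — a deterministic tie-break for
  boundary-straddling features.
* **Deviant-GC regions** (5 kb windows, 0.5 kb step, |z| >= 3) are scored
  against a robust background (median and 1.4826·MAD of all window GC
  values): a 60 kb island in a ~0.6 Mb genome contributes enough spread
  to inflate a plain standard deviation until its own windows sit at the
  detection margin, whereas the robust scale is unaffected.  Significant
  same-direction windows within two steps merge; runs shorter than three
  windows are discarded (with 90%-overlapping windows any genuine tract
  lights up many consecutive windows, single-window excursions are
  noise).  A region's extent runs from the first to the last significant
  window centre padded by half a step — window-support coordinates, not
  full window extents, which would overhang a sharp-edged island by most
  of a window on each side.
* **Motif scans**: uppercase letters must match, `x`/`X` match anything,
  other lowercase letters are *preferred* — reported as an agreement
  fraction, never vetoing a hit (only uppercase positions are "absolutely
  conserved" in the sortase-substrate notation LPxTGc / lPxTGG).  Sortase
  scans default to a 50-residue C-terminal window, since sortase
  substrates are C-terminal cell-wall anchors.

## Synteny

DNA comparison uses maximal exact matches (>= 20 bp by default, both
strands, k-mer-seeded extension; `min_len < 8` is refused as a quadratic
guard).  Amino-acid-level comparison uses ortholog anchors at locus
midpoints.  Chaining is greedy and colinear per orientation (gap <= 20 kb
on both genomes, >= 3 anchors per block) — adequate for block-level
dotplot structure, not a rearrangement-distance method.  The inversion
symmetry score is the fraction of reverse-block anchors whose circular
midpoint mean lies within 5% of genome length of the origin–terminus
axis; a terminus-centred inversion maps x to 2·ter − x, putting that mean
at the terminus.

## Differential expression

Probe tables are tidy DataFrames (gene, probe, condition, replicate,
log2 intensity).  The chain is: iterative two-sided Grubbs outlier
removal within each gene x array cell (stop when nothing is rejected or
n < 3; constant cells are never touched), arithmetic probe averaging,
Cyber-T, then significance = linear fold change >= 5 AND p <= 1e-4.  A
Benjamini–Hochberg column is emitted as supplementary output but takes no
part in the filter, matching the raw-p workflow being emulated.

Cyber-T regularizes each gene's variance toward a local background:
genes ordered by group mean, background s0 = running mean of per-gene
standard deviations over a 101-gene centred window (squared), posterior
variance s*^2 = (nu0·s0^2 + (n−1)s^2)/(nu0 + n − 2) with nu0 = 10, then a
Welch-type t on regularized variances with Welch–Satterthwaite df plus
2·nu0.  Averaging *standard deviations* (the original tool's choice)
rather than variances matters at n = 3: the sd-average background gives a
null type-I rate of ~0.050 at nominal 0.05, while a variance-average
background is conservative (~0.030).  With nu0 = 0 the statistic reduces
exactly to Welch's t.

Known limitation (documented rather than hidden): at 6 probes per cell
the Grubbs statistic saturates at (n−1)/√n ≈ 2.04 against a critical
value of 1.887, so isolated large outliers are caught with moderate power
(~0.54 at 5 sigma) but two or more outliers in one cell mask each other
almost completely.  Under 20% contamination only ~a third of injected
outliers are even detectable in principle.

## The synthetic-data generator

`simulate_ancestor` lays out non-overlapping genes (Gaussian lengths,
mean 900 bp, clipped to [300, 2400]) with short intergenic spacers on a
circular chromosome, default 500 genes (~0.6 Mb) — the study genome
(~2 Mb, ~1900 CDS, GC 44%) at reduced scale so the full pipeline runs in
minutes on one core.  Protein sequences are drawn from a typical
bacterial amino-acid composition; codons are chosen among synonyms with
weights from target base probabilities, and the GC weight is *calibrated*
(bisection on the expected coding GC) so realized genome GC lands within
a point of the target despite the amino-acid composition.  Two realism
features matter for the axis statistics: a replichore G/C skew flipping
at half the genome (parameter 0.12, attenuated by codon constraints to a
realized ~0.05 window skew, the real-genome range), and a leading-strand
coding bias of 0.75 — coding strands are intrinsically G-rich, and
without the strand bias that coding skew would swamp the replichore
signal, exactly as in real genomes with low strand bias.

`evolve` derives one descendant per call: per-site amino-acid
substitutions at a Poisson rate with proposals weighted by
exp(BLOSUM62/2) (so divergence stays alignable the way real divergence
does), gene losses, novel-sequence gene gains (not duplications, keeping
"unique" unambiguous; duplications would need a paralog-aware truth
model), intergenic IS insertions drawn from two identical-copy families
with transposase products, pseudogenization by a premature mid-gene stop,
an optional low-GC intergenic island, and an optional inversion snapped
to gene boundaries that reverse-complements the segment and flips
contained features.  Every event lands in a `SimulationTruth`; an
independent checker (`truth_problems`) verifies the truth record against
the emitted FASTA/GFF3/proteome.  `simulate_clade` grows a star phylogeny
(the group set algebra needs controllable pairwise divergence, not tree
realism) and composes pairwise ortholog truth through the shared
ancestor; `sub_rate_for_mean_identity(0.5)` gives branch rates for ~50%
expected pairwise identity between siblings (convergent substitutions
ignored — a <1% effect at these rates).

`simulate_microarray` emits probe-level values: gene baseline
N(9, 1.5) + condition effect (log2 of the planted fold) + replicate
offset (sd 0.1) + probe noise (sd 0.25), 6 probes x 3 replicates x 2
conditions, with ±5 sigma outliers at rate `outlier_p`.

What passing tests on these simulations do **not** show: performance on
real annotation noise (miscalled starts, frameshift errors), paralogous
families (gains are novel sequences), rearrangements beyond one
inversion, or array normalization artefacts (normalization is out of
scope; inputs are assumed normalized log2 intensities).

## Problem sizes used by the acceptance script

The script regenerates everything from scratch at the sizes the tests
use: a 3-genome clade from a 500-gene ancestor for ortholog/unique
recovery and threshold monotonicity; 300-gene genomes for the island and
inversion recoveries; 200 random pairs for the alignment oracle; 100
random multipartite instances for the clique oracle; 2000 genes, 3 vs 3
replicates for the null-calibration of the DE chain.  These sizes give
stable statistics in a few minutes on one core; all scale linearly or
quadratically if enlarged.
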