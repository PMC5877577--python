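# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind each pipeline stage, and what the synthetic-data tests
do and do not establish about real data.

## Coordinates and records

All coordinates are 0-based, half-open; GenBank's 1-based inclusive
convention is converted at the I/O boundary. A plastome is a circular
sequence over {A,C,G,T,N} plus typed features (CDS/tRNA/rRNA) with ordered
exonic parts; a feature with k parts has k−1 introns. Features crossing the
origin are stored split at the origin and flagged. Ambiguity codes other
than N are rejected at read time: finished plastome submissions are
ACGT(N), and downstream arithmetic (repeat seeding, codon counting) is only
defined over that alphabet. N is excluded from GC content, never matches in
repeat scans, never counts as a substitution, and is skipped in codon
counting.

Interval classification against the annotation uses four exhaustive labels:
CDS (fully inside exonic parts of any gene, including tRNA/rRNA exons),
intron, IGS (fully intergenic), and CDS-IGS for anything straddling an exon
boundary. Single-base classifications tile the genome exactly.

## Inverted-repeat detection and partitioning

Seed-and-extend: exact 25-mers shared between the sequence and its reverse
complement nominate diagonals; seed clusters (split at 500 bp gaps, since
both IR copies of a genome land on the same diagonal of that comparison)
are extended with +1/−3 match/mismatch scoring and an X-drop of 50, then
trimmed to the maximum-scoring endpoints, so exact planted repeats are
recovered at exact coordinates rather than overshooting into flanking
sequence on the mismatch budget. A pair qualifies at length ≥ 10 kb and
identity ≥ 0.99 (both exposed); the longest wins, ties to the smaller start.

Circularity: the linear scan runs at three phase offsets (0, n/3, 2n/3). An
IR copy shorter than a third of the genome covers at most one cut point, so
at least one linearization leaves both copies intact; plastome IRs
(~25–28 kb of ~150 kb) satisfy this with a wide margin. Detection and
partitioning are therefore invariant under rotation and reverse
complementation of the input.

The two single-copy arcs between the copies become LSC (longer) and SSC
(shorter); the canonical rotation starts the LSC at coordinate 0 and orders
LSC–IRb–SSC–IRa. Region lengths always sum to the genome length. Junction
reports search ±2,000 bp around each boundary — comfortably covering the
junction-gene distances seen in real plastomes (hundreds of bp to ~1.4 kb)
— and record the spanning gene with its overlap into each side, or the
nearest gene per side with its distance. Genomes with no detectable IR are
processed as a single region with junction analysis skipped and a logged
warning.

## Dispersed repeats

A hit is a maximal pair (occurrence₁, occurrence₂, length) under one of
four orientation relations — forward, palindromic (reverse complement),
reverse, complement — with ≤ 3 mismatches and length ≥ 30: maximal means
extension at either end would exceed the budget or leave the sequence.
Defaults (min length 30, Hamming ≤ 3, 50 kept per type) follow the
conventional plastome analysis parameterisation.

Implementation: each orientation is a diagonal comparison between the
sequence and a transform of itself (F: identity; C: complement; R:
reversal; P: reverse complement — the latter two on anti-diagonals, handled
by comparing against the reversed transform). Exact 7-mer seeds suffice by
pigeonhole (a 30 bp window with ≤ 3 mismatches contains an exact stretch
≥ 7). Around each seed, the nearest 4 mismatch positions on each side are
located and every maximal window is enumerated from those slots; seeds
inside an already-processed exact stretch are skipped (windows bound only
at mismatches or boundaries, so same-stretch seeds yield identical window
sets). Pairs are canonicalised (pos1 ≤ pos2) and deduplicated; ties at the
per-type cap resolve by (length desc, pos1 asc, pos2 asc), making output
deterministic. Self-overlapping P and R hits are dropped when the
occurrences overlap by ≥ 50%.

A quadratic brute-force enumerator (full per-diagonal mismatch lists
reduced to maximal windows by sentinel slots) ships in the package as the
independent reference; the test suite asserts exact set equality on 100
seeded sequences with planted structures. The IRa copy is masked (N) before
scanning so the genome's own inverted repeat does not flood the output.

## SSRs and tandem repeats

SSRs follow MISA semantics: a reported locus is a maximal run of a
primitive motif (not a power of a shorter one) whose full-unit count meets
the threshold for its unit length (10/5/4/3/3/3 for 1–6 bp). Each run is
reported exactly once under its shortest unit; runs break at N. Compound
SSRs chain loci with inter-locus gaps ≤ 100 bp — the conventional default
of the standard microsatellite tool; totals count members individually.

The tandem-repeat finder is an explicitly simplified, deterministic variant
of the classic heuristic, not an output-identical reimplementation:
candidate (start, period) pairs come from recurring 5-mers at distances up
to the 500 bp period cap; runs are extended while the periodic self-match
score holds (stopping strictly before three consecutive mismatches, so runs
cannot bridge into neighbouring regions that happen to share the period,
e.g. homopolymers), trimmed to the best-scoring subsegment against the
per-phase consensus (Kadane), and scored +2 per consensus match, −7
otherwise; runs scoring ≥ 80 over ≥ 2 periods are reported, with
longer-period duplicates of a reported repeat suppressed. The indel penalty
of the published scheme is carried in the interface but unused: this
variant does not model indels inside runs, which is the main way its output
can differ from the published heuristic (fragmenting indel-containing
arrays). Its counts are compared to published ones qualitatively only.

## Variability percentage and hotspots

For an aligned locus: substitutions = gap-free columns with ≥ 2 distinct
bases (counted once per column, not pairwise — this keeps the statistic
≤ 100 for any number of rows); indel events = maximal runs of columns
containing ≥ 1 gap; indel length = total such columns; percent =
(substitutions + indel events) / (aligned length − indel length + indel
events) × 100. A column containing both a gap and a base mismatch is
charged to the indel run only. Hotspots: percent strictly > 80 for
non-coding loci, > 50 for coding. For more than two sequences the
definition of "number of indels" is not canonical; alignment-level
gap-column runs were chosen and are documented here — published summary
statistics computed with other aligners or per-row event counting will
differ in the decimals, which is why only the formula's exact small-case
values and the coding/non-coding ordering are asserted, not any published
min/mean/max.

Locus extraction takes gene exonic sequences (strand-corrected), introns
(where intron counts agree across genomes), and spacers between genes
consecutive in every genome (named geneA-geneB); loci absent anywhere, or
spacers whose adjacency differs (local inversion), are skipped with a log
note.

Alignment is center-star: the center is the sequence with the highest total
pairwise score; the others are merged in decreasing similarity, "once a
gap, always a gap". Pairwise steps use Biopython's PairwiseAligner (match
+1, mismatch −1, gap open −4, gap extend −1, so a gap of length g costs
4 + g). The values are conventional; determinism for a fixed input order
matters more here than the precise penalties, and the pairwise kernel is
verified against an exhaustive affine-gap DP oracle on small cases. This
aligner is meant for locus-scale input (≤ ~20 kb); the whole-genome tree
stage uses MAFFT when present.

## NG86 selection screen

Codon alignments are built by aligning translations (BLOSUM62, gap open
−11/extend −1) and threading the nucleotides back, so gaps come in whole
codons; sequences are trimmed to frame and terminal stops removed; genes
with internal stops are skipped with a logged reason; genes whose name
starts with *ndh* are excluded by default (frequently lost in orchids,
which breaks cross-genome homology).

Counting follows Nei–Gojobori (1986): per codon, each of the nine one-step
neighbours is synonymous or nonsynonymous (changes to stops count as
nonsynonymous), so site fractions sum to exactly 3 per codon and are
averaged between the pair; observed differences are averaged over all
mutational pathways with equal weights, excluding pathways through stop
codons and renormalising (if every pathway passes a stop, stops are
tolerated and their steps counted as nonsynonymous, so the codon still
scores). Proportions get the Jukes–Cantor correction d = −¾ ln(1 − 4p/3);
p ≥ ¾ raises a saturation error. ω is undefined at dN = dS = 0 and +∞ at
dS = 0 < dN; the screen ranks genes by their maximum finite pairwise ω and
flags those above 1.0. The implementation is cross-checked for exact
equality against Biopython's NG86 on codon pairs where no stop intermediate
can arise (both conventions provably coincide there).

This is a desk-scale screen standing in for site-model likelihood tests:
it cannot identify selected sites, and at low divergence the max-pair ω of
a neutral gene frequently exceeds 1 by noise. Neutral calibration (mean ω
over 50 seeded 500-codon pairs within [0.85, 1.15]) and planted-ω ranking
are what the tests establish.

## Neighbor joining and bootstrap

p-distances are the proportion of differing sites over columns gap-free
and N-free in both rows; a pair with zero comparable sites is an error. NJ
is the canonical Q-criterion algorithm with deterministic tie-breaking (the
lexicographically smallest taxon pair); negative branch lengths are clamped
to zero with the deficit moved to the sister branch. NJ provably recovers
additive matrices; the suite checks exact topology recovery on 100 random
trees and agreement with dendropy's NJ on noisy matrices. Bootstrap
resamples columns with replacement, rebuilds the tree per replicate, and
maps split frequencies onto the full-data tree as percent supports (written
as internal node labels in Newick; taxa containing spaces are quoted).
Outgroup handling is display rooting only.

## Synthetic plastomes and evolution

The generator's defaults emulate a typical orchid plastome: LSC 87 kb, IR
26 kb, SSC 15 kb (154 kb total), background GC 0.37, 30 genes (CDS 300–
1500 bp, 30% with one intron, both strands, placed in all three region
types; a tRNA and an rRNA inside the IR are duplicated with it). Gene
payloads are drawn first and laid out sequentially per region with the
slack distributed into seeded random gaps, so placement succeeds whenever
the content fits. IRa is the exact reverse complement of IRb. Planted SSRs
and dispersed repeats are written at recorded coordinates; SSR runs are
broken at both ends so the planted locus is maximal, and the twelve
single-copy pairings beyond each IR boundary are forced to mismatch so the
planted IR is strictly maximal on the circle and detection recovers its
boundaries exactly. Same seed, byte-identical output.

Evolution along a newick guide tree applies per-site substitutions at
separate coding and non-coding rates (IR positions damped by a
configurable factor, default 0.3, mirroring the lower divergence of IRs;
tRNA/rRNA exons use the coding rate). CDS positions evolve codon-aware:
proposals creating stops are rejected; amino-acid-changing proposals are
accepted with probability min(1, ω) and synonymous ones with min(1, 1/ω) —
the 1/ω damping is what makes planted ω > 1 expressible at all, since
accepting every change of both kinds is exactly neutrality. Indels (seeded
Poisson counts, uniform lengths 1–10) fall only in spacer/intron sequence
outside planted repeats, and feature coordinates are shifted through them,
so leaf annotations stay exact. After each branch, IRa is copy-corrected
from IRb (reverse complement), emulating the gene conversion that keeps
real IRs near-identical; indels are excluded from the IR because
substitution mirroring cannot absorb coordinate shifts. Realized
substitution and indel counts are recorded per branch and per gene.

What the simulator does not model: base-composition heterogeneity along the
genome, rate variation among sites, RNA editing, gene loss and
pseudogenization, genome rearrangement, and within-array indels for tandem
repeats. Passing tests therefore establish algorithmic correctness against
planted truth and the qualitative contrasts (non-coding > coding
divergence; elevated-ω detectability; clade recovery), not performance on
the full messiness of real sequence.

## Problem sizes in tests and the acceptance script

The default test run and the acceptance script use desk-scale inputs chosen
as the package's own verification conditions: 100 sequences of 0.4–2 kb
for the dispersed-repeat oracle; 50 full-size (154 kb) genomes for exact IR
recovery; a 54 kb genome for the repeat/SSR scan quantities; four 36 kb
genomes for the variability contrast; 50 neutral 500-codon pairs and a
planted ω = 5 gene among ten for the selection screen; 100 random 6–10
taxon matrices and a five-taxon two-clade simulation with 100 bootstrap
replicates for the phylogeny stage. All randomness is seeded; the
acceptance script derives every sub-seed from its `--seed` argument.
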