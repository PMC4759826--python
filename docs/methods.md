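# Methods

`triadpart` implements an expression-partitioning analysis for allohexaploid
transcriptomes (AABBDD genomes such as bread wheat) sampled over a stress
time course. The pipeline runs in five stages: homeologous triplet
identification, SNP-diagnostic read quantification, differential-expression
and homeolog-bias testing, partitioning summaries with optional term
enrichment, and a sliding-window hotspot scan over chromosome gene orders.
A synthetic-data generator with complete ground truth backs every stage.

## Triplet identification

Up to three homeologous copies of a gene exist, one per subgenome (A, B, D).
Cross-subgenome gene pairs are scored by banded global alignment
(Needleman–Wunsch with Gotoh affine gaps: match +1, mismatch −1, first gap
base −5, each further gap base −2, band half-width 32 around the main
diagonal, widened automatically when sequence lengths differ by more). The
band is justified because homeologs are near-identical; the implementation
is verified score-identical to an unbanded affine-gap reference aligner on
randomized substitution/indel cases. Per pair we report

- identity = matches / aligned (substitution) columns, and
- coverage = aligned columns / length of the shorter sequence

and keep pairs with identity ≥ 0.90 and coverage ≥ 0.75 (both thresholds
configurable; the coverage denominator is a package choice since "coverage"
alone does not fix one). A fast prescreen skips pairs sharing no exact
21-mer; at ≥ 90% identity over ≥ 200 bp the probability of sharing none is
negligible, and unrelated pairs almost never share one.

Passing pairs form edges of a graph; each connected component with exactly
one gene per subgenome and all three pairwise edges passing becomes a
triplet. Components with zero or multiple candidates in a subgenome are
dropped without arbitration — a deliberate conservative rule, since any
within-cluster choice among recent paralogs would be arbitrary. When
chromosome names carry homeologous-group numbers (2A/2B/2D), the three
members must agree on the group; without chromosome metadata the check is
skipped with a warning.

Diagnostic SNP sites are alignment columns at which the three member
alleles are not all identical, classified as `A|BD`, `B|AD`, `D|AB` or
`all-distinct`. Equal-length members (the substitution-only synthetic case)
are compared column-wise, which makes the site truth exact; otherwise B and
D are projected onto A via the pairwise alignments and columns with gaps or
ambiguity codes are skipped.

## Read assignment and proportional allocation

Reads are located by exact 31-mer seeding against all homeolog sequences
(stride 8 across the read; with ≤ 2 substitutions in a 125-bp read the
longest error-free stretch is ≥ 41 bp, so an exact seed to the true origin
always exists). At the best end-to-end placement the read's mismatch count
against each homeolog is computed; the compatible set is the homeologs
achieving the minimum count, provided that minimum passes the two-mismatch
quality gate (otherwise UNASSIGNED). A read covering at least one
diagnostic column separating two homeologs is thereby specific with respect
to that pair; reads from SNP-free stretches fall into the shared classes.
This yields the seven logically possible compatibility classes A, B, D,
AB, AD, BD, ABD plus UNASSIGNED. Reads whose best mismatch count ties
between two triplets are discarded and logged.

Shared classes are divided among their member homeologs in proportion to
the specific counts of those members (AB splits between A and B as
n_A : n_B, ABD as n_A : n_B : n_D). When the relevant specific counts are
all zero the class is split equally — the proportional rule is undefined at
0/0, and the equal split is the unique choice that preserves both exact
conservation and label symmetry. Allocation is a single pass, not an EM
iteration: the rule prescribes one proportional division. Conservation is
exact: c_A + c_B + c_D equals the number of class-assigned reads per
(triplet, library).

The proportional rule is not a consistent estimator of per-triplet origin
proportions: specific counts are proportional to π_h times the probability
that a read from homeolog h covers a discriminating site, and that
probability varies between homeologs with the chance clustering of SNP
columns. At 2% divergence and 125-bp reads the resulting per-triplet error
is usually well below 0.02 but exceeds it for the few percent of triplets
whose SNPs cluster worst; recovery experiments measure 92–96% of triplets
within ±0.02 of the realized origin fractions depending on the random
instance. This is a property of the allocation rule itself (error-free
reads change nothing), not of read noise.

An import path for external alignments is provided (`counts_from_sam`):
alignments grouped by read, reference names mapped to triplet members, NM
tags as mismatch counts, then the same compatibility/allocation rules.

## Differential expression without replicates

The design has one library per (genotype, condition, timepoint) cell, so no
dispersion can be estimated; each stress-vs-control contrast is tested with
a two-sided Fisher exact test on the 2×2 table of (feature count, remaining
library count) in the two libraries. Fold changes are computed on CPM with
a pseudocount of 0.5 CPM on both sides to stabilise zeros (the test itself
uses raw counts and is scale-free). P-values are Benjamini–Hochberg
adjusted within each contrast family, over the features expressed (raw
count ≥ 1 in at least one library). Calls: `up` iff fold ≥ 2 and q < 0.01
(inclusive at exactly two-fold), `down` for the reciprocal gate. A
dispersion-free Fisher test is anti-conservative for overdispersed
biological replicates; here it is used exactly because the contrasts are
single-library, and its operating characteristics are measured in the
acceptance experiments (sensitivity 1.0 for four-fold effects at ~10^6
total counts; realized false-discovery proportion at q < 0.01 ≈ 0).

A triplet is *responsive* when at least one homeolog is called up or down
in at least one contrast, and shows *unequal contribution* when in at least
one contrast the three homeolog calls are not all identical.

## Homeolog bias test

Within a (triplet, library), allocated counts are tested against the
balanced 1A:1B:1D expectation with a chi-square goodness-of-fit test,
E = total/3 per homeolog, df = 2 (for which the survival function is
exactly exp(−x/2); the implementation agrees to better than 1e-12
relative). The chi-square consumes allocated counts rounded to the nearest
integer — allocation conserves totals, so rounding error is bounded by one
read per homeolog — while the expression ratio uses the unrounded values.
A triplet is flagged *biased* iff p < 0.01 and Exp_max/Exp_min ≥ 1.5, with
a zero minimum and positive maximum treated as an infinite ratio.
Zero-total triplets are not testable and are skipped. Calibration: on
truly balanced triplets at depth 300 the p < 0.01 flag rate is close to
nominal (measured ≈ 0.011–0.016), and the ratio gate can only reduce it.

Term enrichment of any study set against a population uses the one-sided
hypergeometric tail (Fisher), significant at p ≤ 0.01 with no multiplicity
correction, matching common practice for flat term sets; ontology
propagation is out of scope.

## Hotspot scan

Chromosome gene orders (from BED/GFF, or the simulator) are scanned with a
10-gene window stepped by 5 genes; each window reports the percentage of
responsive genes, and trailing windows shorter than the window size are
dropped so percentages stay comparable. Hotspots are the maximal runs of at
least three consecutive responsive genes; runs never span chromosomes.
"Consecutive" means adjacent in the supplied gene order — callers are
expected to build the order from expressed genes only, and both behaviours
(including or excluding unexpressed genes) are available by constructing
the layout accordingly. A hotspot is annotated *tandem* when at least two
members share a gene family, from explicit labels when available, otherwise
from single-linkage clustering of member sequences at ≥ 60% global
identity (a documented heuristic standing in for annotation-based
grouping).

## Synthetic data generator

The generator emulates the structure the analysis assumes, not sequencing
physics:

- **Triplets**: a random ancestral sequence per triplet; each homeolog
  substitutes each site independently with probability divergence/2 (to a
  uniformly chosen different base), so the expected pairwise difference
  fraction is 2m(1−m) + (2/3)m² with m = divergence/2 ≈ the nominal
  divergence. Substitution-only divergence keeps the three homeologs in
  shared coordinates, so diagnostic-site truth is exact single columns.
- **Expression**: homeolog proportions Dirichlet(2, 2, 2) per triplet
  (moderate bias; configurable or pinnable), log-normal triplet totals
  (log-sd 1), each homeolog independently responsive with probability 0.3,
  fold changes log-uniform on [2, 8] applied up or down in stress
  libraries; non-responsive homeologs have fold exactly 1.
- **Reads**: default design 2 genotypes × {control, stress} × 4 timepoints
  (6/12/24/48 h), 125-bp single-end reads (paired mode draws both mates of
  a 250-bp fragment), fixed count of 20,000 reads per library (Poisson
  optional; fixed-count makes conservation tests exact), uniform start
  positions, uniform substitution errors at rate 0.001, constant 'I'
  quality. Per-library generators are subseeded seed + library index, so
  adding a library never perturbs earlier ones.
- **Layouts**: ordered gene maps with planted responsive runs (length ≥ 3,
  non-touching) and independent background responsiveness; accidental
  background runs of ≥ 3 are re-rolled one flag at a time so the planted
  intervals are provably the unique maximal runs.

Not modelled: indels and structural variants, fragment-size/GC/positional
bias, quality-score-dependent errors, intergenic sequence, isoforms.
Passing tests therefore demonstrate the correctness of the assignment,
allocation, testing and scanning logic under the stated model — they do not
certify behaviour on real libraries with indel variation or biased
coverage, for which the SAM import path plus external alignment is the
recommended route.

## Numerical and degenerate-input choices

- Banded aligner scores are integers; traceback ties prefer
  match/mismatch over gap states (any optimal path yields the same score;
  identity/coverage can differ only on exactly tied paths).
- Read placement ties are broken by (minimum mismatch, total mismatch,
  leftmost offset); cross-triplet ties discard the read.
- `bh_adjust` uses a stable mergesort so equal p-values keep input order.
- Fold on CPM with ε = 0.5 CPM; empty-margin Fisher tables return p = 1.
- Zero-total libraries are rejected (CPM undefined); zero-total triplets
  are "not testable" rather than p = 1.
- All simulation randomness flows from `numpy.random.default_rng` seeded
  explicitly; identical seeds give byte-identical output files.

## Problem sizes

The shipped experiments use 200 triplets × 16 libraries × 20,000 reads for
recovery, 2,000 triplets for bias calibration, 5,500 genes for DE operating
characteristics, 600 genes / 12 planted runs for hotspot exactness, and 50
triplets + 30 decoys for the all-vs-all oracle comparison — sizes at which
every brute-force oracle remains exactly computable.
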