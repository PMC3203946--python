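# Methods

`hibernaseq` reimplements, as a tested desk-scale pipeline, the analysis of
a seasonal hibernation transcriptome experiment: three tissues (heart,
skeletal muscle, white adipose) sampled at six points of the circannual
cycle (April, August, October, January torpor, January interbout arousal,
March), sequenced as long single-end pyrosequencing cDNA reads, assembled,
mapped to a reference transcript set, counted, normalized, and tested for
differential expression with an exact test at a very stringent false
discovery rate.  A closed-form read-density model and a mitochondrial
genome reconstruction round out the analysis.  Everything runs against a
synthetic-data generator whose defaults mirror the study design, so each
stage can be scored against known ground truth without any download.

## Synthetic data

The generator (`hibernaseq.simulate`) emulates the structural features of
the study that the downstream stages depend on:

* **Design** — up to 3 tissues × 6 time points = 18 samples, each with its
  own 10-base MID barcode (pairwise Hamming distance ≥ 3, as multiplex
  barcodes are designed) followed by a 16-base adaptor pad, so the fixed
  26-base trim exactly removes both.
* **Read lengths** — trimmed lengths follow a Normal(335, 133) truncated
  below at 40 bases (a read must comfortably exceed the 36-base duplicate
  fingerprint) and capped at the transcript length.  Because of the
  truncation the realized mean is ≈ 339.6 and the sd ≈ 127; property tests
  compare against the truncated-normal moments, not the nominal ones.
* **Abundances** — baseline gene abundances are log-normal (σ = 1 by
  default); planted effects multiply one gene's abundance at one (tissue,
  time point) before renormalization, which is what "k-fold change" means
  here.  Reads are drawn per transcript proportionally to abundance ×
  (L − J̄ + 1): longer transcripts are over-represented, and deliberately no
  length correction is applied anywhere downstream, matching the original
  analysis choice.
* **Mitochondrial reads** — a per-tissue fraction of reads (defaults 0.21
  heart, 0.10 muscle, 0.02 WAT, the study-like proportions) is drawn from
  the transcript units of a 16,459-base circular genome.  The genome is
  tiled by 15 transcript units in the standard vertebrate gene order, with
  one designated overlapping pair (ATP8/ATP6-style, 40 bases).  No
  untranscribed control region is simulated: biologically the D-loop is not
  polyadenylated, but modelling it would make circle closure depend on an
  unmodelled read class; this simplification is what lets "transcript reads
  + junction fragments" determine the whole circle.  A configurable
  fraction of mito reads are windows of the unprocessed polycistronic
  primary transcript and may span unit junctions.
* **Artifacts** — emulsion-PCR artificial replicates are injected per gene:
  a chosen fraction of genes receives one cluster of ≥ 3 byte-identical
  copies of one read, always within a single sample (hence a single time
  point), with copy identifiers recorded for exact scoring.
* **Errors** — substitution errors are available but default to zero;
  error-free reads keep the assembler and filter oracles exact.
  Homopolymer-specific error structure and flowgrams are not modelled.

What passing tests on these data do **not** show: robustness to real 454
error profiles, to poly(A) tails and adaptor read-through, to chimeric
reads, or to reference databases that diverge from the sample species.
Identification rates against real versioned protein databases are
explicitly out of scope.

## Read processing

Demultiplexing is exact-prefix MID matching (mismatch-tolerant matching is
unnecessary at barcode distance ≥ 3 and would complicate the partition
contract).  Trimming removes a fixed 26 bases.  The artificial-replicate
filter groups reads by their first 36 post-trim bases (full sequence when
shorter) and collapses any group of ≥ 3 reads confined to a single time
point, keeping one representative — the longest read, ties broken by
smallest identifier — so a genuinely expressed gene keeps evidence.  The
published rule is ambiguous between "remove all" and "keep one"; both are
implemented (`keep_representative`), keep-one is the default.  Reads that
genuinely share a start position also share a fingerprint; the filter
cannot distinguish them from artifacts, which is the filter's intrinsic
property, not an implementation artifact.  The benchmark scenario therefore
uses long transcripts and moderate depth so natural fingerprint collisions
have negligible probability.

## Assembly and the mitochondrial circle

The assembler is greedy overlap-layout-consensus: repeatedly merge the pair
with the longest suffix–prefix overlap (≥ `min_overlap`, default 30; both
orientations; contained sequences absorbed), ties broken lexicographically
so assemblies are deterministic.  It is a desk-scale stand-in for a
production assembler: the analyses downstream need contigs, not parity with
any particular assembler.  Exact (error-free) overlaps are the default;
a mismatch-tolerant mode exists for error-bearing runs.

`reconstruct_mito` selects the largest contig matching each mitochondrial
gene (shared 21-mers, either strand), orders the unique contigs by the
reference gene order, merges overlapping neighbours, and closes the circle
when the terminal ends overlap; otherwise it returns a linear scaffold with
annotated gaps rather than guessing.  Coordinates are 1-based inclusive;
an interval with end < start wraps the origin.  The reconstruction length
is invariant to rotation of the planted genome's origin (tested).

At full study scale even a rare unprocessed-fragment class covers every
unit junction many times; at desk scale the benchmark keeps the expected
junction bridge count positive by raising the junction-fragment share to
0.3 at ~40× pooled coverage.  The default generator fraction stays at 0.05.

## Annotation

A complete k-mer index (k = 13) over both reference strands seeds matches;
seeds are chained per (transcript, strand, diagonal) and the densest bands
are extended without gaps under an X-drop of 20 with +1/−2 scoring.
Significance is a Karlin–Altschul e-value with the classical ungapped
nucleotide parameters (λ = 1.33, K = 0.621) over query length × database
length, thresholded at 1e-5.  Ties go to more identities, then smaller
gene id.  The transcript → gene map is a required input; no protein-level
mapping is attempted.

## Quantification and normalization

Counts are reads assigned per gene per sample.  Upper-quartile
normalization is strictly within tissue: genes with zero counts across all
of the tissue's samples are excluded, each sample's 75th percentile is
computed with linear interpolation between order statistics (the quantile
convention matters at these depths and is therefore fixed and stated), the
scale factor is sample UQ ÷ mean UQ across the tissue's samples (keeping
normalized values on a counts-like scale), and normalized counts are
rounded half-up to integers — which is why normalized tables are not
exactly additive across sub-genes.  Fold changes are ratios of normalized
counts, reported to one decimal; a zero denominator is reported as a
flagged "≥ n-fold" lower bound instead of an error.

## The exact test

Each gene in a tissue yields a 2×k table (k = 6): row 1 the gene's count
per sample, row 2 the sample's total assigned reads minus the gene's count
(the standard tag-count construction — the complement row has to be defined
somehow, and this is the definition used throughout).  Under the null the
table is multivariate hypergeometric with all margins fixed, and the
two-sided p-value is defined by probability ordering — the sum of P(T) over
tables with P(T) ≤ P(obs)·(1+ε), ε = 1e-7 absorbing floating-point ties —
the only definition that reduces to the classical two-sided Fisher test at
k = 2 (tested against scipy) and generalizes to k > 2.

Two independent exact algorithms are implemented and cross-checked:

* **Meet-in-the-middle enumeration** (row-1 totals ≤ 200): the six columns
  are split into two halves; each half's attainable (subtotal,
  log-probability) pairs are enumerated exhaustively and combined through
  sorted prefix log-sum-exp accumulators.  This enumerates exactly the same
  table space as a naive loop while staying feasible at n = 200, and it
  shares no code path with the network algorithm.
* **Network dynamic programming**: per column and remaining row-1 count,
  the log-sum, maximum and minimum of completion weights are tabulated;
  a breadth-first pass bulk-accepts subtrees whose *most* probable
  completion is already at or below the observed probability, discards
  subtrees whose *least* probable completion is above it, and descends only
  through the straddling boundary.  The final two columns are closed form:
  their pair weight is concave in the split, so the acceptance set is the
  complement of an interval found by binary search.

All accumulation is in log space; reported p-values are floored at 1e-300
(the observed table is always in the acceptance set, so p = 0 is
impossible).  R's `fisher.test` (an independent implementation of the
network algorithm) is used as an external cross-check in the test suite.

For tables too large for exact traversal the dispatcher uses, in order:
a closed-form certificate — at most C(n+k−1, k−1) tables can be at least as
extreme as the observed one and none has probability above P(obs)(1+ε), so
p ≤ count × P(obs)(1+ε) — reported as a certified upper bound when it is
below 1e-8 (conservative, hence valid in Benjamini–Hochberg); the budgeted
network pass, whose unresolved remainder yields rigorous brackets; and
finally stratified Monte Carlo (100,000 draws, add-one estimator, standard
error reported).  Monte-Carlo estimates are flagged indeterminate and are
never allowed to certify q-values below their resolution — in particular
nothing Monte-Carlo can pass the 1e-11 cutoff.

Benjamini–Hochberg q-values come from `statsmodels.multipletests` and are
re-derived by a literal step-up in the tests.  The gene list reports, per
passing gene, the peak time point and the fold change of peak over the
smallest normalized count, plus the tissue-level median and quartiles of
per-gene median normalized expression.

The raw-count path (true sample totals) is the default test input; a
normalized-integer path exists to re-derive gene lists from published
normalized tables, where raw totals are unavailable.

## Read-density model

For a transcript of length L fragmented uniformly, a read of length J ≤ L
has L−J+1 equally likely starts, and the probability that it overlaps
position I is p(I,J,L) = min(I, J, L−I+1, L−J+1)/(L−J+1) — piecewise linear
in I, symmetric, summing exactly to J over positions (each placement covers
J bases).  The expected per-base density averages these curves over the
observed read-length distribution, with lengths capped at L.  R² against
observed coverage is 1 − SS_res/SS_tot (the coefficient-of-determination
convention, not squared correlation), with the unitless density scaled to
counts by total matching; R² may be negative and is reported as computed,
and a zero-variance observed profile yields a missing value with a reason
rather than a number.  Profiles for overlapping mitochondrial gene pairs
are computed per transcript unit; such units violate the single-transcript
assumption and are expected to fit worse.

## Benchmark scenarios and problem sizes

The evaluation scenarios (`hibernaseq.scenarios`, also driven by
`scripts/acceptance.py`) use these sizes, chosen as desk-scale stand-ins
for the study's ~10⁵–10⁶ reads per sample:

* density model: exact identities on a (J, L) grid including (400, 2000);
  brute-force placement enumeration as oracle.
* exact test: 500 random 2×6 tables, row-1 totals ≤ 200, column totals up
  to 2000 — network vs enumeration, plus 200 2×2 tables vs the classical
  test.
* null calibration: 1,000 genes, 6 samples, 100,000 reads per sample,
  log-normal abundances, no planted effects; expected false positives at
  q ≤ 1e-11 are ~10⁻⁸, so the observed pass count should be 0.
* power: 20 of 200 genes planted at 8-fold at one time point, totals
  chosen so the planted peak expectation is ≈ 306 counts (just above 300);
  recovery threshold 18/20.
* replicate filter: 150 genes, 3–6 kb transcripts, 900 reads/sample,
  30% of genes given a 4-read duplicate cluster; recall and false-removal
  counts scored against recorded identifiers.
* mitochondrial circle: ~40× pooled coverage of the 16,459-base genome,
  junction-fragment share 0.3 (see above).
* published tables: the in-text normalized-count rows (MALAT1, ACOD) ship
  as package data; the MALAT1 WAT October/March ratio recomputes to 4.5.
  Full supplementary tables are accepted by
  `validate_against_supplementary` when the user supplies them.

## Known limitations

* The assembler is quadratic-ish and not meant beyond ~10⁴ reads.
* The matcher's e-values use generic Karlin–Altschul parameters, not
  database-calibrated ones; absolute significance is approximate (the 1e-5
  cutoff behaves sensibly; that is all that is claimed).
* Exact p-values for null-like tables with row-1 totals in the thousands
  are genuinely expensive; such genes fall back to Monte Carlo with an
  explicit indeterminate flag rather than silently approximating.
* The generator does not model library-preparation biases (priming,
  GC content), so density-model R² on synthetic data is an upper bound on
  what real libraries show.
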