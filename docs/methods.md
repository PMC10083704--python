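# Methods

`cooccupy` re-implements, as a reusable and fully testable pipeline, the
kind of meta-analysis used to characterise co-occupancy of zygotic
patterning transcription factors (Opa/ZIC-like and Oc/OTX-like, alongside
maternal Bcd and Zld) in the early *Drosophila* embryo: ChIP-seq peak
overlap classification, motif aggregation around peaks, histone-mark
signal matrices, gene-set overlap statistics, age-binned single-cell
co-expression, and FISH expression-domain quantification along the
anterior–posterior (AP) axis. Every stage consumes standard text formats
and has a matching synthetic-data generator with exact planted ground
truth, so the full pipeline is verifiable without any external downloads.

## Interval algebra and co-occupancy (`cooccupy.intervals`)

Peaks are 0-based half-open intervals (BED convention). Two intervals
overlap iff they share at least one base — `[0,100)` and `[100,200)` do
not overlap — matching the bedtools default used in this kind of analysis.
Strand is carried through I/O but ignored for overlap and distance, since
ChIP peaks are unstranded.

`classify_cooccupancy` merges the union of all input peak sets (touching
or overlapping intervals merge) and labels each merged region with the
subset of peak sets intersecting it, producing "X-only" and multi-factor
"overlap" classes. The output is a partition: regions are disjoint and
cover exactly the union of input peaks. Two complementary statistics are
exposed because they answer different questions: `venn_region_counts` is
region-level (how many merged regions fall in each membership class,
the Venn-diagram numbers), while `fraction_overlapping` is peak-level
(what fraction of one factor's peaks touch another factor's peaks —
the "85% of Oc peaks coincide with Opa peaks" style of statement).

Nearest-TSS annotation measures `|peak center − TSS|` with
center = `floor((start+end)/2)`; peaks within 3 kb (inclusive) are
"promoter", others "distal". Equidistant ties resolve to the
lexicographically smallest gene id so results are order-independent.

The peak-overlap chi-squared test compares observed overlap counts with
their expectation under random placement: a query peak of length L
intersects the subject set with probability ≈
`min(1, (covered_bases(subject) + n_subject·L) / G)` (each merged subject
interval is widened by L on one side). The statistic is the usual
`Σ(O−E)²/E` over the overlapping/non-overlapping cells with 1 df. This is
an approximation (it ignores chromosome edges and treats peaks as
independent); an empirical shuffle null (`shuffle_null_pvalues`, default
1000 shuffles) is provided as a cross-check. Under null simulations the
analytic p-value is close to uniform (≈5% of p-values below 0.05).
Degenerate inputs (expected count 0 or n, e.g. a subject covering the
whole genome) raise an error rather than reporting a meaningless p.

## Motif scanning and aggregation (`cooccupy.motifs`)

PWMs hold per-position probabilities over A/C/G/T with a background
composition (default uniform, configurable). JASPAR-format PFMs are read
via Biopython and normalized per column after adding a pseudocount
(default 0.5 per cell). Scoring is summed log2 odds; an `N` contributes 0
(the background identity). Scanning covers both strands by scoring the
reverse-complement matrix and reporting hits at their forward-strand
start; the match threshold is a fraction of the PWM's maximum attainable
score (default 0.8). This fractional threshold mimics HOMER-like known-
motif scanning without reimplementing its internal score calibration; de
novo motif discovery is deliberately out of scope — the module quantifies
known or user-supplied matrices, which is what the downstream figures
(motif fractions per peak subset, aggregation histograms) consume.

Peak sequences are extracted as fixed-length windows (default 200 bp)
centered on peak centers; lowercase (repeat-masked) genome bases become
`N`, and windows truncated at chromosome edges are N-padded so all
sequences have equal length. Motif prevalence uses ZOOPS counting (a peak
is positive if it has ≥1 hit). Aggregation histograms (default ±1000 bp,
50-bp bins) bin each hit's center (`match start + L//2`) by distance from
the region center; all overlapping hits are counted (simple histogram
semantics), and both raw-sum and per-region-normalized modes are
available (raw is the default).

## Signal matrices (`cooccupy.signal`)

Coverage is a step function (the bedGraph model): sorted non-overlapping
intervals with float values, implicitly 0 elsewhere. bedGraph is the
canonical format here because text fixtures make tests bit-exact; a
bigWig reader can wrap the same track type. Window sums use a cumulative
integral per chromosome, so `mean_signal` and `compute_matrix` are exact
(no sampling) and O(log n) per query. Reference-point matrices use the
region center, with length-weighted bin means counting uncovered and
out-of-chromosome bases as 0 (missing data is 0, not NaN, matching
deepTools behaviour). Defaults are ±2000 bp flank and 50-bp bins, both
configurable. Heatmap ordering follows the first-sample convention:
regions sort by descending row mean of the first matrix, the same
permutation applies to all samples, and ties break by region id so the
order is deterministic.

## Gene-set statistics (`cooccupy.genesets`)

Overlap between a peak-derived gene set and (say) a differential-
expression list is tested with the one-sided enrichment tail of the
hypergeometric distribution over a declared universe — Fisher's exact
test for the 2×2 table (a two-sided mode is available by flag). Term
enrichment against offline GMT collections intersects each term with the
universe, computes the same tail p, adjusts across all tested terms with
Benjamini–Hochberg (the FDR procedure is a declared choice and labelled
as such), and reports the top k (default 10) by FDR with deterministic
tie-breaking (p, then term id). `−log10(FDR)` is capped at 300 when the
FDR underflows. Offline GMT input replaces live ontology services for
reproducibility. Note one direction that can surprise: with the overlap
and set sizes held fixed, *growing* the universe makes the enrichment p
smaller (the overlap becomes more surprising), not larger.

## Age-binned co-expression (`cooccupy.coexpression`)

Each nucleus carries a continuous developmental-age score (produced
upstream by a neural-net age predictor; this package consumes, never
computes, the score). Scores are binned to integers; the source methods'
"rounded up to the nearest integer" is self-contradictory, so the default
is round-to-nearest with halves away from zero, and `rounding="ceil"`
gives the literal reading. Raw counts are averaged per bin — no
normalization is applied by default because the upstream tables are raw
count matrices — and bins with zero cells are omitted rather than
reported as 0, to avoid fabricating expression values. Co-expression uses
the double-positive rule: a cell is positive iff it has ≥1 count for
*both* query genes. Window counts use half-open age intervals
`[lo, hi)`; group age distributions are summarized by linear-interpolation
quantiles (min, 2.5%, 25%, 50%, 75%, 97.5%, max).

## Embryo AP profiles (`cooccupy.embryo`)

Images are assumed pre-aligned (AP axis along x, anterior at x = 0) with
an upstream segmentation mask; rotation, registration and segmentation
are out of scope. Channel intensities are averaged over masked pixels in
10-px slices (configurable) tiling the masked span; the terminal partial
slice is kept so the embryo is fully covered. Profiles are normalized
per channel to their own maximum. A domain call is the longest contiguous
run of slices at or above a threshold (default half-max), with boundaries
reported at the run's outer slice *edges* in % egg length. The edge
convention is deliberate: the true boundary falls inside the adjacent
partial slice (whose mean dips below half-max), so edge reporting keeps
every boundary within one slice width of truth, whereas slice midpoints
systematically pull boundaries inward by up to 1.5 slices. Overlap extent
between two domain calls is the clipped intersection length in % egg
length. Nuclei-level co-expression counts double-positive nuclei and the
number of distinct AP column ranks they occupy, with x positions
quantized by a user-supplied nucleus diameter (counts in nuclei, not
pixels).

## Synthetic data (`cooccupy.simulate`)

Every generator is deterministic per (seed, parameters) and emits a
serializable `GroundTruth` record. Wherever the downstream statistic is a
count or fraction, the generator plants an *exact count* rather than a
probabilistic expectation, so recovery tests are equality tests:

- `gen_peak_sets` places exactly `round(fraction·n_a)` query peaks to
  intersect a subject peak and rejection-samples the rest to avoid the
  subject; peaks within a set are kept ≥1 bp apart so normalization
  preserves counts.
- `plant_motifs` plants a consensus into exactly `round(fraction·n)`
  sequences at recorded offsets; a single-letter background alphabet
  disjoint from the consensus makes spurious matches impossible.
- `gen_scrna` draws ages uniformly, counts negative-binomially around
  per-gene age-dependent mean curves, then forces exactly the requested
  number of in-window cells to be double-positive and knocks every other
  in-window cell out of double-positivity.
- `gen_embryo_image` builds an elliptical mask with logistic-edge (or
  hard-step) expression domains at stated % egg length boundaries.
- `gen_coverage` sums triangular bumps discretized to 10-bp steps with
  optional zero-truncated Gaussian noise; `gen_gene_sets` plants an exact
  set overlap inside a universe.

What the generators emulate — and what they do not: peaks are uniform,
non-clustered, and fixed-length (real peaks cluster in open chromatin and
vary in width); sequence backgrounds are i.i.d. (no repeats or
composition domains); single-cell counts have no ambient contamination,
doublets, or depth variation; embryo images have ideal masks and
separable axes. Passing recovery tests therefore demonstrates
correctness of the *computations*, not robustness to every artifact of
real data.

## Default study conditions and problem sizes

The verification suite and `scripts/acceptance.py` run at these sizes,
chosen to match the statistics they exercise: planted peak-overlap
fractions {0.10, 0.50, 0.85} and {0.85, 0.83} with n = 2000 peaks of
200 bp on a 20-Mb single-chromosome genome; per-base oracle comparisons
on 100-kb genomes with up to 600 peaks across 2–4 sets; the exhaustive
Fisher sweep over all 2×2 tables with universe ≤ 60; motif checks on 50
random 2-kb sequences (6–8 bp PWMs) and 500 aggregation regions with
N(0, 50 bp) plant offsets; 10,000 cells with 45 planted co-expressing
cells in the age window [1, 3); and 120×400-px embryos with 10-px slices.
The co-expression surge uses a Gaussian mean-count curve peaking at age
bin 6 with amplitude 5 counts/cell, sd 1.2 bins, baseline 0.05 and NB
dispersion 2 — a realistic zygotic-gene surge under which the trajectory
peak bin is recovered in ≥19/20 seeds.

## Known limitations

- The chi-squared expectation model is approximate; use the shuffle null
  when subject coverage is a large genome fraction.
- De novo motif discovery, motif p-value calibration against genomic
  background models, assembly liftover, peak calling, live ontology
  queries, segmentation, and the age-prediction network itself are all
  out of scope; their outputs are inputs here.
- `fraction_overlapping` is undefined (raises) for an empty query set.
- GO-style term enrichment treats terms as flat sets (no DAG
  propagation).
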