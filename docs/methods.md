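# Methods

## The estimation problem

Shotgun metagenomic profilers that classify every read report *sequence
abundance* — the fraction of reads per taxon — which conflates genome
size with cell count. `markerprof` instead targets *taxonomic
abundance*: the fraction of genome copies (equivalently cells, assuming
one genome copy per cell) per species, estimated directly from the
coverage of universal single-copy marker genes. The profiler is built
for long reads: a single read long enough to contain a complete marker
gene can be classified on its own, and the marker-region reference can
be aligned against with ordinary nucleotide alignment rather than
k-mer heuristics.

Two reference layers are used, mirroring their strengths:

1. a **protein marker database** (eight ribosomal protein genes, RPGs,
   per prokaryotic domain) against which reads are searched in
   frame-shift-aware blastx mode — highly conserved, so marker
   *detection* and genome-copy *counting* are robust to sequencing
   error and taxonomic novelty;
2. a **nucleotide window database** of up to 10 kb regions flanking
   each marker occurrence in reference assemblies — variable enough to
   resolve species.

## Genome-copy estimation

For each marker protein sequence we form the positional coverage
vector over its amino-acid positions 1..L from the filtered hits, then
take a trimmed mean over the central 50% of positions (positions
`floor(0.25 L)+1 .. ceil(0.75 L)`; the leftmost and rightmost 25% of
positions are sliced off). The trimming is positional, by coordinate,
not an order-statistic trim: with the default 75% subject-cover cutoff
every retained hit spans the whole central window, so the trimmed mean
is *exactly* the number of mapped hits. Marker-gene coverage is the sum
of its constituent sequences' trimmed means, and the total genome
copies of a domain is the arithmetic mean of its eight marker
coverages (absent markers contribute zero). Bacteria and archaea are
estimated separately with their own 8-gene sets and summed for a
prokaryotic total.

Two consequences worth noting:

* the detection floor is one read: a species seen through a single
  marker-containing read receives 1/8 ≈ 0.125 genome copies, a limit
  set by the marker count, not by relative abundance;
* the estimator is linear in the hits, so sequencing depth scales the
  estimate but never distorts ratios.

## Hit post-filtering

Protein hits are filtered per query by a greedy overlap cull: sort by
e-value ascending (ties: higher bitscore, then input order) and keep a
hit iff its query-range overlap with *every already-kept* hit is below
25% of the shorter of the two ranges. Overlap is computed on closed
1-based nucleotide intervals as `max(0, min(b,d) - max(a,c) + 1)`.
Because a candidate is compared only against kept hits, a hit that
overlaps a *discarded* hit can still survive — the greedy rule, not a
pairwise-disjointness rule. Multiple copies of one gene on a query may
survive when they occupy distinct ranges.

For database construction two further filters apply: a **boundary
filter** drops hits whose distance from either contig end (measured
from the nearer hit endpoint) is less than the subject length in
nucleotides (3 × the amino-acid length; the factor converts units
because the distance lives on the nucleotide contig), and a
**best-hit-per-marker** rule keeps, per contig and marker, only the
highest-identity hit (ties: lower e-value, then input order).

## Window extraction

Each surviving hit anchors a window of 5 kb flank on either side of
the hit's center (floor midpoint of the query range, 0-based
half-open coordinates). Windows are clipped — never shifted — at
contig ends, so a window near an end is shorter rather than biased
toward one flank. Windows are grouped by (species, marker) and exact
duplicates dropped. Similarity clustering of windows within a group
(the published pipeline compresses at ~one mismatch per 5 kb) is an
external clusterer's job and out of scope here.

## EM reassignment

Reads aligned to marker windows often hit several related species
near-tied. Per read-species pair only the best alignment is retained
(ranked by alignment score AS, local-best score MS, gap-compressed
identity ID, descending). An alignment is *valid* if at least one of
the strict inequalities holds against the read's maxima:
`AS > 0.99·max AS`, `MS > 0.99·max MS`, or `ID > 0.999·max ID`.
Valid pairs form a binary n×k read-species matrix x (k counts only
species with ≥1 valid alignment, so the uniform initialization
θ⁽⁰⁾ = 1/k is over actual candidates).

EM then iterates

* E-step: `z_ij = x_ij θ_j / Σ_j x_ij θ_j`
* M-step: `θ_j = Σ_i z_ij / n`

until the L1 change of θ falls below ε (default 1e-5) or t_max = 100
iterations. θ components below 1e-12 are clamped to zero and θ
renormalized — numeric hygiene that never changes a detectable
species. The observed-data log-likelihood `Σ_i log Σ_j x_ij θ_j` is
non-decreasing across iterations (standard EM guarantee; asserted in
the tests at 1e-9 slack).

Each read is finally hard-assigned to `argmax_j z_ij`. Ties are broken
by a deterministic total order: larger z, properly named species over
placeholders (a bare "*Genus* sp." loses to a binomial name), larger
AS, then MS, then ID, then lexicographic species id. Genome copies are
apportioned to species by assigned read counts
(`copies_j = total_copies · n_j / n`); marker reads that obtained no
species-level alignment fill a reserved *unclassified* row which is
excluded from the relative-abundance normalization.

## Marker selection statistics

Candidate RPGs are screened on an assembly panel by:

* **universality** — fraction of assemblies with ≥1 copy;
* **deviance** — |mean copy − 1|, the mean over *all* assemblies of
  the panel, zeros included (an absent gene and a duplicated gene can
  cancel; universality catches the former);
* **F0.5** of the gene's annotation model,
  `1.25·p·r / (0.25·p + r)` — precision-weighted because a false
  marker annotation costs more than a missed one.

Thresholds (universality > 0.99, deviance < 0.01 in both the full
panel and the tiny-genome (<1 Mb) subset; F0.5 > 0.99) must hold
before clustering. Genes surviving the screen are single-linkage
clustered on their mean relative genomic distances — per circular
assembly, the shortest circular distance `min(|p−q|, L−|p−q|)/L`
(minimum over copy pairs; never exceeding 0.5), averaged over
assemblies where both genes occur — and cut at 0.05 (strict <; the
cut equals connected components of the sub-cutoff graph). Co-located
genes are redundant for coverage estimation under bidirectional
replication, hence one representative per cluster, ranked by higher
universality, lower deviance, higher F0.5, then gene id.

## Evaluation metrics

Profile comparisons use: per-sample x/y ratio (estimated over expected
total genome copies), Pearson correlation over sample totals,
species-set precision/recall (TP = species present in both profiles,
unclassified rows removed) with F1 the standard harmonic mean
`2pr/(p+r)`, and four dissimilarities on union-aligned renormalized
abundance vectors — L1, L2, Bray–Curtis, Jensen–Shannon distance with
base-2 logs (hence ≤ 1). All four are delegated to
`scipy.spatial.distance`.

For profilers that report base pairs (or read counts) per taxid, a
hierarchical genome-size database converts them to copies: each
internal taxid's size is the unweighted mean of its descendant leaf
genome sizes, species missing a size walk up to the lowest sized
ancestor, and read counts are converted at the sample's mean read
length. Plasmids and other extrachromosomal elements are treated as
single-copy in the sizes.

## ARG quantification

Antibiotic-resistance-gene abundance is expressed as **copies per
cell** = ARG copies / total genome copies, the denominator coming from
the marker-based estimate. For host attribution, each ARG read keeps
only its single best host alignment (AS, MS, ID order); a read is
dropped if that alignment's species is absent from the taxonomic
profile, if its source is plasmid or virus (mobile elements would
mis-attribute hosts), if its family is flagged multidrug (multidrug
efflux pumps are not antibiotic-specific), or if its best score ties
across references with different source labels (conservative drop —
the ambiguity is unresolvable).

## Synthetic data generator

The generator emulates the profiler's *inputs* — alignment records —
rather than sequences: base-level error simulation lives upstream of
the tested core and is out of scope. A community of k species draws
taxonomic abundances from LogNormal(μ=0, σ=1) normalized to sum one;
genome lengths are uniform on 2–6 Mb (a typical prokaryotic range);
genome copies are θ scaled by a total (default 100). Taxonomic
abundances convert to sequence abundances as `θ_j L_j / Σ θ_j L_j`.

Each species emits `round(copies · reads_per_copy)` marker-containing
reads, spread over the eight markers by a seeded multinomial; the
per-species totals are deterministic so the depth-copies relation is
exact. Every read yields one full-cover protein hit (making the
trimmed-mean/hit-count identity hold) and one true nucleotide
alignment with AS = MS = 1000, ID = 0.99. At the default depth of
eight reads per genome copy, the estimated total equals the planted
total exactly (one read per marker per copy).

Ambiguity: the community's ambiguity graph pairs consecutive species
into disjoint symmetric edges — window sharing is a symmetric
relation, so reads of *either* partner may carry a near-tied alignment
to the other (probability `ambiguity_frac`, default scores 0.996 of
the true AS/MS and ID 0.9895, inside all three validity thresholds;
both offsets are configurable to exercise the invalid branch too).
Under this symmetric confusion model the planted θ is exactly the EM
fixed point, so recovery error reflects only finite-sample noise.

What the generator does *not* emulate — read-length and quality
distributions, chimeras, within-species strain variation, reference
incompleteness, conservation differences between markers — bounds what
passing tests show: they validate the estimator and its
post-processing, not robustness to real-data artifacts.

## Numerical and interface choices

* Trim boundaries `floor(0.25 L)+1 .. ceil(0.75 L)` are fixed so
  results are bit-stable across platforms.
* PAF identity: the `de:f` (gap-compressed divergence) tag is the
  primary source (`ID = 1 − de`); without it, matches /
  alignment-block-length (columns 10/11) is used — a slight
  underestimate in gapped alignments, noted because aligner versions
  differ in tag output. The generator always writes `de:f`.
* The protein-hit dialect is the standard 12 blastx tabular columns
  plus `qlen` and `slen`, declared explicitly because homology-search
  tools let the user reorder columns freely.
* Profile rows are ordered by copies descending then lexicographic
  lineage; all writers are deterministic byte-for-byte under a fixed
  seed.
* Problem sizes in the test-suite and the reproduction script (32
  species, ≈10⁵ reads, 10⁴ randomized filter instances) were chosen as
  the smallest sizes at which the statistical checks are comfortably
  away from their noise floors.

## Known limitations

* Species absent from the window database can only land in the
  unclassified row; the profiler never invents taxa but under-calls
  novel ones.
* Copies are apportioned by read counts, not per-marker coverage
  shares; for a species whose reads pile onto few markers the split
  between co-detected species can differ slightly from a
  coverage-share apportioning.
* The EM model treats the valid-alignment row as given support and
  ignores how likely each support set is under each true species;
  asymmetric confusion structures therefore bias θ slightly (the
  symmetric generator is unbiased by construction).
* Growth-rate (peak-to-trough) coverage skew is not corrected; marker
  dispersion around the chromosome mitigates but does not remove it.
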