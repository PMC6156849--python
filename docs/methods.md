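# Methods

## Splicing graphs

A gene's transcript structures are represented as a directed acyclic graph.
All exons of all isoforms are decomposed into disjoint subexonic segments at
every distinct exon boundary; each segment contributes a start node and an
end node (node identity is chromosome, strand, position, side) joined by an
exonic edge. Consecutive exons within an isoform contribute junction edges
(end node of the upstream exon → start node of the downstream one); abutting
segments of one exonic run are joined by zero-length adjacency edges, which
carry no genomic span and no signal of their own. A virtual source and sink
are attached to every transcript's first and last boundary. Coordinates are
0-based half-open internally (GTF I/O converts from/to 1-based inclusive);
minus-strand genes are ordered in transcription direction, so "first exon"
always means 5′, and unstranded input is treated as plus strand.

Graphs can also be built from data alone: junction rows (intron interval +
per-sample counts) become junction edges when their FPKM reaches 2 in at
least one sample; exon-bin coverage at ≥ 0.5 FPKM defines expressed regions,
which are cut at junction boundaries into exonic edges. Junction FPKM uses
an effective length of read_length − 2·min_anchor + 1 (default 100 − 2 + 1 =
99): a junction is only observable from reads spanning it with at least
`min_anchor` aligned bases on each side. The exact junction-FPKM convention
of upstream graph builders varies; this one is documented and configurable.
Data-driven graphs carry no isoform map; a junction whose boundary falls in
no covered region is logged and kept as a novel exon boundary.

## Event enumeration

An event is a minimal bubble between a divergence node s and a reconvergence
node t. Traversal units are the annotated isoforms (annotation mode) or all
source→sink edge paths (data mode). For each ordered node pair, units
passing through s then t are grouped by their s→t subpath ("bundles"); an
event requires at least two bundles, no internal node shared by every
subpath (this enforces both the latest divergence and the earliest
reconvergence, i.e. minimality), and edge-disjoint sides. With exactly two
bundles those are Path 1 and Path 2; Path 1 is the one with the larger
transcriptomic length (total exonic bases), ties broken by genomic order of
the leftmost footprint coordinate. With more than two bundles the event is
collapsed to a single binary *complex* event: candidates for Path 1 are
tried in (bundle size, then path rank) order and the first candidate whose
edge set is disjoint from the union of the remaining bundles wins; if no
split is edge-disjoint, no event is emitted. Bubbles where one side has no
material edge (an isoform that simply terminates at the divergence) are not
emitted — such a "path" has no measurable signal. The reference path is the
nearest exonic edge upstream of s and downstream of t shared by every
traversing unit (segmented flanking exons therefore contribute their
nearest shared segment). Alternative first/last exon events arise naturally
with the virtual source/sink as s or t.

Classification is structural, on the unordered pair of material-edge kind
signatures, and therefore invariant to swapping Path 1 and Path 2:
cassette = {junction, exonic, junction} vs {junction}; intron retention =
{exonic spanning I} vs {junction spanning I}; alt 5′ = {exonic, junction}
vs {junction} sharing the downstream node (alt 3′ mirrored upstream; the
transcription-ordered graph makes these strand-aware automatically);
mutually exclusive = two {junction, exonic, junction} paths with disjoint
exons; divergence at the source (convergence at the sink) = alternative
first (last) exon; anything else, including all >2-bundle collapses, is
complex.

For matching, a path's genomic footprint is the union of its exonic spans
plus two 1-bp anchors per junction at the donor and acceptor ends, so a
junction-only path (e.g. the skipping path of a cassette) still occupies
genomic positions and the containment test below is well defined.

## Ψ estimation

Path signals are summarized as the arithmetic mean of the member edges'
per-sample values (FPKM for sequencing, linear probe-set signal for
arrays). The measurement model S_i = a_i·t_i with t_R = t_1 + t_2 gives
S_R = u·S1 + v·S2 with u = a_R/a_1, v = a_R/a_2, and

    Ψ_j = u·S1_j / (u·S1_j + v·S2_j)

per sample j (undefined, and excluded from ΔΨ averages, where the
denominator is zero). (u, v) solve the non-negative least-squares problem
whose rows are the n per-sample signal equations plus three penalty rows
[λ, −λ]·x ≈ 0, [λ, 0]·x ≈ λ, [0, λ]·x ≈ λ, expressing that affinities of
the three paths should be similar and near 1. The Lawson–Hanson active-set
solver returns the global minimizer of this (for λ > 0 strictly) convex
problem.

λ defaults to 0.1 × RMS(S_R): the penalty must be commensurate with the
signal rows or a common rescaling of the data would change the estimate.
When the event is differentially spliced the data rows pin down u and v and
the estimate is insensitive to λ; when Ψ is constant across samples the
problem is poorly determined and the estimate does depend on λ — both
behaviors are asserted in the tests. Signals enter on the linear scale
(the model is additive in concentrations), and all-zero events degenerate
to u = v = 1 with a flag. The relative residual ε = ‖u·S1 + v·S2 −
S_R‖₂/‖S_R‖₂ measures coherence with the additive model; in noisy
simulations the top-50% ε stratum shows markedly worse Ψ recovery than the
bottom half, which is what makes ε useful as a reliability filter.

## Differential-splicing statistics

Sequencing counts are summed per path and transformed to
y = log2((count + 0.5)/(library + 1)·1e6); row-wise residual standard
deviations under the study design are paired with mean log2 counts, a
lowess trend of √sd versus log-count is fitted, and each observation's
weight is its predicted √sd to the −4th power (below 50 rows the trend is
unreliable and unit weights are used, with a warning). Array signals enter
as log2(signal + 0.5) with unit weights. The design is additive (blocking
factor such as cell line + treatment, no interaction); a rank-deficient
design is rejected naming the collinear columns.

Each path is fit by weighted least squares and the contrast of interest
extracted. Residual variances are shrunk towards a common prior fitted by
method of moments on log variances (prior degrees of freedom d0 via the
trigamma inverse; d0 = 0 reduces to the ordinary t-test, d0 → ∞ to a fixed
variance); one prior is shared by both path strata. The moderated t has
d0 + d degrees of freedom.

The event-level call uses p_summary = max(p1, p2) — an intersection–union
test: the event changed only if *both* paths changed — together with the
direction requirement sign(logFC1) = −sign(logFC2) ≠ 0. Significant:
opposite directions and p_summary < 0.001; non-significant: same direction,
or p_summary > 0.2; inconclusive otherwise. Fisher and Irwin–Hall
combinations are available as configurable alternatives to the max rule.
π0 is Storey's single-point estimator at λ = 0.5 (adequate for m ≥ 1000);
FDR(t) = π̂0·m·t/#{p ≤ t} and q-values are the usual step-up
monotonization. Read-depth decimation replaces each count by a
Binomial(count, fraction) draw and rescales library sizes, deterministic
under an explicit seed.

## Filters

Sequencing events are retained only if every splice junction on Path 1 and
Path 2 reaches 2 FPKM (≥, "at least") in at least one sample. Array events
are retained if each alternative path's signal strictly exceeds ("more
than") the array-wide 25% quantile of all reference-path signals in at
least one sample; the quantile uses linear interpolation (type 7). Each
path is tested against the threshold individually rather than averaged —
a weak probe-set on either path makes the event unreliable. Both filters
are idempotent and monotone in their thresholds.

## Cross-platform matching

Events reduce to interval sets A (longer path), B (shorter), R (reference).
Containment (x ⊂ y) means every base of x lies in the union of y, evaluated
on genomic projections on the same strand (sequence-level substring search
would differ only for pathological repeats); reference overlap requires at
least one shared base. A pair matches when A↔A and B↔B are each mutually
containing and the references overlap, or with A and B crossed — covering
near-ties where the platforms ordered the paths differently. Many-to-many
matches are retained by default; an option keeps, per event, the pair with
maximal reciprocal footprint overlap. Candidate pairs are pre-filtered by
overall span overlap. Matched pairs are cross-tabulated by significance
class with unmatched/missing margins.

## Synthetic data

The generator produces data at two levels. At the *signal* level, an event
with known per-sample Ψ*, total concentration t_R, affinities (hence known
u*, v*) and multiplicative log-normal noise (S = a·t·e^N(0, σ²), σ =
noise_cv) exercises the Ψ estimator directly. At the *read* level, a gene
model with isoform concentrations in FPKM units produces junction and
exon-bin count tables: the expected count of a feature is concentration ×
effective length × library/1e9, drawn Poisson by default (negative binomial
with configurable dispersion available).

The default study cohort is 500 cassette-exon genes, two conditions × five
replicates, at a library size of 4.9e7 reads per sample — the average
sequencing depth of the kind of deep bulk cohort the study design emulates
— with gene expression log-normal around 20 FPKM (sd 1.2 on the log scale, a
typical expressed-gene spread), baseline Ψ uniform in [0.15, 0.85], and 30%
of events differential with |ΔΨ*| drawn from [0.3, 0.6] between conditions.
Depth decimation studies thin these counts to 10% and 30%. The two-platform
simulation reuses one splicing truth: the sequencing platform sees read
counts, the array platform sees signal-level data with its own affinities
and noise.

What the generator does *not* emulate: multi-event genes and overlapping
gene loci, positional read biases (GC, fragmentation, mappability),
cross-hybridizing probes, unannotated transcripts, and correlated
biological replicate structure beyond the condition effect. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under the stated generative model, not robustness to every artifact of real
libraries or arrays.

## Numerical choices and degenerate inputs

NNLS penalties guarantee strict convexity for λ > 0, so ties cannot occur;
Ψ with a zero denominator is missing (NaN), not zero. ε is undefined (and
the event flagged) when S_R ≡ 0. Tie-breaks in path ordering (Path 1/A
assignment) use transcriptomic length, then the leftmost footprint
coordinate, then the full footprint — fully deterministic. Events are
deduplicated within a gene on their unordered (Path 1, Path 2) edge-set
pair. All stochastic operations take explicit seeds; identical seeds give
byte-identical tables. Problem sizes in the test and acceptance runs
(500–2000 gene cohorts, 200-gene oracle sweeps, 100 grid-search instances)
were chosen as the package's own desk-scale defaults: large enough for the
stochastic assertions' tolerances, small enough to run in about a minute.

## Known limitations

Complex loci with deeply nested or >2-way alternatives are reduced to
binary complex events rather than decomposed recursively. Data-driven
graphs enumerate all source→sink paths, which can over-generate
pseudo-isoforms in very tangled graphs (capped, with a warning). The
summarized p-value's max rule is conservative; no bootstrap intervals are
provided for Ψ; and matching performs no coordinate liftover — both
platforms must share a genome build.
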