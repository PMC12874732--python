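# Methods

This note documents the models, algorithms and design choices behind
`taxaflow`, in the order data flows through the package.

## Scope and data model

The central object is the stratified functional profile: a matrix of RPKM
values indexed by (EC function, taxon lineage) with one column per sample.
Lineages use the rank-prefixed semicolon dialect
(`d__...;p__...;c__...;o__...;f__...;g__...;s__...`); all seven ranks are
always materialised, with an explicit `unassigned` placeholder where a
classifier left a rank empty, so genus- and phylum-level grouping never
depends on string heuristics. The reference experimental design is 7
treatment groups × 3 replicates (five organic soil amendments plus unamended
Control and undisturbed Natural soils, 21 samples), but nothing in the code
is specific to that shape.

## Pathway panels

The nitrogen (map00910, 39 EC numbers) and phosphonate/phosphinate
(map00440, 31 EC numbers) panels ship as frozen TSV fixtures (gene symbol,
EC, process) reflecting a KEGG snapshot (2024-06) rather than live REST
queries — reproducibility without a network dependency. Composite symbols
(`gltBD`, `napAB`, `norBC`, `nirKS`, `narGZHYIV`, `nifDKH`, `phnGHIL`,
`pmoABC-amoABC`) group subunits or isofunctional genes that share an EC, so
the EC → symbol map is a partition and per-symbol contribution percentages
sum to exactly 100. `phnGHIL` is EC 2.7.8.37 (the "12.7.8.37" sometimes seen
in print is not a valid EC number). Process labels follow the figure-level
groupings of the two pathways (eight nitrogen processes from ammonium
assimilation to nitrogen fixation; five phosphonate processes from C-P-lyase
degradation to phospholipid biosynthesis); membership is an editable fixture,
and user panels can be supplied as TSV.

## Synthetic data generator

The generator's role is to provide ground truth for every downstream stage,
not to imitate real genomes.

* **Genomes** are i.i.d. base sequences at a requested GC fraction, organised
  in a genus/species hierarchy. *Phantom* taxa receive genomes too — the
  verification scenario is precisely "a reference exists but the reads do not
  belong to it".
* **Reads** are drawn uniformly from genomes chosen by per-sample Dirichlet
  abundances, with a substitution-only error model (per-base rate,
  default 1%). Indels, chimeras and platform quality profiles are out of
  scope; substitutions are what stress an identity threshold.
* **Classifier output** relabels each read independently to a uniformly
  chosen phantom species with the configured misassignment probability
  (default 5%), recording the truth of every call.
* **Planted RPKM tables**: each cell is
  `baseline(gene, genus) × multiplier(treatment, gene[, genus]) × exp(N(0, σ))`,
  with the most specific multiplier key winning and zero baselines staying
  exactly zero ("function not detected"). Default σ = 0.1 (≈ 10% replicate
  noise); the planted-share recovery checks use σ = 0.05.

The default designs are calibrated once to the study conditions of the
reference pathway figures: for nitrogen, 32 of 39 ECs detectable, gene shares
glnA 47%, gltBD 12%, gudB 5%, gdhA 4%, pmoABC-amoABC 4%, napAB 2%, nosZ 2%
with the remaining 24% spread over 25 minor genes, and per-treatment mean
totals from 520 (Natural) to 759 (COHort+SS) RPKM; for phosphonate, 17 of 31
ECs, shares phnJ 41%, phnW 20%, phnGHIL 12%, pmmS 7%, PPT 4%, totals 31–69
RPKM. Baselines are an outer product (gene mass × genus weight), and each
treatment's planted dominant genus is boosted ×3 across *all* genes of that
genus. Because the boost scales a whole genus column uniformly, gene shares
are provably invariant to it, so the calibration hits the share targets and
the total targets simultaneously and exactly at σ = 0. A single seed fans
out to per-stage `SeedSequence` substreams, so changing one stage's
parameters does not perturb another stage's stream.

What passing tests on these data do **not** show: robustness to real genome
composition (repeats, conserved operons shared across genera), classifier
errors that are correlated rather than i.i.d., or compositional effects in
real RPKM tables.

## Coverage verification

Reads are pooled per (species, treatment) — replicates unioned, because the
decision rule operates "within any one treatment". The built-in mapper
indexes the reference's exact 31-mers and, for each read (both strands,
every seed offset, first success wins), extends the seed to an ungapped
alignment; a read is confirmed at identity ≥ 0.90 over ≥ 0.80 of its length.
Both knobs are configurable; the per-read criterion is a package choice, as
the upstream rule only fixes the 50% confirmed-fraction cutoff. A hook
accepts externally computed per-read mappings for real data, where one
representative genome per species is expected. Coordinates are 0-based
half-open throughout, which makes interval-union breadth arithmetic
unambiguous. On genomes up to 10 kb the mapper's confirm/reject decisions
are tested equal to an exhaustive sliding-window oracle at the same
thresholds.

Genus rule: a species passes in a treatment iff breadth ≥ 1% OR (assigned
reads ≥ 100 AND confirmed fraction ≥ 50%); boundaries are inclusive. The
default `any_species` mode confirms a genus when any species passes anywhere
(the reading consistent with "did not have enough reads mapped … to pass our
cutoff"); `all_species` implements the stricter grammatical alternative.
The 100-read minimum counts classifier-assigned reads, not confirmed ones;
this too is configurable. Species without a reference are reported
`unverifiable`, never dropped. Breadths in [0.1%, 1%) carry a trace-presence
annotation with the covered-base count.

## Functional profiling

Replicate aggregation sums columns into one per treatment (grand totals
preserved to machine precision and tested at 1e-9 relative); pathway
subsetting keeps rows whose EC belongs to the panel; the two operations
commute. Detection counts panel ECs with RPKM strictly > 0 in any sample —
an exactly-zero RPKM means absent. Contribution percentages group EC rows by
gene symbol and are invariant to uniform rescaling. Per-treatment pathway
totals report mean ± standard error over replicates (s.e. chosen over s.d.
for consistency with how such summaries are usually printed; configurable by
computing from the returned replicate totals); a single replicate yields a
mean with the s.e. flagged unavailable. The noise filter zeroes cells below
a threshold and drops all-zero rows; the default threshold is 0 (off), since
published Sankey figures set it per figure.

## Multivariate statistics

Bray–Curtis (Σ|x−y| / Σ(x+y)) serves abundance profiles; Euclidean,
optionally on z-scored columns, serves soil properties. Distances are
computed with scipy and validated (symmetry, zero diagonal, non-negativity);
a pair of all-zero samples is an error naming the pair.

PERMANOVA uses the sum-of-squares decomposition given in the README. The
p-value convention is (1 + b) / (1 + m) — the observed statistic counts as
one permutation, so p is never 0 — and permuted statistics tying the
observed count as extreme (conservative). When the number of distinct
relabelings (groups of equal size counted unordered, matching the "free
permutations" semantics of a two-group test) does not exceed the requested
permutation count, full enumeration replaces sampling and the p-value is the
exact tail fraction: a 3-vs-3 pair has C(6,3)/2 = 10 free permutations and a
minimal exact p of 0.10. The pairwise Monte-Carlo fallback reports an
additional p from 10 000 relabelings drawn with replacement; this
approximates, but is not asserted equal to, the moment-matched asymptotic
construction of the commercial package that popularised the test, whose
algorithm is unpublished. With SS_within = 0 the pseudo-F is reported
infinite with p still from permutations; an all-zero distance matrix is
flagged degenerate. Exact enumeration is tested against a brute-force
all-relabelings oracle on every design with n ≤ 8, the sampled branch is
calibrated (type-I error within [0.03, 0.07] at α = 0.05 over 500 null
simulations of the 7 × 3 design), and pseudo-F is cross-checked against an
independent implementation.

PCoA double-centres −d²/2 (Gower), eigendecomposes, and keeps positive
eigenvalues; axis variance fractions divide by the positive-eigenvalue sum
by default (the `absolute` denominator is exposed as an option, since usage
varies when negative eigenvalues are present). Sign convention: the first
nonzero loading of each axis is non-negative, making output deterministic.
On Euclidean distances PCoA provably reproduces classical PCA variance
fractions, which is tested to 1e-9.

NMDS minimises Kruskal stress-1 by alternating isotonic regression of
configuration distances on the dissimilarity rank order with a Guttman
majorization step. The recorded stress sequence is non-increasing by
construction (an update that fails to improve terminates the restart,
keeping the previous configuration, flagged unconverged). The first start is
the PCoA configuration; the remaining restarts (default 8 total) are random.

The correlation screen computes Pearson r with two-sided t-test p per
(gene, soil property) cell on pairwise-complete observations (missing values
are NaN), flags p < α (default 0.05, no multiple-testing correction — the
screen is descriptive), and marks cells with < 3 pairs or a zero-variance
side undefined.

## Flow tables

Genus "abundance" for top-N selection is summed pathway RPKM (consistent
with flow-diagram edge weighting), ties break lexicographically for
deterministic output, and unassigned-genus rows are excluded. Edges carry
the RPKM sum per (treatment, genus, process) over the treatment's selected
genera only, so each treatment's edge total equals the pathway total of its
selected genera exactly (tested at 1e-9); with all genera selected and
threshold 0 the flow table is a lossless regrouping of the stratified table.
ECs without a process label route to `unclassified` with a warning. Flags
from verification annotate every genus as confirmed / potentially_spurious /
unverified.

## Problem sizes

The test suite and acceptance script run desk-scale versions of the study
conditions: 20 true + 5 phantom genera on 10 kb genomes at 1 000 reads per
sample across 21 samples and 20 seeds for phantom recovery; 500 null
simulations at 999 permutations for PERMANOVA calibration; full planted
tables (≈ 390 rows × 21 samples) for the profiling and flow stages. These
sizes were chosen so each property is measured with comfortable statistical
margin on a single CPU.

## Known limitations

* The mapper is ungapped and k-mer seeded; reads whose best alignment
  contains no exact 31-mer are rejected by construction. This is part of the
  confirmation definition, not an approximation bug, but it makes the rule
  conservative for highly divergent reads.
* Multi-factor and nested PERMANOVA designs, PERMDISP, and plot rendering
  are out of scope; outputs are coordinate and flow tables.
* Panel process groupings are editorial fixtures; users with different
  pathway readings should edit the TSVs.
* The synthetic generator's independence assumptions (i.i.d. bases, i.i.d.
  errors, per-read independent misassignment) make recovery benchmarks an
  upper bound on real-data performance.
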