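# Methods

This note records the models, statistical procedures, parameter choices and
known limitations of `triplextad`, in enough detail that a reader can judge
what the test suite does and does not establish.

## Triplex site model

Triplex formation is modelled purely at the sequence level; thermodynamic
stability, pH dependence and cytosine protonation are out of scope.

**Target tracts.** A candidate triplex target site (TTS) is a maximal run of
windows of width `min_length` (default 20 nt) whose purine fraction on one
strand reaches `min_purine_fraction` (default 0.9). Both strands are
scanned; a tract is reported on forward coordinates with the strand carrying
the purines. `N` counts as neither purine nor pyrimidine. Because window
unions define the tract, a tract may extend a few bases into mixed flanking
sequence; the per-window criterion, not the merged interval, carries the
purity guarantee.

**Binding codes.** The RNA third strand reads the purine strand of the
duplex through one of three codes:

| motif      | orientation  | code            |
|------------|--------------|-----------------|
| pyrimidine | parallel     | U/T→A, C→G      |
| purine     | antiparallel | A→A, G→G        |
| mixed      | antiparallel | G→G, U/T→A      |

**Matching.** For each (transcript, tract, motif) pair, an ungapped
alignment window qualifies when its length ℓ ≥ `min_length` and its mismatch
count ≤ ⌊`max_error_rate` · ℓ⌋ (default rate 0.05; the floor is computed
with a 1e-9 guard against binary-float underestimation; unmappable RNA bases
and DNA `N`s always mismatch). On each alignment diagonal only
containment-maximal windows are kept (no sub-site enumeration). Windows of
one (transcript, tract, motif) group that overlap on the tract — shifted
alignments of near-homopolymeric sequence — are merged into one site
spanning the union of their tract and RNA extents, with the minimum mismatch
count among the merged members. After this merge the genomic and RNA extents
of a site may differ in length by the diagonal spread; this is the one place
the per-window length identity is deliberately relaxed, in favour of
coverage semantics and a bounded site count.

The implementation restricts matching to candidate RNA segments (runs of
`min_length` windows with at most ⌊rate · L_max⌋ unmappable bases, L_max the
longest tract): any qualifying alignment window lies inside such a run, so
the restriction is lossless; the test suite verifies exact agreement with an
exhaustive substring-pair enumeration on hundreds of random and planted
pairs.

**Isoforms.** For genes with several isoforms, the isoform with the largest
TFS count is kept; ties break to the lexicographically smallest id.

## Shuffle enrichment test

Observed coverage is `|union(sites) ∩ union(regions)|` in bp. The null is
built by re-placing the sites uniformly at random in the genome (chromosome
chosen proportionally to valid placement space, preserving the site-length
multiset; placed sites may overlap), 1000 times by default; a constrained
mode places sites only inside a given region set minus exclusions. The
shuffle distribution is fitted with a normal; z = (obs − mean)/sd and the
one-sided upper-tail p are reported, with a `< 1e-16` sentinel past floating
precision. The Anderson–Darling normality check warns rather than fails
(scipy's interpolated p-value caps at 0.15, meaning "≥ 0.15").

**The shuffled unit is the distinct genomic footprint.** Sites of many
lncRNAs stack on the same polypurine tract. Re-placing each stacked site
independently produces a null with systematically larger union coverage
than the observed clustered configuration, so the test would report strong
*depletion* under a true null. The wrappers (`tad_enrichment`, the pipeline,
the CLI) therefore merge sites to maximal unique intervals before shuffling;
the observed statistic is unchanged (coverage is union-based), and the null
then permutes exactly the objects the statistic is computed from. Null
calibration (factor-1 systems) confirms approximately uniform p-values. The
positional KS and CTCF chi-square statistics sample the same deduplicated
footprints for the same reason; per-lncRNA counts are retained for feature
matrices and annotation densities, where the stacking is the quantity of
interest.

## Positional, correlation, and CTCF statistics

In-TAD site midpoints are mapped to relative positions
(mid − start)/length ∈ [0, 1); the 5-bin histogram is reported for display
and the two-sample KS test runs on the raw relative positions (KS on five
binned frequencies is ill-posed; a `binned` mode exists for completeness).
The size–coverage analysis computes Pearson r between TAD length and
coverage/length; constant normalised coverage returns r = 0 by documented
convention, constant lengths raise. TFS→CTCF distances are
midpoint-to-midpoint (0 on overlap); the 4 bin edges are quantiles of the
pooled real+randomised distances and the two histograms are compared with a
chi-square homogeneity test.

## Annotation

Element tracks derive from gene models: promoter = strand-aware
[TSS − 1000, TSS + 100); 5′/3′UTR = exonic sequence outside the CDS span;
exon = exonic CDS; intron = transcript minus exons; intergenic = the rest.
Each site is labelled by its midpoint under the priority promoter > 5′UTR >
3′UTR > exon > intron > intergenic (configurable). Density per class =
count / merged same-class track length × 10⁴ (sites per 10 kb); same-class
overlaps are merged before length summation, and cross-class overlaps are
resolved only for labelling, not subtracted from track lengths.

## TAD classification and importance

Background regions reuse the exact TAD length multiset, placed longest-first
uniformly over the remaining free space (genome minus TADs minus already
placed intervals), so TAD overlap is impossible and failure occurs only when
packing is genuinely infeasible; generation refuses genomes more than 75 %
covered by TADs, where a size-matched background is not meaningful. Features
are any-overlap TFS counts per (region, lncRNA), columns restricted to
lncRNAs with ≥ 1 site in ≥ 1 TAD (a fixed column universe including all-zero
columns is available for importance null checks). Models are tuned by
accuracy with stratified 5-fold CV on a stratified 80 % split and reported
on the untouched 20 %; split bookkeeping is exposed so leakage is testable.

Target-shuffling importance permutes one test-set column, recomputes
accuracy with the fitted model, and averages the drop over 25 repeats
(configurable; 1 reproduces the literal single-shuffle procedure). Constant
columns score exactly 0. Permutation importance of **correlated** features
is not guaranteed positive — permuting one of several redundant columns can
leave predictions unchanged or improve them by chance — so the importance
*recovery experiment* plants a minimal non-redundant set (two informative
lncRNAs reading two disjoint tract families) and fits the forest with
`max_features = 1.0` so every split sees the informative columns. This is a
property of the importance estimator, not of the implementation.

## Synthetic study systems

The generator emulates the statistical structure the analysis assumes, not
real chromatin. Defaults: 3 chromosomes × 500 kb; 30 TADs of 10–16 kb
(≈ 26 % genome coverage); boundary flank 10 kb (boundaries exactly 20 kb);
anchors at half the boundaries; polypurine tracts at 150/Mb outside TADs and
3× that inside, drawn as lightly mutated copies (2 % per base) of 6 tract
families of 20–30 nt; 100 lncRNAs of 0.5–1.5 knt with TFD counts 0/1/2/3 at
probabilities 0.568/0.277/0.113/0.042 (matching the observed preponderance
of lncRNAs with no or few domains); 7 cell lines with lognormal TPM blocks
(expressed ≈ 50 TPM, silent ≈ 0.5, log-sd 0.25); CTCF at 60/Mb in
boundaries vs 15/Mb elsewhere; 40 non-overlapping gene models. Per-cell-line
TAD sets are jittered copies of the canonical set (±3 kb edges, 10 % domain
loss), so cross-cell-line shared-site analysis has realistic partial overlap.

Deliberate departures from a naive reading of the real system, each with its
reason:

* **TAD coverage ≈ 26 %, not ≈ 50 %.** At desk scale the size-matched
  non-overlapping background must pack into the inter-TAD gaps; at 50 %
  coverage with gaps comparable to TAD lengths this is frequently
  infeasible. Real genomes escape this through scale. Coverage is
  configurable; the guard against > 75 % mirrors the exclusion of
  heavily-covered systems from the classification analysis.
* **Tract families.** Real lncRNA domains bind thousands of genomic sites
  because target tracts recur; independent random tracts would give each
  planted domain ~1 target. Family copies reproduce the one-domain-many-
  sites structure that the feature matrices and enrichment tests rely on.
* **Mild CTCF boundary preference (4×).** The analysis context reports TFS↔
  CTCF distance histograms indistinguishable from random; an extreme
  boundary concentration would contradict the phenomenon being emulated.
* **Nonspecific expression clusters default to 0.** Flat TPM rows carry no
  correlation signal after z-scoring, so they cannot be recovered by
  clustering; they can be enabled (`n_nonspecific_clusters`) when cluster
  recovery is not being scored.
* **Controlled informative sets.** When `n_informative` is set, informative
  lncRNAs take families round-robin (lncRNA *i* reads family *i* mod *F*),
  making planted features minimally redundant for recovery experiments.

What passing tests on this generator do **not** show: robustness to GC/
mappability confounders, nested or overlapping real TADs, isoform
quantification noise, transposon-driven tract families, or any
thermodynamic aspect of triplex formation.

## Expression analysis

Expressed means TPM strictly > 5. Rows are z-scored (population sd; constant
rows map to zero vectors and keep their alignment); clustering is
agglomerative with correlation distance and average linkage — chosen as a
transparent, pluggable stand-in for hierarchical ordered partitioning, whose
exact tree ordering is incidental because only the flat labels feed the
downstream ANOVA — with k chosen by silhouette over 2–12 when not fixed.
Zero-vector rows get distance 1 to everything and 0 to each other. The
one-way ANOVA of a per-lncRNA triplex statistic across clusters uses scipy;
identical constant groups return (0, 1) by convention.

## Numerical and procedural choices

* Coordinates are 0-based half-open everywhere, including BED I/O.
* All randomness flows from explicit seeds through named child streams; a
  config digest is embedded in pipeline reports, and reruns are
  byte-identical.
* Mismatch budgets use ⌊rate·ℓ⌋ with a 1e-9 floor guard.
* Equidistant nearest-gene ties break to the smaller gene id; "within a
  domain" means full containment (any-overlap available via a flag).
* Problem sizes in the canned experiments (150 kb–2 Mb genomes, 8–90 TADs,
  200-shuffle nulls, 50-run studies) are chosen so each study completes in
  minutes on one CPU while keeping the checked fractions inside their
  binomial confidence bands.

## Known limitations

The site predictor is a documented simplification of specialised triplex
alignment tools: no guanine-rate or duplicate-merging heuristics, no
thermodynamic score, and no attempt at bit-for-bit agreement with any
external tool. Enrichment nulls condition only on site lengths and counts,
not on sequence composition. The ANOVA treats lncRNAs as exchangeable across
clusters. Gene Ontology / pathway enrichment of nearest genes is out of
scope, as is any processing of Hi-C contact maps.
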