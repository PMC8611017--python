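# Methods

`mrevo` reconstructs the clonal architecture of a tumour from multi-region,
multi-timepoint bulk sequencing: somatic SNV calling and clonality
stratification, VAF-based clone trees, haplotype-phased allele-specific
copy number with detection of mirrored subclonal allelic imbalance (MSAI),
minimum-event copy-number phylogenies, and per-biopsy molecular risk
calls.  This note records the models, the defaults and why, the numerical
choices, and what the bundled synthetic cohorts do and do not establish.

## Somatic variant calling

Each tumour/normal site passes three filters: tumour VAF >= `t_candidate`
(0.10), matched-normal VAF < `t_control` (0.05), and an upper-tail
probability below `p_max` (0.001) under a beta-binomial model of technical
mismatches fitted to a panel of normals.  The error model is a per-site
(or pooled) method-of-moments fit: the mismatch mean comes from pooled
counts with a 0.5/1.0 pseudocount, the overdispersion from the per-sample
mismatch-fraction variance after subtracting the expected binomial
component; a non-positive overdispersion estimate degrades the model to a
pooled binomial (implemented as concentration 1e6).  The full
empirical-Bayes machinery of panel-based callers (per-site priors shared
across the genome) is deliberately out of scope; the simplified fit keeps
the same three-filter decision structure.

## Expected VAF and clonality stratification

The mixture model underlying every VAF computation is

    VAF = ccf * rho * m / (rho * C_t + 2 (1 - rho)),

with purity `rho`, cancer-cell fraction `ccf`, tumour total copy number
`C_t` at the site and mutation multiplicity `m`.  A variant is *present*
in a sample when its VAF clears a per-sample threshold

    t_s = 0.10 * E[VAF | clonal het, rho_s, C_t(s)] / 0.30,

i.e. the 10% rule anchored at the expected VAF of a clonal heterozygous
mutation in a diploid region at 60% purity (0.30) and rescaled
proportionally for local copy number and purity.  Presence testing uses
m = 1 (heterozygosity assumption; conservative under gains).  A variant is
clonal when present in every sample of the patient, subclonal-specific
when present in exactly one, subclonal in between; a called variant
clearing the threshold nowhere is reported as `absent` rather than
forced into a category.  Sites not covered by any segment are treated as
diploid and flagged.  The same raw-VAF rule is applied to whole-exome and
ultra-deep targeted counts alike; the adjustment formula, not a
platform-specific rescaling, absorbs copy-number differences.

## Purity estimation and VAF clustering

Purity per sample is twice the median VAF of the highest-mean component of
a one-dimensional binomial-mixture pre-clustering over copy-number-neutral
variants (components under 5% weight are ignored as noise; the estimate is
clipped to (0, 1]).  Fewer than 5 usable variants fall back to the
user-supplied purity with a warning.

Joint clustering across samples uses a K-component binomial mixture fitted
by EM (multiple seeded restarts, default 10; convergence at relative
log-likelihood change < 1e-6 or 500 iterations; components below 1e-3
weight pruned).  Model selection minimises BIC over K = 1..20; the scan
stops after three consecutive worsenings.  Observed zero VAFs are floored
at 1e-10 and success probabilities clamped away from {0, 1}, so
likelihoods stay finite when many entries are exactly zero.  Cluster
centres convert to cellular fractions as CF = clip(2 theta / rho, 0, 1);
purity scaling is applied after clustering, when centres are interpreted.
Variants outside diploid segments do not influence the fit; they are
attached afterwards to the nearest centre in CF space and flagged.

## Clone-tree rules

Clusters become clones by explicit rules: clusters with CF > 90% in every
sample merge into the founding clone; the rest are organised by their
sample-presence patterns (CF >= 5%), each clone's parent being present in
the same and potentially more samples; single-sample clusters become
leaves; branch lengths are SNV counts.  Clusters sharing one presence
pattern stay distinct clones chained in decreasing mean CF.  Parent
search is deterministic: candidates must contain the child's presence set
and CF-dominate it (candidate CF >= child CF - 0.05 in the child's
samples); within a shared presence pattern only the chain bottom (lowest
mean CF) is a valid attachment point — its ancestors are interior to the
chain — and remaining ties resolve by smallest presence set, larger mean
CF, then id.  The dominance filter and chain-bottom rule exist because a
"largest CF wins ties" rule alone would glue every deep clone to the
trunk: the trunk, at CF ~1, wins any tie among full-presence candidates,
making subtrees below a chain unreachable.  Clusters with no superset
parent attach to the trunk flagged `unplaced`; sibling CF sums exceeding
the parent by more than 0.05 are reported as warnings, never silently
adjusted.  Patients with fewer than 5 SNVs of non-zero median VAF yield an
explicit insufficient-signal result instead of a tree.  Samples annotate
at their deepest contained clone; a sample containing clones from more
than one branch is flagged as clonally intermixed.

## Joint segmentation, reference phasing, MSAI

Per-sample allele-specific segments combine into one joint segmentation
per patient: breakpoint union, states carried onto refined intervals,
runs identical in every sample merged back.  Intervals not covered by
every sample are dropped with a warning.

Phasing is anchored per joint segment on a reference sample with
significant allelic imbalance.  Because the B-allele label of each
germline SNP is arbitrary, within-sample imbalance cannot be tested by
pooling raw B counts; the test statistic is the pooled majority-allele
count sum(max(b, n-b)) compared against its exact null moments under
BAF 0.5 (normal approximation across SNPs, one-sided).  Among significant
samples (p < 0.01) the reference maximises |folded BAF - 0.5| * sqrt(total
depth).  SNP B-alleles with BAF > 0.5 in the reference define haplotype A;
all samples' pooled haplotype-A fractions are then computed on that fixed
phase, with exact binomial tests against 0.5 for the non-reference
samples (the reference keeps its folded p-value — its phased test would
be self-selected).  Segments with fewer than `min_snps` (10) SNPs or no
imbalanced sample stay unphased, which is a state, not an error.
Haplotype copy numbers start A-major; `correct_cn_states` flips samples
whose significant phased BAF contradicts the orientation, never altering
totals.  An MSAI event is a phased segment where at least one sample
significantly favours haplotype A and at least one favours B (each at
p < 0.01, >= 10 SNPs).  No multiple-testing correction is applied within
a patient, matching the descriptive use of these calls; a Bonferroni
option exists in the significance threshold parameter.

## SCNA event classes and summaries

Against baseline b = round(ploidy): deep loss (total 0), LOH (one
haplotype absent, total <= b — includes copy-neutral LOH), amplification
(total >= 2b + 1), gain (b < total < 2b + 1), else neutral.  The
amplification cutoff 2b + 1 and the 50% band-coverage rule for cytoband
aggregation are package choices, both configurable.  A segment is a
clonal SCNA when every sample carries the identical non-neutral class (a
3-copy and a 4-copy gain count as one clonal gain), subclonal when
altered in some samples or with discordant classes.  Genome fractions use
the total tiled autosomal length as denominator.  Chromosomes classify as
unchanged / whole-chromosome / segmental: whole-chromosome requires every
maximal equal-class run to span >= 95% of the chromosome's tiled length.

## Minimum-event copy-number phylogeny

The directed distance between haplotype vectors is the minimum number of
contiguous segmental +-1 events, computed per chromosome by a scanline
over the difference signal (gains and losses are sums of positive
increments of their respective parts; zero-copy segments act as barriers;
events never span chromosome boundaries).  A transformation requiring a
regained allele is infeasible.  An exhaustive BFS over event sequences is
the test oracle; the scanline agrees with it on every checked pair
(exhaustive through length 4, sampled at lengths 5-6).

Trees are NJ on the pairwise symmetrised distance (minimum of the two
feasible directions) with an all-ones diploid pseudo-sample as root and
negative branch lengths clamped to zero.  Mutually infeasible pairs —
complementary losses — are routed through a segment-wise *meet*
pseudo-ancestor (min where both positive, otherwise the non-zero value):
the meet retains every shared event, so the distance stays on the scale
of the true path length.  An arbitrary large penalty here erases
shared-branch signal and demonstrably scrambles NJ topologies.

NJ returns strictly binary trees, and parallel events hitting the same
chromosome in independent lineages mimic roughly one to two events of
shared signal, so reported clades require an internal branch of at least
2 events (`tree_clades(min_branch=2.0)`); shorter resolutions are treated
as polytomies.  The triangle inequality is *not* asserted anywhere: it
genuinely fails under loss irreversibility.

Ancestral states come from a per-segment, per-haplotype Sankoff dynamic
programme (unit cost per copy step, infinite cost for 0 -> positive,
root fixed diploid, ties toward the smaller copy number); branch event
counts are then recomputed with the contiguity-aware distance.  Jackknife
support drops 50% of joint segments per replicate (100 replicates),
rebuilds the tree and scores each original clade by containment; the
resolution filter is off for replicate containment, which is a topology
question.  No whole-genome-doubling events and no tree search beyond NJ:
this is a deliberate simplification of doubling-aware minimum-evolution
methods.

## Ultra-high-risk calls

A biopsy is TMM-positive with any of: high TERT expression, MYCN
amplification, TERT rearrangement, ALT.  Pathway mutations (TP53 or
RAS-MAPK, configurable gene lists) with VAF strictly above 5% are UHR
mutations.  UHR = TMM-positive AND UHR mutation; TMM-positive alone is
HR_TMM; otherwise TMM_negative.  When no boolean is supplied, MYCN
amplification derives from the 2p24-locus total copy number via the
amplification rule.  Missing telomere indicators count as negative and
are flagged.  A patient is heterogeneous when biopsies disagree;
timepoint-annotated cohorts additionally report whether UHR status was
acquired or lost across timepoints.  Both the per-biopsy view and the
patient-level union are emitted, since a subclonal pathway mutation's
patient-level weight is a judgement call left to the reader.

## Synthetic cohorts

The generator emulates the full input structure with known truth on a
22-autosome genome of equal 100 Mb chromosomes.  Clone trees grow by
uniform attachment (both linear and branched shapes).  CCFs are
stick-broken per sample, children sharing the parent's stick against a
parent-retained share of Dirichlet weight 0.5 — subclone sweeps that
replace most of the parental population, without which deep clones sit
at undetectable ~1% CCF — and clones may be zeroed per sample together
with their descendants (sample-private clones).  A fixed-design escape
hatch accepts planted trees and CCF matrices.  Copy-number events are
Poisson per branch (default 1.0): whole-chromosome with probability 0.3,
otherwise focal with geometric run length (mean ~2 segments); 10% of
focal gains escalate to high-level amplification (+3..14 copies); losses
clamp at zero and lost haplotypes are never regained.  Mirrored gains are
planted per segment with probability `msai_probability` on two disjoint
clades.  Read counts: depth ~ Poisson around the platform coverage (346x
exome-like, 2500x targeted-like), alt counts binomial at the closed-form
expected VAF; germline het-SNP B counts binomial at the haplotype-specific
BAF of the sample's *dominant clone* (the deepest clone above 50% CCF)
mixed with normal cells, with a per-SNP coin flip assigning the B allele
to a haplotype, as in real unphased data.  Matched-normal and
panel-of-normals counts use a 0.002 technical error rate — small enough
that the p < 0.001 filter, not the candidate thresholds, is the operative
test.  Default purity range (0.6, 0.95) mirrors the common >60%
tumour-cell-content selection floor for macrodissected regions; it is a
floor, not a measured distribution.

Simplifications to keep in mind: per-sample segment tables and SNP BAFs
condition on the dominant clone (a clonal approximation within samples),
SNV multiplicity follows the dominant clone's haplotype copy number only,
and there are no FFPE artefacts, mapping errors, GC waves or capture
biases.  Cross-platform concordance on synthetic cohorts (~97-99%) is
therefore higher than the ~88% seen in real WES-vs-targeted comparisons,
and passing recovery benchmarks demonstrates correctness of the
algorithms under the generative model, not performance on real tumours.

## Benchmark operating points

`mrevo.benchmarks` measures recovery at fixed, documented conditions
(also used by `scripts/acceptance.py`):

* clone-tree/cluster recovery: 20 cohorts, 3 samples, 5 clones, 500x,
  purity 0.6-0.9, *identifiable* CCF designs — pairwise CCF gaps >= 0.15
  in at least one sample, entries clear of the 5% presence cutoff, no
  non-root clone above 0.85 everywhere, and presence patterns that
  determine the tree.  Note that a pair separated by exactly 0.15 in a
  single sample sits at the statistical detection limit: on such draws
  even the Bayes-optimal assignment only reaches ARI ~0.90.
* MSAI: two biopsies dominated by disjoint clades, purity 0.7, 50 SNPs
  per segment at depth 100; sensitivity over 100 planted mirrored gains
  and false events over 1000 balanced segment-samples.
* copy-number trees: 50 planted 7-clone trees, 110 segments, 3 events
  per branch, samples at the leaf clones, defining branches carrying at
  least 3 events (one above the stated resolution limit); topology
  compared by rooted Robinson-Foulds distance.  Jackknife support is
  checked on two clades separated by five single-chromosome events each.

Problem sizes (20/50/100 replicates, 110 segments, coverage as stated)
are the package's benchmark definitions; each function accepts larger
values.

## Known limitations

No indels, no sex chromosomes, no whole-genome doubling, no
overdispersed (beta-binomial) mixture clustering, no joint
multiplicity/CCF deconvolution, no statistical phasing from population
panels, no recurrence significance testing across patients.  Manual
review steps of interactive workflows are replaced by machine-readable
warnings and flags.
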