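# Methods

## The estimation problem

A full-sib mapping cross consists of two outbred parents and their
offspring, genotyped at haplotyped, SNP-containing loci. Because the
parents are outbred, loci fall into the five CP segregation types
(ab×cd, ef×eg, hk×hk with both parents heterozygous; lm×ll and nn×np with
one): a locus carries linkage information only for the parents that are
heterozygous at it, and the hk×hk heterozygous offspring class does not
reveal which parent transmitted which allele. The package's job is to
estimate pairwise linkage from such data, assemble and order linkage
groups, merge two family maps into a consensus, and tie the resulting map
to comparison genome assemblies.

## Two-point likelihood and EM

Per offspring and locus we encode the set of (maternal allele index,
paternal allele index) transmissions compatible with the observed genotype
as a 4-bit mask. For a locus pair, a parent contributes an informative
meiosis only if heterozygous at both loci; given a linkage phase per
informative parent, the offspring probability is (up to a constant) the
sum over compatible transmission combinations of r^R (1−r)^(K−R), with K
the number of informative parents and R the recombinant meioses in the
combination. A single sex-averaged r is estimated: maximizing separate
male/female fractions per pair is not identifiable for one-parent pairs,
and the sex-specific maps are instead obtained by restricting which
parent's meioses count (`scope="female"|"male"`).

The E-step takes the expected number of recombinant meioses per offspring
under the current r; the M-step divides by the informative meioses.
Identical (mask, mask) offspring patterns are pooled, so an EM iteration
costs O(distinct patterns) ≤ 256 regardless of family size. Phases are
handled by enumeration (≤ 4 configurations); the reported result is the
phase with the highest maximized likelihood, ties broken toward coupling,
and a pair whose runner-up phase is within 0.1 LOD is flagged
phase-low-confidence. LOD is log₁₀ L(r̂, phase) − log₁₀ L(½), which is
phase-independent at r = ½.

Numerical choices: r initialized at 0.25; convergence requires both
|Δ log L| < 1e-6 and |Δr| < 1e-7 (near r = ½ the likelihood is flat while
r still drifts; the dual criterion keeps the EM within 1e-3 of a 1e-4
brute-force grid, which the test suite checks); iteration cap 2000;
estimates below 1e-7 are reported as exactly 0. Estimated r̂ is clamped to
[0, 0.5] and LOD to ≥ 0.

## Grouping, ordering, QC, positions

Grouping is the transitive closure of pairs with LOD ≥ 6 and r ≤ 0.35
(connected components; groups numbered by smallest member locus id;
singletons are reported unplaced, not mapped).

Ordering minimizes a strictly lexicographic criterion over adjacent pairs:
(1) total expected crossovers Σ n_informative·r̂, (2) −Σ LOD (a two-point
surrogate for the multipoint likelihood), (3) map length Σ d(r̂). All
three terms are sums over adjacencies, so a full ripple pass is cheap and
every term is invariant under order reversal; orientation is fixed by
putting the smaller terminal locus id at 0 cM. The seed order grows by
greedy insertion from the highest-LOD pair of loci informative in both
parents; remaining loci are inserted at their best position; a sliding
window of 4 then tries all window permutations until a pass accepts
nothing. Adjacent pairs with no shared informative parent (a
maternal-only next to a paternal-only locus) have no direct two-point
estimate; their cost and, later, their cM increment come from the
shortest-path completion of the pairwise distance matrix, i.e. the linkage
information flowing through flanking loci. Vetoing such adjacencies
outright (the obvious alternative) systematically distorts orders on
mixed-informativeness groups.

Order QC, applied once per group and followed by re-estimation and
re-ordering:

- **Tight double-crossovers.** Parental transmissions are phased along the
  chain of that parent's informative loci (all pairs are estimated, so
  one-parent loci of the other sex do not break the chain). A single
  resolved transmission disagreeing with agreeing neighbors within 10 cM
  is a genotyping-error signature and the call is set to missing. Masking
  runs only in the first QC pass: iterating it cascades (each pass strands
  new calls between farther neighbors) and was measured to deflate
  simulated map lengths by ~20%. The 10 cM window balances missed errors
  (which inflate the map, ~+35% at a 4 cM window under the simulator's
  0.5% error rate) against masking genuine close double crossovers
  (~−25% when unbounded).
- **Excess crossovers per individual.** Individuals above
  mean + 3 SD of per-LG crossover counts are removed, guarded by a
  Bonferroni Poisson upper tail (p < 0.05/n at λ = mean): the bare z-rule
  would cull the natural right tail of clean data.
- **Large gaps.** An adjacent gap > 20 cM is closed by removing whichever
  flanking locus closes it (terminal flanks trivially); unclosable gaps
  are reported in the diagnostics.

Positions are cumulative: cM(i) = cM(i−1) + d(r̂ᵢ) with Kosambi
d = 25 ln[(1+2r)/(1−2r)] by default or Haldane d = −50 ln(1−2r) by
configuration. Kosambi is the conventional default of the mapping-software
lineage this pipeline follows; under the simulator's no-interference
crossover process Haldane is the generative truth, and the residual
difference at typical marker spacing is below the error-driven noise. An
adjacent r̂ = 0.5 raises an ordering-failure error rather than producing an
infinite distance.

Loci with byte-identical call vectors (zero observed recombination,
missingness pattern included — the conservative reading, since identity is
untestable at missing entries) are collapsed before estimation; the
lexicographically smallest locus id represents the bin and the passengers
are re-attached at the representative's final position, so map totals
count them.

## Marker QC

Filters are applied in the order individuals (≤ 50% missing) → locus call
rate (≥ 90%) → minor allele frequency (≥ 0.05, recomputed within the
family over parental plus offspring alleles, the only option without the
upstream cohort) → segregation distortion (Pearson χ² against the
Mendelian ratio of the segregation type, genotype classes — so 1:2:1 for
hk×hk — with the Bonferroni denominator equal to the number of loci tested
in the current map build). Every removal is logged with its reason.

## Consensus

Conflicts are shared loci whose relative order against another shared
locus is opposite between the two family maps (linkage groups matched by
maximal shared-locus overlap; ties are an error, not a guess). Each round
removes conflicted loci — most-conflicted first, and only until every
opposite-ordered pair involves a removal (a greedy cover; removing every
conflicted locus outright was measured to strip half of small simulated
maps) — from the map with the larger zero-recombination cluster (an
unclustered locus counts as cluster size 1; ties removed from map B,
logged). Up to three rounds; surviving conflicts are reported, never
silently dropped. Because removed loci are co-positioned with their
cluster mates, removal cannot change the surviving loci's relative order
or adjacent recombination fractions, so "re-ordering" after removal
reduces to re-anchoring positions at 0.

Merging solves one LP per linkage group: variables are consensus positions
for the union of loci plus one absolute-deviation variable per
(locus, map) incidence; the objective is the mean |consensus − component|;
constraints are each map's order chain (strictly ordered pairs separated
by ε = 0.01 cM — below map resolution, preventing degenerate collapse;
co-positioned pairs equal). Two refinements keep the post-resolution
system feasible by construction: ties are chained in the *other* map's
order, and a tie whose members the other map strictly orders is relaxed to
a non-strict inequality instead of an equality. One global LP per linkage
group is used (no interval/window parameterization — a deliberate
simplification). Solved with HiGHS via `scipy.optimize.linprog`; the
achieved MAE is reported per LG. A locus that lost both family-map
positions during resolution is restored at a surviving cluster mate's
consensus position (logged per locus), so the consensus always contains
the union of component loci.

## Synteny

Anchor assignment (the hit-filtering step is this package's own rule, as
such criteria are rarely published): per locus and genome, the top-bitscore
hit is kept iff its e-value ≤ 1e-10 and its bitscore exceeds the best hit
on any other chromosome by more than 10% of itself; otherwise the locus is
unanchored for that genome. Both thresholds are configuration keys.

Blocks are found by a left-to-right scan of each linkage group's anchored
loci (map order): a run breaks at a chromosome change or a bp-direction
reversal. A reversing locus closer (in cM) than tolerance × LG length to
the neighbor it conflicts with is skipped and logged — the mismatch is
ignored, the block is not split, and the skipped locus is not a member. At
a genuine break, the closing run's last member joins the new run when it
lies nearer in bp to the incoming locus than to its own predecessor; this
attributes the boundary locus of an inverted segment to the inverted run,
matching the ground-truth segmentation of the simulator exactly
(precision = recall = 1 at tolerance 0 in the acceptance suite). Runs
shorter than 2 loci are not blocks. Orientation is the sign of the bp
trend; block cM spans are flank-to-flank.

Per-genome statistics: block and locus counts, averages, total/average
spans in Mb and cM, and the proportion of the map covered
(100 × merged cM spans / total map length, overlaps merged within each LG
before summation; a cross-genome union coverage is computed the same way).

Feature placement anchors external sequences by the same best-unique-hit
rule; a feature whose bp falls within a block's span is placed at the
bp-fraction linear interpolation between the two flanking mapped loci
(exactly a member's bp → that member's cM). Features supported by several
genomes report every placement with the smallest-evalue one marked
primary — this package's tie rule, exposed rather than hidden. Placements
cluster along each LG by single linkage with a configurable gap.

## The simulator, and what passing tests do not show

`simdata` generates: a true map (first locus of each LG pinned at 0 cM,
the rest uniform); full-sib families in which each offspring receives one
recombinant gamete per parent with crossovers from a Poisson process (one
event per Morgan — Haldane's no-interference model, chosen because it
makes the simulator analytically checkable: the observed recombinant
fraction at d cM converges to (1 − e^(−d/50))/2, which a Monte-Carlo test
verifies at n = 10,000 meioses to ±0.01); genotyping errors as symmetric
re-draws among the genotypes producible for the segregation type (the
simplest model that biases r̂ upward); missingness independent per call;
comparison genomes laid out at a configurable bp/cM scale with inversions
(bp reflected within the interval) and translocations (interval moved to a
target chromosome, internal order kept), with ground-truth blocks derived
from the event segmentation; and external features dropped strictly
between anchored loci (truth cM by interpolation) or far outside anchored
regions. A chi-square interference model (gamma-distributed inter-event
distances, thinned) is available but off by default; no claim is made
about any real species' interference regime.

Defaults emulate the targeted study design: ~160 offspring per cross, a
CP-type mix dominated by one-parent markers (10% ab×cd, 15% ef×eg, 25%
hk×hk, 25% lm×ll, 25% nn×np — typical of reduced-representation SNP data
in outbred crosses), 0.5% genotyping error, 5% missing calls, 24 linkage
groups of 66.9 cM with 119 loci each at consensus scale.

What the simulator does not emulate — and therefore what green tests do
not certify for real data: linked-read or restriction-site artifacts
(sequence level is out of scope), sex differences in recombination rate,
segmental duplication causing non-Mendelian clustering, locus-dependent
error/missingness, interference (by default), and comparison-genome
assembly errors or paralogous similarity hits beyond the ambiguity the
anchor margin rule models. Acceptance-scale runs use one 100-locus,
100 cM linkage group with 150 offspring for order recovery and 4 linkage
groups of 25 loci for block recovery; these sizes were chosen to exercise
every code path at desk scale, and the stochastic bands (Kendall's τ ≥
0.9, length within 25%) reflect run-to-run variation across seeds at those
sizes.

## Known limitations

- Two-point positions inflate with genotyping error at sparse marker
  spacing (visible in the README example); the double-crossover QC
  compensates only where flanking informative loci are close. Multipoint
  HMM re-estimation would address this and is out of scope.
- The ripple explores window permutations only; gross seeding errors
  outside any window are not recoverable (mitigated by LOD-greedy
  seeding).
- Conflict resolution assumes conflicts sit in zero-recombination
  clusters; an ordering conflict between well-separated loci is removed by
  the same larger-cluster rule with cluster sizes 1 (tie → map B).
- `merge` composes pairwise; merging more than two maps in one LP is not
  implemented (the targeted design has two families).
- Block membership of loci skipped under the 5% tolerance is neither
  member nor separator; a different reading (split but do not drop) would
  change member counts at a few boundaries.
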