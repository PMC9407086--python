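# Methods

This note documents the models and estimators implemented in
`ylineage`, the assumptions behind the synthetic-data generator, and the
numerical choices made where the design was genuinely open.

## Data model

A Y-STR profile is a mapping from locus to an ordered list of allele
calls; alleles are decimal repeat counts with fractional parts
restricted to .0/.1/.2/.3, the microvariant steps seen in
capillary-electrophoresis nomenclature.  A single-copy locus normally
holds one allele; the duplicated loci DYS385a/b, DYF387S1a/b and
DYS527a/b hold an unordered pair stored sorted ascending, so genotype
identity is order-free.  An empty list is a null call; more alleles than
the expected copy number is a copy-number variant (CNV).  Four panels
are built in (Yfiler 17, PowerPlex Y23 23, Yfiler Plus 27, Yfiler
Platinum 38 loci, counting each duplicated locus twice); the smaller
panels nest inside the 38-locus set, so one table can be re-scored under
all four.  Locus names are normalized through an alias table
(`DYS389-2` → `DYS389II`, `DYS387S1` → `DYF387S1a/b`, `Y-GATA-H4` →
`YGATAH4`, ...), since published tables vary.

The exact identity of the Yfiler Platinum single-copy loci beyond the
Yfiler Plus ∪ PPY23 union is taken from the commonly reported 38-locus
composition (DYS444, DYS447, DYS522, DYS596, DYS612, DYS622, DYS645
plus DYS527a/b); none of the panel-level statistics depend on locus
identity, only on locus count and copy number.

## Forensic statistics

All spectrum-level parameters (MP, HD, DC, FUH; formulas in the README)
are computed with exact rational arithmetic and converted to float only
at the end, so printed-precision comparisons carry no accumulation
error.  Display rounding is half-up (5 decimals for parameters, 4 for
gene diversity), matching forensic reporting convention.  Gene diversity
uses the unbiased (n/(n−1)) form; when the "locus" is the whole-panel
haplotype, GD coincides with HD (asserted numerically in the suite).

Samples with a null call at any panel locus are excluded from that
panel's spectrum only (each kit's n may differ on incomplete data).
Variant-bearing samples stay in the spectrum — their haplotypes are
simply distinct; whether a source study excluded them is generally not
reported, and keeping them is the neutral default.

The variant screen classifies microvariants (nonzero fractional part),
CNVs (more alleles than expected copies) and nulls; a CNV list that also
contains a fractional allele appears in both categories.  The
carrier-by-clade cross-tabulation takes its sample universe from the
haplogroup call map and counts a 2×2 table; clade membership is resolved
through the haplogroup tree when one is supplied.

## AMOVA R<sub>ST</sub>

With per-sample repeat-score vectors over single-copy integer loci and
d(i,j) = Σ(a<sub>il</sub> − a<sub>jl</sub>)², the implementation forms
SS<sub>total</sub> and SS<sub>within</sub> (computed via deviations from
group means, which equals the pairwise-distance form), then

    MS_among = (SS_total − SS_within)/(K−1)
    MS_within = SS_within/(N−K)
    n_c = (N − Σ n_k²/N)/(K−1)
    σ²_among = (MS_among − MS_within)/n_c
    Rst = σ²_among/(σ²_among + MS_within)

Multi-copy loci and CNV-bearing calls are excluded (repeat arithmetic is
undefined on unordered pairs); microvariant alleles enter with their
decimal value; samples missing a chosen locus are dropped.  DYS389II can
optionally be entered as DYS389II − DYS389I (`dys389_adjust`), since
reference implementations differ on this point.

Negative estimates are reported raw with a log flag rather than
truncated: on literally duplicated groups the estimator sits at its
floor −1/(n<sub>c</sub>−1) (MS<sub>among</sub> = 0), and preserving that
behaviour keeps the estimator testable.  A 0/0 degenerate case (both
variance components zero) is defined as 0.

## MDS and neighbor joining

MDS starts from the classical (Torgerson) solution — double-center
−½D², top eigenvectors scaled by √eigenvalue — and by default refines it
non-metrically: per iteration, isotonic (monotone) disparities are
fitted to the configuration distances in dissimilarity order, Kruskal
stress-1 is evaluated, and a Guttman transform updates the
configuration.  Iteration stops when the stress improvement falls below
1e-6, after 200 iterations, or when an update would increase stress-1
(the previous configuration is kept), so the recorded stress history is
non-increasing by construction.  Negative input distances (possible from
raw R<sub>ST</sub>) are clamped to zero with a log message; an all-zero
matrix is rejected as degenerate.

Neighbor joining is the Saitou–Nei algorithm with the standard Q
criterion and branch-length formulas, ending with the three-point
closed form.  Q ties break by lexicographic label order of the joined
pair, making the output deterministic.  On additive matrices the tree
reproduces the input path lengths exactly (verified against randomly
generated trees); negative branch lengths on non-additive input are
written to Newick as-is and logged.

## Haplogroup calling

The built-in tree covers a 24-marker pedigree panel (E, D/D1a1a1/D1a2a,
C/C2, G, IJK/IJ/I, K, N/N1a1, O with O1a, O1b/O1b2, O2/O2a1/O2a2/
O2a2a1a2/O2a2b/O2a2b1a1, QR) with ISOGG placements; trees are
serializable as `clade, marker, parent` TSV.

A sample receives the deepest clade whose defining marker is derived and
none of whose typed ancestor markers is ancestral.  A no-call at an
intermediate marker does not block deeper assignment — the deeper
derived state implies the ancestor, which is recorded as imputed.
Derived markers off the chosen path are biologically impossible on a
tree and are flagged as conflicts (`path_consistent=False`); depth ties
break by tree preorder.  Samples with no supportable derived marker are
`unresolved` and are excluded from frequency denominators with a log
entry, so called frequencies sum to 100 %.

Clade aggregation sums a clade and all its descendants present in a
frequency vector, operating on tree structure rather than observed
labels (an internal clade aggregates correctly even if no sample
resolves exactly there).

PCA of a populations × clade-frequencies table uses correlation mode by
default (columns standardized; the common default of desktop statistics
packages), with covariance mode available.  Constant columns are
dropped with a log message; within each component the largest-magnitude
loading is made positive, fixing the sign convention.

## Median-joining networks

Network haplotypes are integer repeat vectors over the classic 15-locus
panel: the 13 single-copy Yfiler loci (DYS385a/b excluded), DYS389I,
and the derived DYS389b = DYS389II − DYS389I, which removes the repeat
block that the DYS389II amplicon shares with DYS389I so the two
contribute independent coordinates.  Samples flagged by the DYS389b
derivation, carrying a null/CNV call, or carrying a fractional allele at
a network locus are excluded with a log entry — the integer step metric
is undefined across a partial-repeat offset.

Distances are weighted Manhattan, d(u,v) = Σ w<sub>l</sub>|u<sub>l</sub>
− v<sub>l</sub>|.  Weights are quintile bins of log10 mutation rate
mapped to 5…1 (slowest quintile → 5), giving the anti-monotone
rate-to-weight relation; all-equal rates fall in the middle bin
(weight 3).

Construction proceeds on the ε-relaxed minimum spanning network: an
edge (u,v) is included iff d(u,v) ≤ minimax(u,v) + ε, where minimax is
the largest edge on the MST path (the Kruskal merge level); ε = 0 gives
exactly the union of all MSTs.  Median vectors (component-wise medians
of triples) are then added.  Instances with ≤ 8 observed haplotypes are
solved by a bounded exhaustive search over the median closure (up to
n−2 additions, 20 000 spanning-cost evaluations), which provably reaches
the minimal spanning cost in that regime — a plain greedy can require
chains of individually non-improving medians and miss the optimum.
Larger inputs use the greedy pass: among medians of triplets connected
in the current MSN, add the one that most reduces the spanning cost,
iterating until none helps.  Obsolete medians (inferred nodes of degree
≤ 2 whose removal does not raise the spanning cost) are pruned, and the
final MSN over the surviving nodes is returned.  With ε = 0 the edge set
always contains a minimum spanning tree, and the spanning cost never
exceeds the observed-only MST cost.

The ancestral node is the frequency-weighted medoid — the observed
haplotype minimizing Σ count<sub>j</sub>·d(h, h<sub>j</sub>) — with ties
broken toward higher own count, then lexicographically.  The
composition summary reports, per population, sample and haplotype
counts and the count-weighted mean/median shortest-path distance to the
ancestral node in the network.  When comparing a source population with
a daughter founded from it, the ancestral node should be computed on
the source (or an external reference) alone: a pooled medoid
systematically lands in the tighter cluster, which after long isolation
is the *drifted* population, inverting the intended polarity.

## Synthetic-data generator

The simulator is a haploid Wright–Fisher model of a constant-size male
population: each generation every male draws a father uniformly at
random; each STR allele copy mutates with its per-locus rate under the
single-step stepwise mutation model (±1 repeat, equal probability,
reflecting at 1 repeat so alleles stay positive).  Rare events add the
structure real capillary data shows: microvariant events attach a +0.2
fractional offset that is inherited (and survives later ±1 steps, like
the stable lineage microvariants confined to single clades); duplication
events convert a single-copy call into a two-allele list whose copies
then mutate independently.  Haplogroup identity is inherited unchanged:
Y-SNP mutation rates (~1e-9/generation) are negligible on simulated
time scales, so SNP profiles are derived deterministically from the
lineage's haplogroup path and the caller recovers the truth exactly.

Defaults define the emulated study conditions: effective male size
N = 3000, 200 generations, samples of 150 males, per-locus rates from
the packaged table (4e-4 to 1.8e-2 per generation, spanning the range
reported for Y-STRs), microvariant and duplication rates of 1e-5 per
locus-generation, founder haplogroup weights resembling a lower-Yangtze
Han paternal mix (O-dominated, O1a largest, moderate N and C2).  The
choice of N follows from the sampling identity P(two sampled men share
an unmutated recent ancestor) ≈ 1/(1 + 2NΣμ): with Σμ ≈ 0.17 per
generation over 38 loci, N in the low thousands reproduces the
singleton-dominated spectra (FUH ≳ 0.9 under the 38-locus panel) that
real regional samples show, whereas N of a few hundred would make
duplicate haplotypes common.  Founders receive haplogroup-specific
repeat offsets plus light per-founder jitter so clades carry distinct
STR backgrounds.

Divergence scenarios copy the evolved ancestral population at a split
and evolve the daughters independently; options allow unequal post-split
drift (`split_generations_b`) and a founder bottleneck for daughter B
(`founder_bottleneck_b`), which together emulate island founding from a
mainland source.  A single seeded RNG stream drives everything, so runs
are byte-reproducible; an event log counts lineage-generations,
mutations, microvariant and duplication events for calibration checks.

What the generator does **not** emulate: population growth or migration,
multi-step mutations, locus-specific allele ranges or stutter/typing
error, SNP no-calls, and female demography (the Y is non-recombining, so
none is needed).  Passing tests therefore show estimator correctness and
qualitative pattern recovery under an idealized neutral model, not
calibration against any real population's history.

## Problem sizes and tolerances

The test suite runs simulations at reduced sizes chosen for signal
rather than realism where only an ordering or recovery property is
asserted (e.g. N = 200, 20 seeds for the divergence-monotonicity grid;
N = 120 for network polarity), and at the default study regime where the
claim is about the regime itself (singleton dominance).  Oracle
comparisons use tight float tolerances (1e-10 for AMOVA and additive
tree recovery, 1e-9 for spanning costs); published-table reproductions
are exact at the printed precision.  MDS convergence is declared at
stress improvement < 1e-6 or 200 iterations.

## Known limitations

- R<sub>ST</sub> follows one published variance-component convention;
  online AMOVA services differ in their treatment of DYS389II and of
  multi-copy loci, so absolute values may differ slightly from theirs
  (the `dys389_adjust` option covers the main variant).
- The greedy median-joining pass for large networks is a heuristic; only
  the ≤ 8-haplotype regime carries an optimality guarantee.
- The haplogroup tree covers the 24-marker panel only; markers outside
  it are rejected rather than placed.
- Non-metric MDS minimizes stress-1 from the classical start; it is a
  local method and is not guaranteed to find the global stress minimum.
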