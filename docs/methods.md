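# Methods

This note documents the models and procedures implemented in `pansv`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## SV calling from alignment blocks (`pansv.svcall`)

Input is a set of filtered one-to-one alignment blocks between a query
accession and the common reference (PAF rows or MUMmer show-coords TSV).
Blocks are retained only if **strictly longer than 1 kb** on the reference
("longer than 1,000 bp" read literally: a 1,000 bp block is removed).
Coordinates are 0-based half-open throughout; 1-based conventions appear
only when writing GFF3/VCF.

**Collinear chain.** Per (accession, reference chromosome), blocks mapping
to the chromosome's majority query partner are chained by a dynamic
programme that finds the increasing run in (ref_start, qry_start)
maximising first the number of blocks and then the aligned bp (the
tie-break prefers larger blocks). Off-chain blocks are secondary
alignments; they are not discarded but feed the CNV/TRANS callers and the
coverage guard below.

**PAV.** For consecutive chained blocks with reference gap `g_r` and query
gap `g_q`: `g_r >= min_sv_len` (default 50 bp, the community SV floor; the
source analysis states no lower bound) and `g_r >= gap_ratio * max(g_q, 1)`
(default ratio 5) calls an absence (`PAV_del`) of length `g_r`; the
symmetric condition calls a presence (`PAV_ins`) of length `g_q` anchored
at the reference junction. Mixed gaps below the ratio produce no call and
are logged. A *coverage guard* suppresses a candidate when more than half
of the gap interval is aligned elsewhere in the same accession: a reference
gap whose sequence aligns from another locus is a relocation (TRANS), not
an absence, and a query gap whose sequence aligns back to the reference is
a duplication (CNV), not novel sequence. Without this guard every tandem
duplication would be double-reported as an insertion and every
translocation as a deletion + insertion pair.

**INV.** Maximal runs of reverse-strand blocks (per accession and
chromosome pair) are reported as one inversion spanning the run's reference
extent, kept only when the span strictly exceeds 1 kb. Runs are maximal, so
two adjacent reverse blocks give one call, and a fully strand-flipped
chromosome gives exactly one chromosome-length inversion.

**CNV.** Reference intervals covered by two or more distinct query segments
of the same accession become copy-gain records with `copy_number` equal to
the maximum coverage depth; the symmetric query-side multi-coverage is
reported with the reference anchor as the record locus. The operational
rule is deliberately simple (the upstream tools the rule replaces do not
document theirs) and is configurable.

**TRANS.** Each query chromosome's majority reference partner (by aligned
bp) defines the expected synteny. A block is translocated if its reference
chromosome differs from that partner, or if it lies on the partner but more
than `displacement` (default 1 Mb) off the syntenic diagonal, measured
against the median ref-minus-qry offset. Contiguous translocated blocks
(reference gap <= 1 kb) merge into one record carrying the query-side
destination as `partner_locus`.

## Non-redundant catalogue (`pansv.catalogue`)

Two same-type calls merge iff they share the reference chromosome, both
breakpoints lie within `bp_tol` (default 100 bp) and their reciprocal
length overlap is at least 0.8 (for zero-span insertion points the
criterion applies to the inserted lengths). Merging is the transitive
closure of this relation (union-find), which makes the result independent
of input order; a greedy scan would not be. Record coordinates are the
cluster **medoid** — the member minimising the summed breakpoint distance
to the others, ties broken lexicographically — so the catalogue serialises
byte-identically under any input shuffle. Because medoids are members, no
two surviving records can still satisfy the merge criterion, hence
re-merging a catalogue is a no-op (idempotence). The merge tolerances are
common SV-merging practice; the source analysis does not state its own.

The size spectrum reports, per type, the share of records below a headline
threshold (PAV 2 kb, INV 100 kb, CNV 4 kb, TRANS 20 kb by default,
configurable). Types with no records report NaN, never 0/0.

## SV-gene context (`pansv.annotate`)

Eleven categories relate SVs to gene models with 5 kb strand-aware flanks
(upstream = 5'). Deletions are assigned one category by priority **whole
gene > CDS start > exons > upstream > downstream**: a deletion spanning the
entire gene is `DELgene` even though it necessarily also covers the CDS
start and every exon. The category list itself carries no precedence, so
the priority is a package decision; `multi_label=True` disables it for
sensitivity checks. Insertions are classified by their insertion point
(exon, intron, upstream/downstream flank), CNVs become `Dup`, and every
gene with any SV in its body or flanks — including inversions and
translocations, which have no specific category — receives the
`PresenceSVs` superset flag. `PresenceSVs` is read as the superset
indicator rather than a residual class; the alternative reading is not
recoverable from the category list. Overlap is half-open and requires at
least one shared bp: abutting features do not overlap. Unstranded genes
are treated as '+' with a warning; genes without a CDS start skip the
`DELCDSstart` check with a log message.

The gene-family LTR test is a one-tailed binomial: with background
proportion `p0` = fraction of all genes overlapping intact LTR intervals,
a family of `n` genes with `k` overlapping returns `P(X >= k | Bin(n, p0))`
and the fold `(k/n)/p0`.

## Pan-genome families (`pansv.pangenome`)

The family x accession count matrix is an input (orthology clustering is
upstream). Occupancy `n` of `n` accessions is core, occupancy 1 private,
2..n-1 dispensable. The saturation curve reports pan(k) (families in at
least one of the first k accessions of an ordering) and core(k) (families
in all of them) as means +- sd over orderings: 1,000 random permutations by
default (fixed seed), exact enumeration of all k! orderings for up to 8
accessions, or a single fixed ordering — both modes are provided because
it is not stated whether published added-family counts come from one
ordering or permutation means. pan(k) is non-decreasing and core(k)
non-increasing in every ordering by construction. The added-family ratio
is `100 * added / total`, reported at two decimals.

## Differential expression (`pansv.expression.call_degs`)

A gene is a DEG iff `|log2FC| >= 1` and BH-adjusted `p < 0.05`, with log2FC
computed on mean library-size-normalised counts with a pseudocount of 1.
The p-value comes from a negative-binomial Wald test: a method-of-moments
dispersion pooled across the two groups (`phi = max(0, (s2 - m)/m2)`),
the delta-method standard error of `log2(mean + 1)`, and a **t reference
with n1 + n2 - 2 df** rather than a normal one — a small-sample correction
that keeps the test calibrated at moderate replicate counts. This replaces
the external DE tool used upstream; the downstream contracts (threshold
rule, BH correction, enrichment inputs) only need calibrated p-values and
the exact fold-change rule. The Wald test is asymptotic: its null p-values
are verified uniform at 30 replicates per side, and no claim is made about
calibration at n = 3, where only the thresholding contract is exercised.

## SV-expression screens (`pansv.expression`)

*Proximity enrichment*: per accession and category, the observed share of
category genes in the expression-altered set is compared against random
gene-label draws of the same size from the universe (the gene-ward null;
SV-position shuffling is the phrased alternative and can be emulated by
supplying a different universe). One-sided permutation p with the +1
correction, BH across all category x accession cells.

*HR fixed-SV screen*: (1) keep SVs present in >= 3 heat-resistant
accessions and no heat-susceptible accession; (2) attach genes overlapping
or within 5 kb ("nearby" = the same flank convention as the category
classifier); (3) per (SV, gene) a two-tailed Wilcoxon rank-sum test — exact
when both sides have < 8 observations and no ties, normal approximation
with tie correction otherwise — compares per-replicate TPM between samples
of carrier and non-carrier accessions (control condition by default;
whether the upstream analysis used replicate samples or accession means is
not stated, so means are available via `condition=None` and pre-averaged
input); (4) BH across all tested pairs, keep q < 0.05; (5) flag
heat-responsive genes (DEG heat vs control in any accession/tissue/time
stratum) and annotate pathway membership. Every stage logs its count and
the counts are non-increasing. Rank-test p-values are verified uniform
under the null at 24 observations per side; at the 3+3 accession design the
exact test's discreteness makes a KS uniformity check meaningless, which is
a property of exact rank tests, not of the pipeline.

## Population analyses (`pansv.popgen`)

*Filtering*: an SV is removed iff MAF < 0.05 **or** missing rate > 0.1
(strict inequalities, so the boundary values 0.05 and 0.10 are retained).

*fdSV scan*: per SV, `delta_f = |f_A - f_B|` between the two groups with
missing genotypes excluded per group; fdSVs have `delta_f >= 0.5`. Windows
of 100 kb sliding by 10 kb average `delta_f` over the SVs inside (windows
with no SVs are excluded from ranking, not scored 0); sweep regions are
the top 1% of windows, merged when overlapping. Window size, step and the
0.5 cutoff are configurable defaults — the upstream analysis defers them
to its own reference — while the top-1% rule is kept exactly. The scan is
symmetric in the group labels. The cross-population composite-likelihood
statistic it stands in for is not reimplemented; the mean-|delta_f| window
statistic is the documented substitute with the same selection rule.

*Pathway enrichment*: Pearson chi-squared on the 2x2 sweep x pathway table,
continuity correction off (the correction is conservative for 1-df tables
of this size); automatic switch to Fisher's exact test, logged, when an
expected cell drops below 1.

*Kinship and structure*: K is the simple-matching matrix — the share of
markers with identical genotype calls per pair, over pairwise-complete
markers — giving entries in [0, 1] with unit diagonal. S holds the top
three principal components of the SV-wise mean-imputed, centred genotype
matrix. Individuals missing more than half their calls are excluded.

*PAV-GWAS*: the mixed linear model `y = X a + S b + g + e` with
`g ~ N(0, sg2 K)` and `e ~ N(0, se2 I)`. Variance components are estimated
once by REML on the null (no-marker) model through the spectral
decomposition of K, profiling the scale and maximising over the
heritability ratio on a bounded scalar search (grid then Brent). Each
marker is then tested by generalised least squares in the rotated basis
with those components fixed — the population-parameters-previously-
determined approximation, which trades per-marker exactness for a
2,000-marker scan in well under a second; `reml_per_marker=True`
re-estimates components per marker for validation on small panels (the two
agree to r > 0.98 on -log10 p). The per-marker statistic uses a t
reference with the residual scale re-estimated per marker, so with K = I
the procedure collapses exactly to ordinary least squares. Markers are
significant at -log10(p) > 5. Null simulations at n = 200 with a polygenic
background of h2 = 0.3 give type-I error within [0.03, 0.07] and
lambda_GC within [0.9, 1.1].

*Diversity*: windowed nucleotide diversity is the mean pairwise per-site
difference (`2 p (1-p) n/(n-1)` summed over sites, divided by the number
of surveyed sites in the window — a per-site, not per-bp, convention);
Shannon H is `-sum p ln p` over allele frequencies per locus, aggregated
as the **sum over loci** (the upstream H is not defined, so the convention
is stated here and in reports); cohort comparisons use Spearman
correlation of windowed marker densities.

## Closed-form estimators (`pansv.estimators`)

Genome size `G = (N (L - k + 1) - B) / D` with k = 17 by default; `D` is
taken as the histogram mode **excluding depth <= 1** because the error peak
at depth 1 would otherwise dominate shallow surveys. LTR dating
`K = -0.75 ln(1 - 4λ/3)`, `T = K / 2r` with `r = 1.3e-8` per site per
year; λ >= 0.75 is a domain error (Jukes-Cantor saturation). TF proportion
`N_TF/N_total` and `REC = S1/S2 x 100%` are exact ratios with input
validation.

## Synthetic data (`pansv.sim`)

One root seed derives independent per-submodule streams (CRC-keyed
`SeedSequence` spawns), so identical configurations are byte-identical and
changing one generator never perturbs another.

*Genomes*: a uniform-random reference (default 2 x 1 Mb), non-overlapping
genes packed by uniform partition of the slack (infeasible packing is an
explicit error), a ~40% repeat track. A shared pool of SV events (defaults
20/20/6/4/2 PAV-ins/PAV-del/CNV/INV/TRANS, 52 events — above the 50-event
floor the recovery benchmarks require) is placed non-overlapping with 2 kb
separation so every flanking alignment block survives the 1 kb filter;
each event is carried by a random ~60% subset of the ten accessions.
Lengths are log-uniform within per-type ranges; CNV lengths start at
1.1 kb because a copy block shorter than the block filter could never be
recovered by any filtered-block caller, and inversions start at 1.5 kb for
the same reason relative to the 1 kb inversion floor. Alignment blocks are
emitted directly from the event bookkeeping — the exact one-to-one synteny
segments an aligner would report at zero noise — because the callers
consume aligner output, and desk-scale testing needs both noiseless and
noise-injected block sets, which truth can produce (boundary jitter via
`noise`). No aligner is run; alignment artefacts (spurious micro-blocks,
repeat-induced mis-chaining, identity decay) are **not** emulated, so
perfect recovery at zero noise validates the calling logic, not robustness
to real aligner output.

*Expression*: negative-binomial counts (gamma-Poisson, dispersion 0.1 —
standard bulk RNA-seq), log-normal baselines, a 30% heat-responsive gene
fraction at |log2FC| = 2, cis-SV effects (+2 log2FC) applied only in
carrier accessions, three biological replicates per condition, TPM as
count/length scaled to 1e6 per sample. Library-size variation, batch
effects and outlier replicates are not emulated.

*Population*: 200 diploid-equivalent individuals in two climate groups
with Balding-Nichols background drift (Fst 0.05), 2,000 SVs (10,000 in
scan benchmarks), 20 differentiated SVs at delta_f = 0.8 clustered in
100 kb, one causal SV at 15% trait variance plus a polygenic background of
h2 = 0.3 built from the genotypes themselves, a two-mode latitude gradient
aligned with the groups, 2% missingness. Linkage disequilibrium beyond the
cluster, inbreeding and admixture are not modelled.

*k-mer histograms*: read-start coverage of k-mer positions is tracked
directly (exact for error-free reads on a genome with unique k-mers, which
a 1 Mb uniform-random sequence is to excellent approximation); errors are
binomial thinning with corrupted copies re-entering as singletons. Uniform
and random (Poisson) coverage modes are provided; uniform is the default
the estimator's "peak depth" reading assumes.

*LTR pairs*: both copies evolve forward under Jukes-Cantor for T years at
rate r (per-site transition probabilities, not just the expected
divergence), so the dating estimator is the exact inverse of the
simulation's expectation.

## Problem sizes

The shipped benchmarks use 2 Mb genomes with ~52 events per instance
(5 instances), 2,000-gene family matrices, 200-gene x 36-sample expression
designs, and populations of 200 individuals with 2,000-10,000 SVs (50
seeds for GWAS power, 20 for sweep recovery). These sizes are chosen so
the full suite exercises every code path in well under a minute per
benchmark while keeping every statistical check adequately powered.

## Known limitations

- The callers assume a dominant one-to-one synteny per chromosome pair;
  heavily rearranged genomes with competing chains are out of scope.
- CNV copy-number is bounded below by the block filter: copies shorter
  than the filter length are invisible by construction.
- The PPD approximation shares variance components across markers; markers
  in strong kinship with the background lose a little power relative to
  exact per-marker REML.
- The enrichment null permutes gene labels, not SV positions; spatial
  clustering of genes is therefore not part of the null.
- Breakend VCF output records translocation endpoints but not orientation
  phase (all breakends are written in the t[p[ form).
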