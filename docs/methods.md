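# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ccf1tx`. Everything stated here is computed by the package
and exercised by the test suite; no external datasets are used.

## Genome and transcriptome model

The synthetic genome is deliberately minimal: each chromosome is a linear
coordinate system (1-based, inclusive intervals throughout; coordinates are
never converted), and a transcript is an intron-free genomic interval with
one isoform per gene. The eight CC founder strains share a common
transcript/gene/coordinate skeleton; founder B (C57BL/6J) is the reference,
and every other founder differs from it by independent substitutions planted
at `snp_rate` per transcript base (default 0.01/bp, an intentionally dense
rate so that short 43 bp reads regularly span allele-distinguishing sites at
desk scale). Sex chromosomes are not simulated; the mitochondrial contig is
optional and flagged maternal-only, matching a breeding design in which
every F1 inherits B6 mitochondria.

The default simulation emulates the structure of the study design it stands
in for: a hemizygous transgene carrier crossed to a non-carrier
(`transgene_carrier_prob = 0.5`, the Mendelian expectation), sexes balanced,
ages restricted to {4, 12} months, and 43 bp reads. Reads are single-end:
paired-end reads add no logic the equivalence-class EM needs at this scale.
Sequencing QC metrics are eight correlated Gaussians loading on a planted
per-sample batch score, so that downstream Seq.PC computation has a real
direction to find.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: realistic recombination maps and
block-length distributions (breakpoints are uniform random), indels and
structural variants, overdispersed count noise (expression matrices are
Gaussian on the log2 scale, so negative-binomial-specific behavior of count
models is out of reach), GC/positional sequencing bias, and annotation
complexity (overlapping genes, multi-isoform loci).

## Haplotype stitching and the diploid reference

A strain transcriptome is stitched by assigning each transcript whole to
one founder. The paper-gap here is breakpoint-spanning genes; the package
assigns the founder with maximal base-pair overlap, breaking ties toward
the founder whose earliest overlapping block has the smaller start
coordinate. This is deterministic and keeps one sequence per transcript,
which the downstream EM index requires; per-segment chimeric stitching was
rejected as unsupported. CC strains are treated as fully inbred
(homozygous mosaics); heterozygous ancestry states are out of scope.

The F1 diploid reference is the allele-tagged union of the maternal B6 copy
(`_M` suffix) and the paternal stitched copy (`_P`), with MT transcripts
emitted maternal-only. Founder-of-origin contribution at a locus is the
fraction of its base pairs covered by each founder's blocks; rows sum to 1
exactly and are one-hot whenever a locus does not straddle a breakpoint.

## Equivalence classes and EM quantification

Read-to-reference compatibility is exact substring containment, found by
k-mer seeding and verified per candidate placement; optional mismatch
tolerance uses pigeonhole seeding (a read split into `m+1` segments must
match one segment exactly to harbor ≤ m substitutions). A read's
equivalence class is the set of all compatible (transcript, allele) pairs.

The EM treats θ as the per-transcript-allele fraction of reads. E-step:
each class count is split among members proportionally to θ_t/ℓ_t with
effective length ℓ = max(length − read_length + 1, 1); M-step: θ is the
renormalized assigned total. Initialization is uniform; convergence is
max-abs θ change < 1e-8 with a 1000-iteration cap (non-convergence sets a
flag rather than raising); the data log-likelihood is monotone
non-decreasing and asserted so in tests. A `unique_only` switch drops all
ambiguous classes first, reproducing a strict uniquely-aligned-reads
quantification; the general multiread EM is the default because that is
what the method exists for. The hierarchical allele→isoform→gene EM of
full-scale tools collapses to this flat transcript-allele EM under the
one-isoform toy model.

Gene TPM pools the M and P alleles of each gene **before** scaling: read
fractions are converted to molar abundances (θ/ℓ), summed per gene, and the
column scaled to 1e6. Pooling before scaling was chosen (the alternative,
scaling per allele first, gives the same result up to a common factor but
makes the allele-resolved layer awkward to interpret).

## Preprocessing

"Not expressed" is operationalized as TPM ≤ 0.1; a gene is kept iff
TPM > 0.1 in strictly more than 20% of samples (both thresholds are flags).
Seq.PCs are the top-5 principal components of column-z-scored QC metrics,
with constant metrics dropped (all-constant input returns all-zero scores)
and each component's sign fixed so its largest-magnitude loading is
positive, making reruns byte-identical.

Residualization fits ordinary least squares per gene on log2(TPM+1)
against a treatment-coded design with intercept, and returns residuals
plus each gene's grand mean so matrices stay on an interpretable scale.
The full stated formula (`line + genotype + sex + age + Seq.PC1..5`) is the
function default, but the pipeline stages default to regressing **technical
terms only** (the Seq.PCs): regressing genotype out before testing genotype
would nullify the differential analysis, and the network stage correlates
eigengenes with age/sex/genotype afterwards. The per-analysis covariate
sets are exposed rather than hard-coded because the single stated formula
and the downstream tests of those same factors cannot both be taken
literally.

## Differential expression

The per-gene test is a Welch two-sample t on log2 expression; the
negative-binomial machinery of count-based frameworks is intentionally not
replicated, and the test function is isolated behind the thresholding,
pairwise-matrix and intersection logic so an NB variant could be swapped
in. log2FC is the difference of group means on the log2 scale (not the log
of a ratio of means). DEG: |log2FC| > 1 and BH FDR < 0.05. Genes with zero
variance in both groups get p = 1 when means agree and p = 0 otherwise.
Conserved DEGs across strains require membership in every comparison's DEG
set **and** concordant fold-change sign; the sign requirement is a design
choice (an unsigned intersection is recoverable by ignoring it).

## Consensus network analysis

Biweight midcorrelation follows the standard weighting: u = (x − med)/(9·MAD),
w = (1 − u²)²·1[|u| < 1]; pairs where a gene has MAD 0 fall back to Pearson
(with a warning) and constant genes are dropped. Signed adjacency is
((1 + cor)/2)^β with β = 16 (age/sex network) or 14 (genotype network) —
taken as given, the scale-free fit search that produced them is out of
scope. TOM is (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) with unit
diagonal. Consensus across datasets power-scales each TOM so its 0.2
off-diagonal quantile matches dataset 1 (`TOM^(log q1/log qs)` — ratio
scaling was rejected because TOM must stay ≤ 1), then takes the
element-wise minimum.

Module detection clusters 1 − TOM by average linkage and applies a dynamic
branch cut implemented as: a static cut at `cut_height` (0.999) yields
initial branches; a branch is recursively split while the merge-height gap
at its top exceeds the `deep_split`-mapped quantile of the gaps within the
branch (deep_split 0–4 → quantile 0.95 down to 0.55). A split that would
leave one side below `min_module_size` (100) peels that side off as
unassigned while the larger side is revisited; a split leaving both sides
undersized is not taken. This is not a re-implementation of the published
hybrid tree-cut — the planted-module recovery and pure-noise tests are the
behavioral contract. `pam_stage` is accepted only as `False` (no post-hoc
reassignment).

Eigengenes are the first principal component of the z-scored module
submatrix (per-dataset z-scoring, samples concatenated across datasets for
the consensus case), unit-norm, with sign fixed so the mean member kME is
positive. Modules whose eigengene dissimilarity 1 − cor(ME) falls below
`merge_thresh` (0.25 or 0.2, both used in the emulated design and both
exposed) are merged iteratively, closest pair first. Genes with own-module
kME < 0.7 are reassigned to grey. Labels are conventional color names in
decreasing module size. Module–trait correlation is Pearson with
t-distribution p-values (n − 2 df), BH-adjusted over the whole
module × trait table; significance requires FDR < 0.05 **and** |r| ≥ 0.1.
Traits are coded age 4→0/12→1, sex F→0/M→1, genotype WT→0/carrier→1.

## Enrichment and preservation

Fisher enrichment forms the 2×2 table within the declared universe and
takes the two-sided p as the sum of hypergeometric point probabilities not
exceeding the observed table's (verified against exhaustive fixed-margin
enumeration to 1e-12). Odds ratios get a 0.5 continuity correction when a
cell is zero; p-values are never corrected that way. Because the exact
test is discrete, null "uniformity" is checked on the randomized
probability-integral transform of the p-value, which is exactly
Uniform(0,1) iff the computation is calibrated. Directional enrichment
splits DEGs by fold-change sign; an empty direction yields overlap 0 / p 1
rather than an error. Gene-set eigengenes are PC1 of the z-scored listed
genes (≥ 3 required), sign-fixed as above.

Module preservation uses exactly two statistics: module **density** (mean
within-module signed adjacency in the test data) and **connectivity**
preservation (Pearson correlation between intramodular connectivity in
reference vs test). The reference implementation aggregates more
statistics (and medianRank variants); the reduced pair is this package's
contract, validated by planted/null constructions. The null is `n_perm`
(≥ 50, default 100) random same-size gene sets from the shared universe;
Z = (obs − null mean)/null SD per statistic, Z_summary their mean, with a
1e-6 floor on the null SD so degenerate nulls (e.g. test data identical to
reference, where every permuted connectivity correlation is exactly 1)
yield a near-zero rather than unbounded Z. Bands: < 2 not preserved,
[2, 5) moderate, [5, 10] preserved, > 10 highly preserved.

## Problem sizes and numerical conventions

The test suite and examples run at desk scale, chosen as the smallest
sizes at which each statistical contract is comfortably identifiable:
stitching oracles use 20 mosaics × 200 transcripts; EM recovery uses
100,000 error-free reads over 15 genes (2% relative TPM error for gene
weights ≥ 5%); DE calibration uses 2,000 null genes at n = 20/group;
network recovery uses 5 planted modules × 120 genes over two 60-sample
datasets; preservation uses 100 permutations. Random number streams are
derived from a single mandatory seed with per-generator stream tags, so
adding one generator call never perturbs another's output and every
artifact is a pure function of its configuration.

## Known limitations

- Whole-transcript founder assignment misrepresents transcripts that truly
  straddle haplotype breakpoints (no chimeric sequence is produced).
- The Welch t substitute will differ from count-model results on strongly
  overdispersed low-count genes; the synthetic Gaussian matrices cannot
  expose that difference.
- The dynamic branch cut approximates, not reproduces, the published
  hybrid algorithm; module boundaries can differ in borderline topologies.
- Preservation Z-summary with two statistics is systematically simpler
  than the multi-statistic reference; absolute Z values are not comparable
  across implementations, though the bands behave equivalently on the
  planted/null constructions tested.
- Exact-substring compatibility mapping (default 0 mismatches) is an
  idealization of alignment; with sequencing errors enabled, reads may go
  unmapped unless mismatch tolerance is raised accordingly.
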