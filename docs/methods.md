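# Methods

This note documents the models and procedures `patchrep` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Single-cell QC

Cells are removed, in order, when (1) the mitochondrial read fraction
exceeds 0.10, (2) total UMIs fall below 1200 **or** detected genes below
500, (3) the doublet flag is set, (4) more than one IG heavy or light
chain was recovered. The wording of the thresholds is honoured
literally: "more than 10%" is a strict `>`, "fewer than 1200/500" a
strict `<`, so boundary cells (exactly 10% mitochondrial, exactly 1200
UMIs, exactly 500 genes) survive. The four rules are independent
predicates, so the sequential application equals their conjunction; the
per-rule removal counts in the QC report attribute each cell to the
first rule it fails. Doublet detection itself is out of scope: the
`doublet_flag` metadata column is consumed as input, as are the chain
counts and cluster labels. Genes detected (count > 0) in fewer than 10
cells are then dropped.

Mitochondrial genes are flagged by a configurable, case-insensitive
name prefix (default `MT-`), since deposited matrices differ in naming
convention.

## Normalisation and highly variable genes

Counts are scaled per cell to the median library size and transformed
with `log(1 + x)`. Cells with zero totals are an error at this stage —
they should have been removed by QC.

Highly variable genes (default n = 3000) are ranked by the dispersion
(variance/mean) of the log-normalised values, with a lexicographic
gene-name tie-break for determinism; genes with zero mean rank last.
This is a deliberately simple variance-stabilised dispersion rank, not a
re-implementation of any particular toolkit's HVG flavour: the exact
selector is not the scientific contribution here, and on the simulated
data the latent-factor module genes are recovered into the top ranks at
≥ 99% (asserted at ≥ 90% in the tests).

## Co-expression modules

- **Adjacency**: `a_ij = |cor(x_i, x_j)|^β` over HVGs with zero
  diagonal. The soft-threshold power β defaults to 6, the customary
  unsigned-network default, and is exposed in the run config.
  Zero-variance genes get zero correlations with a warning.
- **Topological overlap**: the standard unsigned form
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
  `k_i = Σ_u a_iu` and `TOM_ii = 1`. An all-zero adjacency therefore
  yields the identity. `TOM ≥ a` is *not* an invariant and is not
  asserted; symmetry and the [0, 1] range are.
- **Modules**: Ward linkage (Lance–Williams update, as implemented in
  scipy) on the dissimilarity `1 − TOM`, with the tree cut to exactly
  `module_count` clusters (default 100) by cluster count, not by
  height. Modules are numbered by their lexicographically smallest
  member gene, making the output order-stable.
- **Scores**: each gene's cross-cell expression vector is divided by its
  Euclidean norm; because the input is non-negative this bounds every
  entry to [0, 1] (an l2-normalised non-negative vector cannot exceed
  1), which resolves the ambiguity of "normalised to [0, 1] by l2
  normalisation" for signed data. A cell's module score is the mean over
  the module's genes; all-zero genes contribute 0.

## Cluster association statistic

Each module score is tested against each cell cluster by a
generalised linear model with the cluster as the explaining variable.
Two aspects are under-determined in prose and were fixed as follows:

- **Family/link**: Gaussian with identity link, making the residual
  deviance the residual sum of squares.
- **Design**: a one-vs-rest indicator per cluster, so a statistic exists
  for every (module, cluster) pair rather than one per module.

The statistic is `100 · (D_null − D_fit) / D_null`, where `D_null` is
the total sum of squares about the grand mean and `D_fit` the residual
sum of squares about the two group means. It is defined as 0 when
`D_null = 0` (constant scores, warned). Under these choices it equals
`100 · R²` of the one-hot regression — equivalently 100 × the squared
point-biserial correlation — and the test suite asserts agreement with
that closed form to 1e-10.

`gene_set_score` reports, per cluster, the mean normalised expression
of a gene set and `log2((mean_in + ε)/(mean_rest + ε))` with
ε = 1e-9 to guard empty means.

## Clonal lineage inference

A lineage is the set of heavy chains plausibly descending from one
V(D)J recombination: identical V allele, identical J allele, identical
CDR3 length, and CDR3 nucleotide mismatch fraction within the threshold
(default 0.20). Choices that the definition leaves open:

- **Inclusivity**: "a maximum of 20% mismatches" is read as
  `mismatch_fraction ≤ 0.20` (inclusive); the threshold is a config
  field.
- **Linkage**: single linkage (transitive closure of the pairwise
  predicate), matching common clonotype-tool behaviour. Chained fixtures
  in the tests document that members > 20% apart can share a lineage
  through intermediates.
- **Combined clustering**: single-cell and bulk heavy chains enter the
  initial clustering together, rather than bulk being attached to
  single-cell-seeded lineages afterwards.
- **Ambiguous allele calls**: comma-joined multi-allele calls compare as
  sets, any overlap counting as identical. Since set overlap is not
  transitive, "grouping by key" is implemented as union-find over the
  full pairwise predicate (bucketed by CDR3 length); for single-allele
  calls this is exactly key grouping.
- **N bases**: N mismatches any other base in the CDR3 comparison
  (conservative) but N positions are excluded from both numerator and
  denominator of SHM, the standard repertoire convention.
- **Determinism**: records, members and lineages are sorted
  (key, then smallest member sequence id) before ids are assigned, so
  the output is invariant to input row order.

**Light-chain refinement**: lineages whose paired single-cell members
carry more than one distinct light-chain key (light V allele, J allele,
CDR3 length) are split into one sub-lineage per key. All members without
light-chain information — every bulk read, plus single-cell members with
no recovered light chain — are then assigned to the sub-lineage
containing the single-cell reference heavy CDR3 with minimum Levenshtein
distance (unit-cost edit distance, iterative dynamic programme), ties
to the lowest sub-lineage id. Routing unpaired single-cell members
through the same resolution step (rather than only bulk reads) is a
deliberate choice; if no sub-lineage holds a single-cell reference the
records land in a residual lineage flagged `unresolved`. Splitting and
resolution preserve the partition property: every input record is in
exactly one lineage at every stage.

**Isotype assignment**: the observed constant-region fragment is
compared to each class reference by ungapped prefix alignment over the
shared length; the best identity wins if it reaches `isotype_min_score`
(default 0.90), otherwise "unknown". Bulk duplicate counts never weight
clustering (membership is per unique sequence); they weight read
abundance in tracing only.

## Tissue tracing and summaries

- **Relative abundance** is duplicate-weighted lineage reads divided by
  the tissue library's total reads (traced or not). "Fraction of traced
  reads" is obtainable by passing only traced records as the library.
  Lineage/tissue pairs without members are omitted (sparse long format).
- **SHM by compartment** summarises `v_shm_percent`
  (= 100 × (1 − v_identity) when derived from the annotator's identity
  fraction) with n, mean, median and quartiles per tissue; the whole
  aligned V region is the denominator.
- **V/J usage** counts sequences (not reads) per gene, collapsing
  alleles by stripping the `*NN` suffix; an allele-level table is
  available via `level="allele"` since figures sometimes quote alleles.
- **Isotype composition** reports counts and percentages over paired
  cells; empty calls count as "unknown".

## Synthetic data

The generators define the desk-scale study conditions used throughout
the tests; they are pure functions of their configuration, seed
included.

**Repertoire** (defaults: 50 lineages, 1500 heavy chains — the same
order as a real caecal PC dataset, scaled down ~1 order of magnitude on
the lineage axis): clone sizes are a deterministic largest-remainder
apportionment of power-law weights (exponent 1.5, minimum clone size 2);
each lineage draws a heavy V and J allele and a random CDR3 (lengths
21–60 nt in codon steps) from a synthetic germline set, plus one light
ancestor. Members accumulate independent per-site substitutions on the
V segment at `shm_rate_per_site` (default 0.02, a typical
germinal-centre SHM load) and at most
`cdr3_mutation_max_fraction` (default 0.10, half the clustering
threshold) substitutions on the CDR3 relative to the ancestor, so the
maximum intra-clone pairwise divergence is ≤ 2× the bound. Same-key
ancestors are rejected until their CDR3s differ by more than
`threshold + 2 × bound`: without that guard, mutated members of two
clones whose ancestors are just beyond the threshold could come within
it, and exact recovery would not be a property of the generator.
Each lineage's first member is single-cell (tissue "caecum", with a
paired light chain); further members are single-cell with probability
0.30, otherwise bulk with a tissue drawn from a shared multinomial over
(PBMC, spleen, mesLN, axLN, BM) = (0.30, 0.08, 0.35, 0.07, 0.20),
reflecting the qualitative ranking seen in vivo (mesenteric lymph node
and blood rich, spleen and axillary nodes scarce). Isotypes follow the
caecal PC mix (IgA 0.83, IgM 0.07, IgG1 0.03, IgE 0.01, IgG3 0.003,
IgG2 0.003, unknown 0.054); each isotype is backed by an exact
constant-region fragment, so isotype assignment is exactly recoverable
when fragments are uncorrupted. Bulk duplicate counts are geometric
(p = 0.5). The ground truth records per-sequence lineage labels and the
*realized* per-tissue counts, which is what presence-recovery is scored
against.

Not emulated: V(D)J recombination machinery, SHM hotspot bias and
indels, UMI/sequencing error, allele ambiguity in the annotations.
Passing recovery tests therefore demonstrates the correctness of the
clustering logic under the stated divergence bounds, not robustness to
annotation noise.

**Expression** (defaults: 600 cells × 1200 genes, 4 clusters, 8 planted
modules of 15 genes): counts are negative-binomial (dispersion r = 2)
with `log μ = baseline + cluster effect + loading × module factor`;
baselines are log-normal (meanlog 0.7, sdlog 0.6) so typical cells carry
~2–3 × 10³ UMIs and ~900 detected genes, comfortably above the QC
floors; cluster effects are N(0, 0.3); module factors are per-cell
standard normal with loading 0.9 (`within_module_correlation`; 0 gives
independent genes). The first 13 genes carry real mitochondrial names
(MT-ND1, …). The trailing cells are planted QC failures constructed
against the fixed QC constants so each violates exactly one rule:
high-mito cells have mitochondrial counts scaled to ~15% of the total;
low-UMI cells carry 600 genes at count 1 (600 UMIs < 1200, 600 genes
≥ 500); low-gene cells carry 450 genes at count 3 (450 < 500,
1350 UMIs ≥ 1200).

Not emulated: ambient RNA, batch effects, real library-size
distributions, dropout beyond the NB sampling.

**Fixture bundle** (`write_fixtures` / `patchrep simulate`): the full
set of files the CLI consumes, with a run config scaled to the fixture
(300 HVGs, 20 modules — the matrix is far smaller than a real dataset);
regeneration with the same seed is byte-identical.

## Problem sizes and determinism

The test-suite and acceptance-script problem sizes — 50 lineages / 1500
chains, 20 oracle repertoires of ≤ 300 records, 500 edit-distance pairs
of length ≤ 7 against the exponential recursion, 100 random GLM
fixtures, 600 × 1200 count matrices — were chosen so every brute-force
oracle remains exactly computable while the statistical checks (binomial
envelopes, Clopper–Pearson intervals at n = 1500) retain power. A single
seed drives each stochastic component; all pipeline stages themselves
are deterministic, and the CLI writes a manifest (config hash, input
checksums, per-stage row counts) so re-runs can be verified identical.

## Known limitations

- Single linkage makes lineage membership sensitive to chaining when
  intra-clone divergence approaches the threshold; the adversarial
  fixtures in the tests document this rather than hide it.
- The percent-deviance statistic with one-vs-rest indicators tests each
  cluster marginally; a multi-level factor model would give one joint
  statistic per module instead.
- Isotype assignment assumes the observed fragment aligns to the
  reference start (amplicon-style data); arbitrary-offset fragments
  would need local alignment.
- The expression simulator's planted-failure constants presume the
  standard QC thresholds; changing those thresholds in `RunConfig`
  does not move the planted cells.
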