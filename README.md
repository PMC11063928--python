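# patchrep

Single-cell gene-module detection and B-cell receptor (BCR)
clonal-lineage tracing for gut-associated lymphoid tissue.

Intestinal plasma cells (PCs) arise in organized lymphoid follicles such
as caecal patches, where germinal-centre B cells hypermutate their
immunoglobulin genes before disseminating antibody-secreting cells
through the body. Studying this process from one animal combines two
data types: a droplet single-cell transcriptome of the tissue's
leukocytes (with paired heavy/light V(D)J transcripts for the PCs), and
deep bulk IgG/IgA heavy-chain repertoires from distal compartments
(blood, spleen, lymph nodes, bone marrow). `patchrep` implements the
bespoke computations such a study needs as a tested, reusable pipeline:

- **QC filters** — remove cells with mitochondrial read fraction
  > 0.10, fewer than 1200 UMIs or fewer than 500 expressed genes
  (strict inequalities), flagged doublets, and cells expressing more
  than one IG heavy or light chain; drop genes detected in fewer than
  10 cells.
- **Gene modules** — over n = 3000 highly variable genes, an unsigned
  weighted co-expression network `a_ij = |cor(x_i, x_j)|^β` (β = 6), its
  topological overlap matrix
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
  Ward agglomeration on `1 − TOM` cut into 100 modules, and per-cell
  module scores from l2-normalised gene vectors.
- **Cluster association** — per module × cell-cluster pair, the percent
  difference between the residual deviances of a Gaussian-identity GLM
  on the cluster indicator and its null model,
  `100 · (D_null − D_fit) / D_null`, which for this family equals
  `100 · R²` of the one-hot regression.
- **Clonal lineages** — heavy chains from single-cell and bulk data
  combined, grouped by identical V and J allele and CDR3 length, then
  single-linkage clustered allowing at most 20% CDR3 nucleotide
  mismatches; lineages with discordant light chains are split by
  light-chain V/J/CDR3-length key, and heavy chains without light-chain
  information are attached to the sub-lineage with the minimum
  Levenshtein distance to a single-cell reference CDR3.
- **Tracing and summaries** — per-tissue lineage relative abundance
  (duplicate-weighted reads over the tissue library total), V/J gene
  usage, somatic hypermutation (% V-gene nucleotide mismatch) by
  compartment, and isotype composition from constant-region alignment.
- **Synthetic data** — simulators for clonal repertoires (power-law
  clone sizes, bounded CDR3 divergence, per-lineage tissue multinomials,
  SHM, isotypes) and negative-binomial count matrices (cluster effects,
  latent-factor gene modules, named mitochondrial genes, planted QC
  failures), each returning ground-truth labels, so the whole pipeline
  is testable at desk scale without any deposited dataset.

## Worked example

```sh
patchrep simulate --out fixtures --seed 5
patchrep pipeline --fixtures fixtures --out run
```

The second command logs, among other lines:

```
INFO patchrep: qc: retained 591/600 cells, 1200 genes
INFO patchrep: modules: 20 modules over 300 HVGs
INFO patchrep: lineages: 50 lineages over 1500 heavy chains
INFO patchrep: trace: 143 lineage/tissue rows, 6 compartments
INFO patchrep: pipeline: lineage ARI vs truth = 1.0000
```

Reading: the nine planted QC failures were removed (591 of 600 cells
retained); the 1500 simulated heavy chains were grouped into exactly the
50 planted clonal families (adjusted Rand index 1.0 against the
simulator's labels); and the traced lineages appear in 143
lineage-by-tissue combinations across the six compartments. Stage
outputs land in `run/` as TSV tables (`lineage_members.tsv`,
`module_association.tsv`, `trace_table.tsv`, `isotype_composition.tsv`,
…) plus a `manifest.json` recording config hash, input checksums and
per-stage row counts.

The same operations are importable as a library:

```python
from patchrep import (RepertoireSimConfig, simulate_repertoire,
                      infer_lineages, pair_cells)

records, truth = simulate_repertoire(RepertoireSimConfig(seed=5))
heavy = [r for r in records if r.locus == "IGH"]
lineages = infer_lineages(heavy, pair_cells(records), threshold=0.20)
print(len(lineages))   # 50
```

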