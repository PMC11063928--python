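"""Single-cell QC filters, co-expression gene-module detection and the
percent-deviance cluster-association statistic.

The module-detection path follows the weighted gene co-expression network
recipe: an unsigned soft-thresholded adjacency over highly variable genes,
its topological overlap matrix (TOM), Ward agglomeration on 1 - TOM cut
to a fixed module count, per-cell module scores from l2-normalised gene
vectors, and, per module x cell-cluster pair, the percent difference
between the residual deviances of a Gaussian-identity GLM with the
cluster indicator as the explaining variable and its null model.  For a
Gaussian identity model the residual deviance is the residual sum of
squares, so the statistic equals 100 x R-squared of the one-hot
regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .config import RunConfig

#: metadata columns the QC filter needs beyond what the matrix computes
QC_META_COLUMNS = ("doublet_flag", "n_heavy_chains", "n_light_chains")


@dataclass
class ExpressionMatrix:
    """Genes x cells count matrix with gene flags and per-cell metadata."""

    counts: sparse.csr_matrix          # genes x cells, non-negative ints
    gene_names: np.ndarray
    cell_ids: np.ndarray
    mito_flag: np.ndarray              # bool per gene
    cell_meta: pd.DataFrame            # indexed by cell_id

    def __post_init__(self):
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.mito_flag = np.asarray(self.mito_flag, dtype=bool)
        if self.counts.shape != (len(self.gene_names), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def total_umi(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def n_genes_detected(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        totals = self.total_umi()
        mito = np.asarray(self.counts[self.mito_flag].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        return frac

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(self.counts[:, mask], self.gene_names,
                                self.cell_ids[mask], self.mito_flag,
                                self.cell_meta.loc[self.cell_ids[mask]])

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(self.counts[mask], self.gene_names[mask],
                                self.cell_ids, self.mito_flag[mask],
                                self.cell_meta)


@dataclass
class QcReport:
    n_input: int
    removed: dict[str, list[str]]       # rule name -> removed cell ids
    retained: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed.items()}


@dataclass
class GeneModule:
    module_id: int
    genes: list[str]
    scores: Optional[np.ndarray] = None


@dataclass
class ModuleAssociation:
    module_id: int
    cluster_id: str
    percent_deviance_difference: float
    deviance_null: float
    deviance_fit: float


def qc_filter_cells(m: ExpressionMatrix,
                    cfg: RunConfig) -> tuple[ExpressionMatrix, QcReport]:
    """Remove cells failing the stated QC rules, in order: (1) more than
    the allowed mitochondrial read fraction (strict >); (2) fewer UMIs or
    fewer expressed genes than the floors (strict <); (3) flagged
    doublets; (4) more than one IG heavy or light chain."""
    for col in QC_META_COLUMNS:
        if col not in m.cell_meta.columns:
            raise KeyError(f"cell metadata is missing required column {col!r}")
    mito = m.mito_fraction()
    umi = m.total_umi()
    genes = m.n_genes_detected()
    meta = m.cell_meta.loc[m.cell_ids]
    doublet = meta["doublet_flag"].to_numpy(dtype=bool)
    heavy = meta["n_heavy_chains"].to_numpy(dtype=int)
    light = meta["n_light_chains"].to_numpy(dtype=int)

    rules = [
        ("high_mito", mito > cfg.mito_max_fraction),
        ("low_depth", (umi < cfg.min_umi) | (genes < cfg.min_genes)),
        ("doublet", doublet),
        ("multi_chain", (heavy > 1) | (light > 1)),
    ]
    alive = np.ones(m.n_cells, dtype=bool)
    removed: dict[str, list[str]] = {}
    for name, fails in rules:
        hit = alive & fails
        removed[name] = [str(c) for c in m.cell_ids[hit]]
        alive &= ~fails
    report = QcReport(m.n_cells, removed, [str(c) for c in m.cell_ids[alive]])
    return m.subset_cells(alive), report


def filter_genes(m: ExpressionMatrix, cfg: RunConfig) -> ExpressionMatrix:
    """Drop genes detected (count > 0) in fewer than the configured number
    of cells."""
    detected = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    return m.subset_genes(detected >= cfg.min_cells_per_gene)


def normalize_log(m: ExpressionMatrix) -> np.ndarray:
    """Library-size normalisation to the median cell total, then
    log(1 + x).  Returns a dense genes x cells float array."""
    totals = m.total_umi()
    if (totals == 0).any():
        bad = m.cell_ids[totals == 0][:5]
        raise ValueError(f"zero-total cells present (e.g. {list(bad)}); "
                         f"run QC filtering first")
    target = float(np.median(totals))
    x = m.counts.toarray().astype(float)
    x *= target / totals
    return np.log1p(x)


def select_hvg(norm: np.ndarray, gene_names: Sequence[str],
               n: int = 3000) -> list[str]:
    """Top-n highly variable genes ranked by dispersion (variance/mean) of
    the variance-stabilised (log-normalised) values; ties broken by gene
    name for determinism.  Genes with zero mean rank last."""
    gene_names = list(gene_names)
    if n > len(gene_names):
        raise ValueError(f"requested {n} HVGs but only "
                         f"{len(gene_names)} genes available")
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1) if norm.shape[1] > 1 else np.zeros(len(gene_names))
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, -np.inf)
    order = sorted(range(len(gene_names)), key=lambda i: (-disp[i], gene_names[i]))
    return [gene_names[i] for i in order[:n]]


def build_adjacency(x: np.ndarray, power: float = 6.0) -> np.ndarray:
    """Unsigned soft-thresholded adjacency: a_ij = |cor(gene_i, gene_j)|^power
    with zero diagonal.  Zero-variance genes get zero correlations."""
    if x.shape[0] < 2:
        raise ValueError("build_adjacency requires at least two genes")
    sd = x.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance genes; their "
                      f"correlations are set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    r[zero_var, :] = 0.0
    r[:, zero_var] = 0.0
    a = np.abs(np.clip(r, -1.0, 1.0)) ** power
    np.fill_diagonal(a, 0.0)
    return a


def compute_tom(a: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap:
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with k_i the row sum of the adjacency and TOM_ii = 1."""
    a = np.asarray(a, dtype=float)
    k = a.sum(axis=1)
    numer = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cut_modules(tom: np.ndarray, gene_names: Sequence[str],
                k: int = 100) -> list[GeneModule]:
    """Ward agglomeration on the dissimilarity 1 - TOM, tree cut to
    exactly k modules.  Modules are numbered 1..k in order of their
    lexicographically smallest member gene."""
    gene_names = list(gene_names)
    if k > len(gene_names):
        raise ValueError(f"cannot cut {len(gene_names)} genes into {k} modules")
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    z = linkage(squareform(d, checks=False), method="ward")
    labels = cut_tree(z, n_clusters=k).ravel()
    groups: dict[int, list[str]] = {}
    for g, lab in zip(gene_names, labels):
        groups.setdefault(int(lab), []).append(g)
    ordered = sorted(groups.values(), key=lambda genes: min(genes))
    return [GeneModule(i, sorted(genes))
            for i, genes in enumerate(ordered, start=1)]


def score_modules(x: np.ndarray, gene_names: Sequence[str],
                  modules: Sequence[GeneModule]) -> pd.DataFrame:
    """Per-cell module scores: each gene's cross-cell expression vector is
    divided by its Euclidean norm (non-negative input, so values fall in
    [0, 1]); a cell's module score is the mean over the module's genes.
    Returns a cells x modules DataFrame (columns = module ids)."""
    index = {g: i for i, g in enumerate(gene_names)}
    covered = sorted(g for mod in modules for g in mod.genes)
    if len(covered) != len(set(covered)) or set(covered) != set(gene_names):
        raise ValueError("modules must partition the gene set")
    norms = np.linalg.norm(x, axis=1)
    unit = np.divide(x, norms[:, None], out=np.zeros_like(x, dtype=float),
                     where=norms[:, None] > 0)
    out = {}
    for mod in modules:
        rows = [index[g] for g in mod.genes]
        out[mod.module_id] = unit[rows].mean(axis=0)
        mod.scores = out[mod.module_id]
    return pd.DataFrame(out)


def test_module_association(scores: pd.DataFrame,
                            cluster_labels: Sequence) -> pd.DataFrame:
    """Percent-deviance association between each module score and each
    cell cluster.

    For a module score y and one-vs-rest cluster indicator, the fitted
    Gaussian-identity GLM deviance D_fit is the residual sum of squares
    about the two group means and D_null the total sum of squares about
    the grand mean; the statistic is 100 x (D_null - D_fit) / D_null.
    """
    labels = np.asarray(cluster_labels)
    if len(labels) != len(scores):
        raise ValueError("cluster_labels length does not match score rows")
    uniq = sorted(set(map(str, labels)))
    labels = labels.astype(str)
    if len(uniq) < 2:
        raise ValueError("at least two non-empty clusters are required")
    rows = []
    for module_id in scores.columns:
        y = scores[module_id].to_numpy(dtype=float)
        d_null = float(((y - y.mean()) ** 2).sum())
        if d_null == 0.0:
            warnings.warn(f"module {module_id}: constant scores, "
                          f"statistic set to 0")
        for cluster in uniq:
            ind = labels == cluster
            if d_null == 0.0:
                rows.append((module_id, cluster, 0.0, 0.0, 0.0))
                continue
            d_fit = float(((y[ind] - y[ind].mean()) ** 2).sum()
                          + ((y[~ind] - y[~ind].mean()) ** 2).sum())
            stat = 100.0 * (d_null - d_fit) / d_null
            rows.append((module_id, cluster, stat, d_null, d_fit))
    return pd.DataFrame(rows, columns=["module_id", "cluster_id",
                                       "percent_deviance_difference",
                                       "deviance_null", "deviance_fit"])


# despite the test_ prefix this is library API, not a pytest test
test_module_association.__test__ = False


def gene_set_score(norm: np.ndarray, gene_names: Sequence[str],
                   gene_sets: Mapping[str, Sequence[str]],
                   cluster_labels: Sequence,
                   eps: float = 1e-9) -> pd.DataFrame:
    """Per-cluster mean normalised expression of each gene set and the
    log2 fold-change against all other cells, with a small pseudocount
    eps guarding against empty means."""
    labels = np.asarray(cluster_labels).astype(str)
    if len(labels) != norm.shape[1]:
        raise ValueError("cluster_labels length does not match cells")
    index = {g: i for i, g in enumerate(gene_names)}
    rows = []
    for set_name in sorted(gene_sets):
        hits = [index[g] for g in gene_sets[set_name] if g in index]
        if not hits:
            raise ValueError(f"gene set {set_name!r} has no genes in the matrix")
        sub = norm[hits]
        for cluster in sorted(set(labels)):
            ind = labels == cluster
            mean_in = float(sub[:, ind].mean())
            mean_rest = float(sub[:, ~ind].mean()) if (~ind).any() else 0.0
            log2fc = float(np.log2((mean_in + eps) / (mean_rest + eps)))
            rows.append((set_name, cluster, mean_in, mean_rest, log2fc))
    return pd.DataFrame(rows, columns=["gene_set", "cluster_id",
                                       "mean_expression", "mean_rest",
                                       "log2_fold_change"])
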