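"""Synthetic repertoires and count matrices with the statistical structure
the analysis assumes, plus ground-truth labels for recovery tests.

The repertoire simulator emits clonal families that share a heavy V/J
allele and CDR3 length, accumulate somatic hypermutation on the V segment
and bounded substitutions on the CDR3, carry isotype labels backed by
constant-region fragments, and disseminate across tissues by a
multinomial.  The expression simulator draws negative-binomial counts
whose log-mean combines a per-gene baseline, a cluster effect and a
per-module latent factor, with named mitochondrial genes and planted
QC-failure cells that each violate exactly one QC rule.

Both simulators are pure functions of their configuration (seed
included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .config import RunConfig
from .expression_modules import ExpressionMatrix
from .lineage_inference import Rearrangement, hamming_fraction

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TISSUES = ("PBMC", "spleen", "mesLN", "axLN", "BM")
#: qualitative ranking from the study: caecal lineages most abundant in
#: mesenteric lymph node and blood, present in bone marrow, scarce in
#: spleen and axillary lymph nodes
DEFAULT_TISSUE_PROBS = (0.30, 0.08, 0.35, 0.07, 0.20)
#: caecal plasma-cell isotype mix (IgA-dominated mucosal repertoire)
DEFAULT_ISOTYPE_PROBS = {
    "IgA": 0.83, "IgM": 0.07, "IgG1": 0.03, "IgE": 0.01,
    "IgG3": 0.003, "IgG2": 0.003, "unknown": 0.054,
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate_rate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent per-site substitution at the given rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return arr.tobytes().decode("ascii")


def _mutate_k(rng: np.random.Generator, seq: str, k: int) -> str:
    """Substitute exactly k distinct positions."""
    if k <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    for i in rng.choice(arr.size, size=k, replace=False):
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return arr.tobytes().decode("ascii")


@dataclass
class GermlineSet:
    """Synthetic germline references: V/J alleles per locus and one
    constant-region fragment per isotype."""

    heavy_v: dict[str, str]
    heavy_j: dict[str, str]
    light_v: dict[str, str]   # IGKV*/IGLV* names
    light_j: dict[str, str]
    constants: dict[str, str]

    @classmethod
    def generate(cls, rng: np.random.Generator, n_heavy_v: int = 15,
                 n_heavy_j: int = 6, n_light_v: int = 8, n_light_j: int = 4,
                 v_length: int = 300, j_length: int = 48,
                 c_length: int = 150) -> "GermlineSet":
        heavy_v = {f"IGHV{i + 1}-1*01": _random_seq(rng, v_length)
                   for i in range(n_heavy_v)}
        heavy_j = {f"IGHJ{i + 1}-1*01": _random_seq(rng, j_length)
                   for i in range(n_heavy_j)}
        light_v, light_j = {}, {}
        for locus in ("IGK", "IGL"):
            for i in range(n_light_v):
                light_v[f"{locus}V{i + 1}-1*01"] = _random_seq(rng, v_length)
            for i in range(n_light_j):
                light_j[f"{locus}J{i + 1}*01"] = _random_seq(rng, j_length)
        isotypes = [iso for iso in DEFAULT_ISOTYPE_PROBS if iso != "unknown"]
        constants = {iso: _random_seq(rng, c_length) for iso in isotypes}
        return cls(heavy_v, heavy_j, light_v, light_j, constants)


@dataclass
class RepertoireSimConfig:
    n_lineages: int = 50
    n_sequences: int = 1500
    clone_size_exponent: float = 1.5
    min_clone_size: int = 2
    shm_rate_per_site: float = 0.02
    cdr3_mutation_max_fraction: float = 0.10
    clustering_threshold: float = 0.20
    cdr3_lengths: Sequence[int] = tuple(range(21, 61, 3))
    tissue_names: Sequence[str] = DEFAULT_TISSUES
    tissue_probabilities: Sequence[float] = DEFAULT_TISSUE_PROBS
    fraction_single_cell: float = 0.30
    isotype_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOTYPE_PROBS))
    germline: Optional[GermlineSet] = None
    seed: int = 1234

    def validate(self) -> "RepertoireSimConfig":
        if self.n_lineages < 1 or self.n_sequences < self.n_lineages:
            raise ValueError("need n_sequences >= n_lineages >= 1")
        if abs(sum(self.isotype_probabilities.values()) - 1.0) > 1e-9:
            raise ValueError("isotype probabilities must sum to 1")
        if abs(sum(self.tissue_probabilities) - 1.0) > 1e-9:
            raise ValueError("tissue probabilities must sum to 1")
        if len(self.tissue_probabilities) != len(self.tissue_names):
            raise ValueError("tissue probability/name length mismatch")
        if not 0.0 <= self.cdr3_mutation_max_fraction < 1.0:
            raise ValueError("cdr3_mutation_max_fraction must be in [0, 1)")
        if not 0.0 < self.fraction_single_cell <= 1.0:
            raise ValueError("fraction_single_cell must be in (0, 1]")
        return self


@dataclass
class RepertoireTruth:
    """Ground truth for lineage-recovery scoring."""

    lineage_of: dict[str, str]                # sequence_id -> true lineage id
    tissue_counts: pd.DataFrame               # lineage x tissue realized counts
    tissue_probabilities: dict[str, dict[str, float]]
    keys: dict[str, tuple[str, str, int]]     # lineage -> (V, J, CDR3 length)
    germline: GermlineSet


def _apportion_sizes(cfg: RepertoireSimConfig) -> list[int]:
    """Deterministic largest-remainder apportionment of n_sequences over
    lineages with power-law weights rank^(-exponent), floored at
    min_clone_size."""
    ranks = np.arange(1, cfg.n_lineages + 1, dtype=float)
    weights = ranks ** (-cfg.clone_size_exponent)
    weights /= weights.sum()
    floor = min(cfg.min_clone_size, cfg.n_sequences // cfg.n_lineages)
    quota = weights * (cfg.n_sequences - floor * cfg.n_lineages)
    sizes = np.floor(quota).astype(int) + floor
    remainder = cfg.n_sequences - sizes.sum()
    order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    sizes[order[:remainder]] += 1
    return sizes.tolist()


def simulate_repertoire(
    cfg: RepertoireSimConfig,
) -> tuple[list[Rearrangement], RepertoireTruth]:
    """Simulate clonal families of heavy chains (single-cell members with
    paired light chains, bulk members with tissue labels) plus ground
    truth.  Deterministic given the config seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    germ = cfg.germline or GermlineSet.generate(rng)
    sizes = _apportion_sizes(cfg)

    # naive ancestors; same-key ancestors are rejected until their CDR3s
    # are separated by more than threshold + 2 x intra-clone bound, so
    # mutated members of distinct clones can never fall within the
    # single-linkage threshold
    min_sep = cfg.clustering_threshold + 2.0 * cfg.cdr3_mutation_max_fraction
    heavy_v_names = sorted(germ.heavy_v)
    heavy_j_names = sorted(germ.heavy_j)
    ancestors = []
    by_key: dict[tuple[str, str, int], list[str]] = {}
    for _ in range(cfg.n_lineages):
        for _attempt in range(1000):
            v = heavy_v_names[rng.integers(len(heavy_v_names))]
            j = heavy_j_names[rng.integers(len(heavy_j_names))]
            length = int(rng.choice(np.asarray(cfg.cdr3_lengths)))
            cdr3 = _random_seq(rng, length)
            clash = any(hamming_fraction(cdr3, other) <= min_sep
                        for other in by_key.get((v, j, length), []))
            if not clash:
                break
        else:
            raise RuntimeError(
                "could not place distinct same-key lineage ancestors after "
                "1000 attempts; reduce n_lineages or widen cdr3_lengths"
            )
        by_key.setdefault((v, j, length), []).append(cdr3)
        # one light ancestor per lineage
        locus = "IGK" if rng.random() < 0.5 else "IGL"
        lv = sorted(n for n in germ.light_v if n.startswith(locus))
        lj = sorted(n for n in germ.light_j if n.startswith(locus))
        light = (locus, lv[rng.integers(len(lv))], lj[rng.integers(len(lj))],
                 _random_seq(rng, int(rng.choice(np.asarray(cfg.cdr3_lengths)))))
        ancestors.append((v, j, cdr3, light))

    isotypes = sorted(cfg.isotype_probabilities)
    iso_probs = np.array([cfg.isotype_probabilities[i] for i in isotypes])
    tissue_probs = np.asarray(cfg.tissue_probabilities, dtype=float)

    records: list[Rearrangement] = []
    lineage_of: dict[str, str] = {}
    tissue_counts = {t: np.zeros(cfg.n_lineages, dtype=int)
                     for t in cfg.tissue_names}
    caecum_counts = np.zeros(cfg.n_lineages, dtype=int)
    keys = {}
    serial = 0
    for li, ((v, j, cdr3_anc, light), size) in enumerate(zip(ancestors, sizes)):
        true_id = f"T{li + 1:04d}"
        keys[true_id] = (v, j, len(cdr3_anc))
        germ_v = germ.heavy_v[v]
        germ_j = germ.heavy_j[j]
        max_k = math.floor(cfg.cdr3_mutation_max_fraction * len(cdr3_anc))
        l_locus, l_v, l_j, l_cdr3 = light
        for mi in range(size):
            serial += 1
            is_sc = mi == 0 or rng.random() < cfg.fraction_single_cell
            v_seq = _mutate_rate(rng, germ_v, cfg.shm_rate_per_site)
            cdr3 = _mutate_k(rng, cdr3_anc, int(rng.integers(0, max_k + 1)))
            iso = isotypes[rng.choice(len(isotypes), p=iso_probs)]
            v_ident = 1.0 - hamming_fraction(v_seq, germ_v) \
                if v_seq != germ_v else 1.0
            common = dict(
                v_call=v, j_call=j, cdr3=cdr3, c_call=iso,
                c_region=germ.constants.get(iso, ""),
                v_identity=v_ident, v_sequence=v_seq,
                sequence=v_seq + cdr3 + germ_j,
            )
            if is_sc:
                cell_id = f"cell{serial:05d}"
                sid = f"sc{serial:05d}-H"
                records.append(Rearrangement(
                    sequence_id=sid, locus="IGH", cell_id=cell_id,
                    tissue="caecum", source="single_cell",
                    duplicate_count=1, **common))
                lineage_of[sid] = true_id
                caecum_counts[li] += 1
                lv_seq = _mutate_rate(rng, germ.light_v[l_v],
                                      cfg.shm_rate_per_site)
                lid = f"sc{serial:05d}-L"
                records.append(Rearrangement(
                    sequence_id=lid, locus=l_locus, v_call=l_v, j_call=l_j,
                    cdr3=l_cdr3, cell_id=cell_id, tissue="caecum",
                    source="single_cell", duplicate_count=1,
                    v_identity=1.0 - hamming_fraction(lv_seq, germ.light_v[l_v])
                    if lv_seq != germ.light_v[l_v] else 1.0,
                    v_sequence=lv_seq))
                lineage_of[lid] = true_id
            else:
                tissue = cfg.tissue_names[rng.choice(len(tissue_probs),
                                                     p=tissue_probs)]
                sid = f"bk{serial:05d}"
                records.append(Rearrangement(
                    sequence_id=sid, locus="IGH", tissue=tissue,
                    source="bulk",
                    duplicate_count=int(rng.geometric(0.5)), **common))
                lineage_of[sid] = true_id
                tissue_counts[tissue][li] += 1

    counts_df = pd.DataFrame(tissue_counts,
                             index=[f"T{i + 1:04d}"
                                    for i in range(cfg.n_lineages)])
    counts_df.insert(0, "caecum", caecum_counts)
    probs = {f"T{i + 1:04d}": dict(zip(cfg.tissue_names, tissue_probs))
             for i in range(cfg.n_lineages)}
    truth = RepertoireTruth(lineage_of, counts_df.rename_axis("lineage_id"),
                            probs, keys, germ)
    return records, truth


@dataclass
class ExpressionSimConfig:
    n_cells: int = 600
    n_genes: int = 1200
    n_clusters: int = 4
    n_modules: int = 8
    module_size: int = 15
    within_module_correlation: float = 0.9   # latent-factor loading
    cluster_effect_sd: float = 0.3
    nb_dispersion: float = 2.0
    base_log_mean: float = 0.7
    base_log_sd: float = 0.6
    mito_gene_count: int = 13
    n_high_mito: int = 3
    n_low_umi: int = 3
    n_low_gene: int = 3
    seed: int = 1234

    def validate(self) -> "ExpressionSimConfig":
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules x module_size must be <= n_genes")
        if not 0.0 <= self.within_module_correlation <= 1.0:
            raise ValueError("within_module_correlation must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        n_planted = self.n_high_mito + self.n_low_umi + self.n_low_gene
        if n_planted >= self.n_cells:
            raise ValueError("planted QC failures exceed cell count")
        if self.mito_gene_count > self.n_genes:
            raise ValueError("mito_gene_count exceeds n_genes")
        if self.n_low_umi and self.n_genes - self.mito_gene_count < 600:
            raise ValueError("planted low-UMI cells need >= 600 non-mito "
                             "genes to pass the expressed-gene floor")
        if self.n_low_gene and self.n_genes - self.mito_gene_count < 450:
            raise ValueError("planted low-gene cells need >= 450 non-mito "
                             "genes to pass the UMI floor")
        return self


_MITO_NAMES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6",
               "MT-CO3", "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6",
               "MT-CYB")


@dataclass
class ExpressionTruth:
    module_of: dict[str, int]      # gene -> module id (0 = background)
    cluster_of: dict[str, str]     # cell -> cluster label
    planted: dict[str, str]        # cell -> failure type


def simulate_expression(
    cfg: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Negative-binomial counts with cluster effects and correlated gene
    modules driven by per-cell latent factors; the last cells are planted
    QC failures, each violating exactly one QC rule against the study's
    thresholds (mito fraction > 0.10, UMIs < 1200, genes < 500)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    mito_names = [(_MITO_NAMES[i] if i < len(_MITO_NAMES) else f"MT-X{i}")
                  for i in range(cfg.mito_gene_count)]
    gene_names = mito_names + [f"GENE{i + 1:05d}"
                               for i in range(cfg.n_genes - cfg.mito_gene_count)]
    cell_ids = [f"cellE{i + 1:05d}" for i in range(cfg.n_cells)]

    # module membership over non-mito genes
    module_of = {g: 0 for g in gene_names}
    non_mito = gene_names[cfg.mito_gene_count:]
    for m in range(cfg.n_modules):
        for g in non_mito[m * cfg.module_size:(m + 1) * cfg.module_size]:
            module_of[g] = m + 1
    module_idx = np.array([module_of[g] for g in gene_names])

    clusters = rng.integers(0, cfg.n_clusters, size=cfg.n_cells)
    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    cluster_eff = rng.normal(0.0, cfg.cluster_effect_sd,
                             size=(cfg.n_genes, cfg.n_clusters))
    factors = rng.normal(size=(cfg.n_modules + 1, cfg.n_cells))
    factors[0] = 0.0  # background genes load on nothing

    log_mu = base[:, None] + cluster_eff[:, clusters]
    log_mu += cfg.within_module_correlation * factors[module_idx]
    mu = np.exp(log_mu)
    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    # planted QC failures occupy the trailing cells; constants are chosen
    # against the fixed QC thresholds (0.10 / 1200 / 500) so each cell
    # violates exactly one rule
    planted: dict[str, str] = {}
    n_mito = cfg.mito_gene_count
    col = cfg.n_cells
    for _ in range(cfg.n_low_gene):
        col -= 1
        counts[:, col] = 0
        hit = rng.choice(np.arange(n_mito, cfg.n_genes),
                         size=min(450, cfg.n_genes - n_mito), replace=False)
        counts[hit, col] = 3           # 450 genes < 500; 1350 UMIs >= 1200
        planted[cell_ids[col]] = "low_gene"
    for _ in range(cfg.n_low_umi):
        col -= 1
        counts[:, col] = 0
        hit = rng.choice(np.arange(n_mito, cfg.n_genes),
                         size=min(600, cfg.n_genes - n_mito), replace=False)
        counts[hit, col] = 1           # 600 genes >= 500; 600 UMIs < 1200
        planted[cell_ids[col]] = "low_umi"
    for _ in range(cfg.n_high_mito):
        col -= 1
        non_mito_total = counts[n_mito:, col].sum()
        target = int(np.ceil(0.15 / 0.85 * non_mito_total)) + n_mito
        per_gene = target // n_mito + 1
        counts[:n_mito, col] = per_gene  # mito fraction > 0.10, depth kept
        planted[cell_ids[col]] = "high_mito"

    meta = pd.DataFrame({
        "cell_id": cell_ids,
        "cluster": [f"C{c}" for c in clusters],
        "doublet_flag": False,
        "n_heavy_chains": 1,
        "n_light_chains": 1,
    }).set_index("cell_id")
    matrix = ExpressionMatrix(
        sparse.csr_matrix(counts), np.array(gene_names, dtype=object),
        np.array(cell_ids, dtype=object),
        np.array([g.startswith("MT-") for g in gene_names]), meta)
    truth = ExpressionTruth(module_of,
                            dict(zip(cell_ids, meta["cluster"])), planted)
    return matrix, truth


def write_fixtures(outdir,
                   repertoire_config: Optional[RepertoireSimConfig] = None,
                   expression_config: Optional[ExpressionSimConfig] = None,
                   seed: Optional[int] = None) -> dict[str, Path]:
    """Write a complete fixture bundle every pipeline stage accepts:
    single-cell and per-tissue bulk rearrangement TSVs, constant-region
    FASTA, counts MTX with name files and metadata, a run config scaled
    to the fixture, and ground-truth TSVs.  Regeneration with the same
    seed is byte-identical."""
    from . import io_formats  # deferred: io_formats imports ExpressionMatrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep_cfg = repertoire_config or RepertoireSimConfig()
    expr_cfg = expression_config or ExpressionSimConfig()
    if seed is not None:
        rep_cfg = RepertoireSimConfig(**{**rep_cfg.__dict__, "seed": seed})
        expr_cfg = ExpressionSimConfig(**{**expr_cfg.__dict__,
                                          "seed": seed + 1})

    records, rep_truth = simulate_repertoire(rep_cfg)
    matrix, expr_truth = simulate_expression(expr_cfg)

    paths: dict[str, Path] = {}
    sc = [r for r in records if r.source == "single_cell"]
    paths["sc_airr"] = outdir / "sc_airr.tsv"
    io_formats.write_airr(sc, paths["sc_airr"])
    for tissue in rep_cfg.tissue_names:
        bulk = [r for r in records if r.source == "bulk" and r.tissue == tissue]
        p = outdir / f"bulk_{tissue}.tsv"
        io_formats.write_airr(bulk, p)
        paths[f"bulk_{tissue}"] = p

    paths["c_regions"] = outdir / "c_regions.fasta"
    io_formats.write_fasta(rep_truth.germline.constants, paths["c_regions"])
    paths["germline_v"] = outdir / "germline_v.fasta"
    io_formats.write_fasta(rep_truth.germline.heavy_v, paths["germline_v"])

    paths["mtx"] = outdir / "counts.mtx"
    paths["genes"] = outdir / "genes.txt"
    paths["cells"] = outdir / "cells.txt"
    paths["metadata"] = outdir / "cell_metadata.tsv"
    io_formats.write_counts(matrix, paths["mtx"], paths["genes"],
                            paths["cells"], paths["metadata"])

    run_cfg = RunConfig(hvg_count=min(300, expr_cfg.n_genes),
                        module_count=min(20, expr_cfg.n_genes),
                        seed=rep_cfg.seed)
    paths["config"] = outdir / "config.yaml"
    run_cfg.to_yaml(paths["config"])

    paths["truth_lineages"] = outdir / "truth_lineages.tsv"
    pd.DataFrame(sorted(rep_truth.lineage_of.items()),
                 columns=["sequence_id", "lineage_id"]).to_csv(
        paths["truth_lineages"], sep="\t", index=False)
    paths["truth_tissue_counts"] = outdir / "truth_tissue_counts.tsv"
    rep_truth.tissue_counts.to_csv(paths["truth_tissue_counts"], sep="\t")
    paths["truth_modules"] = outdir / "truth_modules.tsv"
    pd.DataFrame(sorted(expr_truth.module_of.items()),
                 columns=["gene", "module_id"]).to_csv(
        paths["truth_modules"], sep="\t", index=False)
    return paths
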