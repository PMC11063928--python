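"""Run configuration shared by every pipeline stage.

The defaults are the study's stated analysis constants: cells with more
than 10% mitochondrial reads, fewer than 1200 UMIs or fewer than 500
expressed genes are excluded; genes detected in fewer than 10 cells are
dropped; 3000 highly variable genes feed the co-expression network, which
is cut into 100 modules; clonal lineages tolerate at most 20% CDR3
nucleotide mismatches.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    mito_max_fraction: float = 0.10
    min_umi: int = 1200
    min_genes: int = 500
    min_cells_per_gene: int = 10
    hvg_count: int = 3000
    module_count: int = 100
    adjacency_power: float = 6.0
    cdr3_mismatch_max_fraction: float = 0.20
    isotype_min_score: float = 0.90
    mito_prefix: str = "MT-"
    seed: int = 1234

    def validate(self) -> "RunConfig":
        for name in ("min_umi", "min_genes", "min_cells_per_gene",
                     "hvg_count", "module_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mito_max_fraction", "cdr3_mismatch_max_fraction",
                     "isotype_min_score"):
            frac = getattr(self, name)
            if not 0.0 < frac <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {frac!r}")
        if self.adjacency_power <= 0:
            raise ValueError("adjacency_power must be positive")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable hash of the configuration for run manifests."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
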