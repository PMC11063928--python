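"""Cross-compartment tracing of caecal clonal lineages: per-tissue
relative abundance, somatic-hypermutation summaries, V/J gene usage and
isotype composition."""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .lineage_inference import Lineage, PairedCell, Rearrangement


def _by_tissue(bulk: Union[Mapping[str, Sequence[Rearrangement]],
                           Iterable[Rearrangement]]
               ) -> dict[str, list[Rearrangement]]:
    if isinstance(bulk, Mapping):
        return {t: list(rs) for t, rs in bulk.items()}
    out: dict[str, list[Rearrangement]] = {}
    for r in bulk:
        out.setdefault(r.tissue, []).append(r)
    return out


def trace_lineages(lineages: Sequence[Lineage],
                   bulk_by_tissue) -> pd.DataFrame:
    """Per lineage x tissue: member count, duplicate-weighted read count
    and relative abundance (reads of the lineage / total reads of that
    tissue's library).  Lineage/tissue pairs with no members are omitted;
    rows are sorted for determinism.

    `bulk_by_tissue` is either a mapping tissue -> bulk records (the full
    library, traced or not, defining the denominators) or a flat iterable
    of tissue-labelled bulk records.
    """
    libraries = _by_tissue(bulk_by_tissue)
    totals = {t: sum(r.duplicate_count for r in rs)
              for t, rs in libraries.items()}
    for tissue, total in totals.items():
        if total == 0:
            raise ValueError(f"tissue {tissue!r} has zero total reads")
    rows = []
    for lin in lineages:
        per_tissue: dict[str, list[Rearrangement]] = {}
        for m in lin.bulk_members:
            per_tissue.setdefault(m.tissue, []).append(m)
        for tissue in sorted(per_tissue):
            if tissue not in totals:
                raise ValueError(f"lineage {lin.lineage_id} has members in "
                                 f"unknown tissue {tissue!r}")
            reads = sum(m.duplicate_count for m in per_tissue[tissue])
            rows.append((lin.lineage_id, tissue, len(per_tissue[tissue]),
                         reads, reads / totals[tissue]))
    return pd.DataFrame(rows, columns=["lineage_id", "tissue", "member_count",
                                       "read_count", "relative_abundance"]
                        ).sort_values(["lineage_id", "tissue"],
                                      ignore_index=True)


def shm_by_compartment(lineages: Sequence[Lineage],
                       compartments: Optional[Sequence[str]] = None
                       ) -> pd.DataFrame:
    """Per compartment (tissue label of traced lineage members): n, mean,
    median and quartiles of heavy-chain V-gene SHM%.  Compartments named
    in `compartments` but holding no traced members get an n=0 row with
    empty statistics."""
    values: dict[str, list[float]] = {}
    for lin in lineages:
        for m in lin.members:
            shm = m.v_shm_percent
            if shm is not None:
                values.setdefault(m.tissue, []).append(shm)
    names = sorted(set(values) | set(compartments or ()))
    rows = []
    for tissue in names:
        v = np.asarray(values.get(tissue, []), dtype=float)
        if v.size:
            rows.append((tissue, v.size, v.mean(), np.median(v),
                         np.percentile(v, 25), np.percentile(v, 75)))
        else:
            rows.append((tissue, 0, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["compartment", "n", "mean_shm",
                                       "median_shm", "q25_shm", "q75_shm"])


def _gene_name(call: str, level: str) -> str:
    primary = sorted(c.strip() for c in call.split(",") if c.strip())[0]
    return primary if level == "allele" else primary.split("*")[0]


def vj_usage(records: Sequence[Rearrangement],
             level: str = "gene") -> pd.DataFrame:
    """Heavy-chain V and J usage: per-sequence counts (not duplicate
    weighted) with frequencies normalised within each segment class.
    `level` 'gene' collapses alleles by stripping the '*NN' suffix;
    'allele' keeps full allele names."""
    if level not in ("gene", "allele"):
        raise ValueError("level must be 'gene' or 'allele'")
    counts: dict[tuple[str, str], int] = {}
    for r in records:
        if r.locus != "IGH":
            continue
        for segment, call in (("V", r.v_call), ("J", r.j_call)):
            key = (segment, _gene_name(call, level))
            counts[key] = counts.get(key, 0) + 1
    totals = {"V": sum(c for (s, _), c in counts.items() if s == "V"),
              "J": sum(c for (s, _), c in counts.items() if s == "J")}
    rows = [(segment, gene, n, n / totals[segment])
            for (segment, gene), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["segment", "gene", "count",
                                       "frequency"])


def isotype_composition(cells: Union[Mapping[str, PairedCell],
                                     Sequence[PairedCell]]) -> pd.DataFrame:
    """Isotype counts and percentages over paired cells (heavy-chain
    c_call; empty calls count as 'unknown')."""
    items = list(cells.values()) if isinstance(cells, Mapping) else list(cells)
    if not items:
        raise ValueError("isotype_composition requires at least one cell")
    counts: dict[str, int] = {}
    for cell in items:
        iso = cell.heavy.c_call or "unknown"
        counts[iso] = counts.get(iso, 0) + 1
    total = len(items)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [(iso, n, 100.0 * n / total) for iso, n in rows],
        columns=["isotype", "count", "percent"])
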