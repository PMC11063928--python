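"""Readers and writers for the formats the pipeline touches.

AIRR-style rearrangement tables (tab-separated, UTF-8, header row, empty
string = missing), MatrixMarket count matrices with gene/cell name files
and a per-cell metadata TSV, and FASTA references.  All readers/writers
round-trip: writing then reading yields semantically identical objects.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as scipy_io
from scipy import sparse

from .expression_modules import ExpressionMatrix
from .lineage_inference import Rearrangement


class AirrFormatError(ValueError):
    """Malformed rearrangement table."""


REQUIRED_COLUMNS = ("sequence_id", "locus", "v_call", "j_call", "cdr3")
COLUMN_ORDER = REQUIRED_COLUMNS + (
    "cell_id", "c_call", "tissue", "source", "duplicate_count",
    "v_identity", "sequence", "v_sequence", "c_region",
)
VALID_LOCI = {"IGH", "IGK", "IGL"}
_CDR3_RE = re.compile(r"^[ACGTN]+$")


def read_airr(path) -> list[Rearrangement]:
    """Read a rearrangement TSV into records.

    Missing optional columns get documented defaults: duplicate_count 1,
    source inferred from cell_id presence (non-empty -> single_cell).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AirrFormatError(f"{path}: missing required column(s) "
                              f"{', '.join(missing)}")
    for col in COLUMN_ORDER:
        if col not in df.columns:
            df[col] = ""

    ids = df["sequence_id"]
    dup_ids = ids[ids.duplicated()].unique()
    if len(dup_ids):
        raise AirrFormatError(f"{path}: duplicate sequence_id(s): "
                              f"{', '.join(dup_ids[:5])}")
    bad_cdr3 = [sid for sid, c in zip(ids, df["cdr3"])
                if not _CDR3_RE.match(c or "")]
    if bad_cdr3:
        raise AirrFormatError(f"{path}: non-ACGTN or empty cdr3 for "
                              f"sequence_id(s): {', '.join(bad_cdr3[:5])}")
    bad_locus = sorted(set(df["locus"]) - VALID_LOCI)
    if bad_locus:
        raise AirrFormatError(f"{path}: invalid locus value(s): {bad_locus}")

    records = []
    for row in df.itertuples(index=False):
        source = row.source or ("single_cell" if row.cell_id else "bulk")
        if source == "single_cell" and not row.cell_id:
            raise AirrFormatError(f"{path}: single_cell row "
                                  f"{row.sequence_id!r} lacks cell_id")
        if source == "bulk" and row.cell_id:
            raise AirrFormatError(f"{path}: bulk row {row.sequence_id!r} "
                                  f"carries a cell_id")
        records.append(Rearrangement(
            sequence_id=row.sequence_id,
            locus=row.locus,
            v_call=row.v_call,
            j_call=row.j_call,
            cdr3=row.cdr3,
            cell_id=row.cell_id,
            c_call=row.c_call,
            tissue=row.tissue,
            source=source,
            duplicate_count=int(row.duplicate_count or 1),
            v_identity=float(row.v_identity) if row.v_identity else None,
            sequence=row.sequence,
            v_sequence=row.v_sequence,
            c_region=row.c_region,
        ))
    return records


def write_airr(records: Iterable[Rearrangement], path) -> None:
    """Write records as a rearrangement TSV with fixed column order."""
    rows = []
    for r in records:
        rows.append({
            "sequence_id": r.sequence_id, "locus": r.locus,
            "v_call": r.v_call, "j_call": r.j_call, "cdr3": r.cdr3,
            "cell_id": r.cell_id, "c_call": r.c_call, "tissue": r.tissue,
            "source": r.source, "duplicate_count": r.duplicate_count,
            "v_identity": "" if r.v_identity is None else repr(r.v_identity),
            "sequence": r.sequence, "v_sequence": r.v_sequence,
            "c_region": r.c_region,
        })
    df = pd.DataFrame(rows, columns=list(COLUMN_ORDER))
    df.to_csv(path, sep="\t", index=False)


def _read_names(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_counts(mtx_path, genes_path, cells_path, metadata_path,
                mito_prefix: str = "MT-") -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from MatrixMarket counts, gene/cell
    name files and a per-cell metadata TSV.

    Mitochondrial genes are flagged by a case-insensitive name prefix.
    Metadata must list every cell; optional columns default to cluster
    "0", doublet_flag False and one heavy/one light chain.
    """
    counts = sparse.csr_matrix(scipy_io.mmread(mtx_path))
    genes = _read_names(genes_path)
    cells = _read_names(cells_path)
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match {len(genes)} genes "
            f"x {len(cells)} cells in the name files"
        )
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("negative entries in count matrix")

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"cell_id": str})
    if "cell_id" not in meta.columns:
        raise ValueError("metadata is missing required column 'cell_id'")
    meta = meta.set_index("cell_id")
    absent = [c for c in cells if c not in meta.index]
    if absent:
        raise ValueError(f"metadata lacks rows for cells: {absent[:5]}")
    meta = meta.loc[cells]
    defaults = {"cluster": "0", "doublet_flag": False,
                "n_heavy_chains": 1, "n_light_chains": 1}
    for col, default in defaults.items():
        if col not in meta.columns:
            meta[col] = default
    if meta["doublet_flag"].dtype == object:
        meta["doublet_flag"] = meta["doublet_flag"].astype(str).str.lower().isin(
            ("true", "1"))
    meta["cluster"] = meta["cluster"].astype(str)

    mito = np.array([g.upper().startswith(mito_prefix.upper()) for g in genes])
    return ExpressionMatrix(counts, np.array(genes, dtype=object),
                            np.array(cells, dtype=object), mito, meta)


def write_counts(m: ExpressionMatrix, mtx_path, genes_path, cells_path,
                 metadata_path) -> None:
    scipy_io.mmwrite(str(mtx_path), sparse.coo_matrix(m.counts), field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in m.gene_names))
    Path(cells_path).write_text("".join(f"{c}\n" for c in m.cell_ids))
    m.cell_meta.rename_axis("cell_id").reset_index().to_csv(
        metadata_path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA to a name -> upper-cased sequence mapping; duplicate names
    are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA record name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
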