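"""B-cell receptor clonal-lineage inference over combined single-cell and
bulk heavy chains.

A clonal lineage groups rearrangements that plausibly descend from one
V(D)J recombination event: identical V and J allele assignment, identical
CDR3 length, and at most a bounded fraction of nucleotide mismatches
between CDR3s (default 20%, single linkage).  Lineages whose single-cell
members carry discordant light chains are split by light-chain key
(light V allele, J allele, CDR3 length); heavy chains that carry no light
chain — all bulk reads, plus unpaired cells — are then attached to the
sub-lineage whose single-cell reference CDR3 is nearest by Levenshtein
distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

HEAVY_LOCUS = "IGH"
LIGHT_LOCI = ("IGK", "IGL")

ISOTYPES = ("IgA", "IgM", "IgG1", "IgG2", "IgG3", "IgG4", "IgE")


@dataclass
class Rearrangement:
    """One annotated IG chain (heavy or light), single-cell or bulk."""

    sequence_id: str
    locus: str
    v_call: str
    j_call: str
    cdr3: str
    cell_id: str = ""
    c_call: str = ""
    tissue: str = ""
    source: str = ""  # "single_cell" or "bulk"
    duplicate_count: int = 1
    v_identity: Optional[float] = None
    sequence: str = ""
    v_sequence: str = ""
    c_region: str = ""

    @property
    def v_shm_percent(self) -> Optional[float]:
        """Somatic hypermutation of the V segment, % nucleotide mismatch
        to germline, derived from the annotator's v_identity fraction."""
        if self.v_identity is None:
            return None
        return 100.0 * (1.0 - self.v_identity)


@dataclass(frozen=True)
class LineageKey:
    v_call: str
    j_call: str
    cdr3_length: int


@dataclass
class PairedCell:
    cell_id: str
    heavy: Rearrangement
    light: Rearrangement


@dataclass
class Lineage:
    lineage_id: str
    heavy_key: LineageKey
    members: list[Rearrangement] = field(default_factory=list)
    light_key: Optional[LineageKey] = None
    parent_id: Optional[str] = None
    unresolved: bool = False

    @property
    def member_ids(self) -> list[str]:
        return [m.sequence_id for m in self.members]

    @property
    def single_cell_members(self) -> list[Rearrangement]:
        return [m for m in self.members if m.source == "single_cell"]

    @property
    def bulk_members(self) -> list[Rearrangement]:
        return [m for m in self.members if m.source == "bulk"]


def hamming_fraction(a: str, b: str) -> float:
    """Fraction of mismatching positions between equal-length strings.

    N versus any other base counts as a mismatch; N versus N matches.
    """
    if len(a) != len(b):
        raise ValueError(
            f"hamming_fraction requires equal lengths ({len(a)} != {len(b)})"
        )
    if len(a) == 0:
        raise ValueError("hamming_fraction requires non-empty sequences")
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return float((aa != bb).mean())


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion),
    iterative two-row dynamic programme."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1,          # deletion
                           cur[j - 1] + 1,       # insertion
                           prev[j - 1] + (ca != cb)))  # substitution
        prev = cur
    return prev[-1]


def _alleles(call: str) -> frozenset[str]:
    """Split a possibly comma-joined ambiguous allele call into a set."""
    return frozenset(c.strip() for c in call.split(",") if c.strip())


def _primary_allele(call: str) -> str:
    parts = sorted(_alleles(call))
    return parts[0] if parts else ""


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def records_cluster_together(a: Rearrangement, b: Rearrangement,
                             threshold: float) -> bool:
    """Pairwise clonal predicate: overlapping V and J allele sets, equal
    CDR3 length, CDR3 mismatch fraction within the threshold (inclusive)."""
    if len(a.cdr3) != len(b.cdr3):
        return False
    if not (_alleles(a.v_call) & _alleles(b.v_call)):
        return False
    if not (_alleles(a.j_call) & _alleles(b.j_call)):
        return False
    return hamming_fraction(a.cdr3, b.cdr3) <= threshold


def cluster_heavy_lineages(records: Sequence[Rearrangement],
                           threshold: float = 0.20) -> list[Lineage]:
    """Partition heavy chains into clonal lineages.

    Single-linkage: two records belong to the same lineage if connected
    by a chain of pairwise matches under :func:`records_cluster_together`.
    Lineage ids are deterministic (sorted by key, then by the smallest
    member sequence_id).
    """
    recs = sorted(records, key=lambda r: r.sequence_id)
    for r in recs:
        if r.locus != HEAVY_LOCUS:
            raise ValueError(
                f"cluster_heavy_lineages expects IGH records, got locus "
                f"{r.locus!r} for {r.sequence_id!r}"
            )
        if not r.cdr3:
            raise ValueError(f"empty CDR3 for {r.sequence_id!r}")

    by_length: dict[int, list[int]] = {}
    for idx, r in enumerate(recs):
        by_length.setdefault(len(r.cdr3), []).append(idx)

    uf = _UnionFind(len(recs))
    for idxs in by_length.values():
        # candidate pairs pre-bucketed by (primary V, primary J) would be
        # exact-key grouping; the full pairwise scan also honours ambiguous
        # multi-allele calls (set overlap), which is not transitive.
        for pos, i in enumerate(idxs):
            for j in idxs[pos + 1:]:
                if records_cluster_together(recs[i], recs[j], threshold):
                    uf.union(i, j)

    groups: dict[int, list[Rearrangement]] = {}
    for idx, r in enumerate(recs):
        groups.setdefault(uf.find(idx), []).append(r)

    lineages = []
    for members in groups.values():
        members.sort(key=lambda r: r.sequence_id)
        rep = members[0]
        key = LineageKey(_primary_allele(rep.v_call),
                         _primary_allele(rep.j_call), len(rep.cdr3))
        lineages.append(Lineage("", key, members))
    lineages.sort(key=lambda l: (l.heavy_key.v_call, l.heavy_key.j_call,
                                 l.heavy_key.cdr3_length, l.members[0].sequence_id))
    for i, lin in enumerate(lineages, start=1):
        lin.lineage_id = f"L{i:04d}"
    return lineages


def pair_cells(records: Iterable[Rearrangement]) -> dict[str, PairedCell]:
    """Group single-cell records into cells with exactly one heavy and one
    light chain; cells violating that (which QC should have removed) are
    dropped with a warning."""
    by_cell: dict[str, list[Rearrangement]] = {}
    for r in records:
        if r.source == "single_cell" and r.cell_id:
            by_cell.setdefault(r.cell_id, []).append(r)
    cells: dict[str, PairedCell] = {}
    n_dropped = 0
    for cell_id, chains in by_cell.items():
        heavy = [c for c in chains if c.locus == HEAVY_LOCUS]
        light = [c for c in chains if c.locus in LIGHT_LOCI]
        if len(heavy) == 1 and len(light) == 1:
            cells[cell_id] = PairedCell(cell_id, heavy[0], light[0])
        else:
            n_dropped += 1
    if n_dropped:
        warnings.warn(f"pair_cells dropped {n_dropped} cells without "
                      f"exactly one heavy and one light chain")
    return cells


def _light_key(light: Rearrangement) -> LineageKey:
    return LineageKey(_primary_allele(light.v_call),
                      _primary_allele(light.j_call), len(light.cdr3))


def refine_by_light_chain(
    lineages: Sequence[Lineage],
    cells: Mapping[str, PairedCell],
) -> tuple[list[Lineage], dict[str, list[Rearrangement]]]:
    """Split heavy-chain lineages whose single-cell members carry more than
    one distinct light-chain key.

    Returns the refined lineage list plus, per split parent lineage, the
    members that carry no light chain (all bulk reads and unpaired
    single-cell members); those are attached by :func:`resolve_divergent`.
    """
    refined: list[Lineage] = []
    unassigned: dict[str, list[Rearrangement]] = {}
    for lin in lineages:
        keyed: dict[LineageKey, list[Rearrangement]] = {}
        keyless: list[Rearrangement] = []
        for m in lin.members:
            if m.source == "single_cell" and m.cell_id in cells:
                keyed.setdefault(_light_key(cells[m.cell_id].light), []).append(m)
            elif m.source == "single_cell":
                keyless.append(m)  # no paired light chain: route onward
            else:
                keyless.append(m)
        if len(keyed) <= 1:
            lin.light_key = next(iter(keyed), None)
            refined.append(lin)
            continue
        subs = []
        for j, key in enumerate(sorted(keyed, key=lambda k: (k.v_call, k.j_call,
                                                             k.cdr3_length)),
                                start=1):
            subs.append(Lineage(f"{lin.lineage_id}.{j}", lin.heavy_key,
                                sorted(keyed[key], key=lambda r: r.sequence_id),
                                light_key=key, parent_id=lin.lineage_id))
        refined.extend(subs)
        unassigned[lin.lineage_id] = sorted(keyless, key=lambda r: r.sequence_id)
    return refined, unassigned


def resolve_divergent(
    lineages: Sequence[Lineage],
    unassigned: Mapping[str, Sequence[Rearrangement]],
) -> list[Lineage]:
    """Attach light-chain-less heavy chains of split lineages to the
    sub-lineage whose single-cell heavy CDR3 is nearest by Levenshtein
    distance (ties to the lowest sub-lineage id)."""
    out = [Lineage(l.lineage_id, l.heavy_key, list(l.members), l.light_key,
                   l.parent_id, l.unresolved) for l in lineages]
    by_parent: dict[str, list[Lineage]] = {}
    for lin in out:
        if lin.parent_id is not None:
            by_parent.setdefault(lin.parent_id, []).append(lin)
    for parent_id in sorted(unassigned):
        records = unassigned[parent_id]
        subs = sorted(by_parent.get(parent_id, []), key=lambda l: l.lineage_id)
        refs = [(lin, [m.cdr3 for m in lin.single_cell_members]) for lin in subs]
        refs = [(lin, cdr3s) for lin, cdr3s in refs if cdr3s]
        if not refs:
            residual_key = (records[0] if records else None)
            key = subs[0].heavy_key if subs else LineageKey(
                _primary_allele(residual_key.v_call),
                _primary_allele(residual_key.j_call), len(residual_key.cdr3))
            out.append(Lineage(f"{parent_id}.unresolved", key, list(records),
                               parent_id=parent_id, unresolved=True))
            continue
        for rec in records:
            best = min(refs, key=lambda item: (
                min(levenshtein(rec.cdr3, c) for c in item[1]),
                item[0].lineage_id))
            best[0].members.append(rec)
    for lin in out:
        lin.members.sort(key=lambda r: r.sequence_id)
    out.sort(key=lambda l: l.lineage_id)
    return out


def infer_lineages(heavy_records: Sequence[Rearrangement],
                   cells: Mapping[str, PairedCell],
                   threshold: float = 0.20) -> list[Lineage]:
    """Full lineage inference: heavy-chain clustering, light-chain
    refinement, Levenshtein resolution of light-chain-less members."""
    initial = cluster_heavy_lineages(heavy_records, threshold)
    refined, pending = refine_by_light_chain(initial, cells)
    return resolve_divergent(refined, pending)


def assign_isotype(record, c_refs: Mapping[str, str],
                   min_score: float = 0.90) -> str:
    """Assign the antibody class by ungapped prefix alignment of the
    observed constant-region fragment against each class reference.

    `record` may be a Rearrangement or a raw constant-region string.
    Identity below `min_score`, or an empty fragment, yields "unknown".
    """
    if not c_refs:
        raise ValueError("assign_isotype requires a non-empty reference set")
    c_region = record.c_region if isinstance(record, Rearrangement) else record
    if not c_region:
        return "unknown"
    obs = np.frombuffer(c_region.encode("ascii"), dtype=np.uint8)
    best_iso, best_ident = "unknown", -1.0
    for iso in sorted(c_refs):
        ref = c_refs[iso]
        n = min(len(obs), len(ref))
        if n == 0:
            continue
        rr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)[:n]
        ident = float((obs[:n] == rr).mean())
        if ident > best_ident:
            best_iso, best_ident = iso, ident
    return best_iso if best_ident >= min_score else "unknown"


def shm_percent(v_sequence: str, germline_v: str) -> float:
    """Somatic hypermutation of an aligned V segment: percent nucleotide
    mismatch to germline, with N positions excluded from both numerator
    and denominator."""
    if len(v_sequence) != len(germline_v):
        raise ValueError(
            f"shm_percent requires pre-aligned equal-length sequences "
            f"({len(v_sequence)} != {len(germline_v)})"
        )
    obs = np.frombuffer(v_sequence.encode("ascii"), dtype=np.uint8)
    germ = np.frombuffer(germline_v.encode("ascii"), dtype=np.uint8)
    n_code = ord("N")
    mask = (obs != n_code) & (germ != n_code)
    compared = int(mask.sum())
    if compared == 0:
        raise ValueError("shm_percent: zero compared length after N masking")
    return 100.0 * float((obs[mask] != germ[mask]).sum()) / compared
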