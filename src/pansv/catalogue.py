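"""Non-redundant SV cataloguing across accessions and size spectra.

Per-accession calls are merged into a catalogue in which no two records of
the same type still satisfy the merge criterion (idempotence), every input
call maps to exactly one record, and the result is invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import SV_TYPES, StructuralVariant

DEFAULT_BP_TOL = 100
DEFAULT_RECIPROCAL_OVERLAP = 0.8

DEFAULT_SPECTRUM_THRESHOLDS = {
    "PAV": 2_000, "INV": 100_000, "CNV": 4_000, "TRANS": 20_000,
}


@dataclass
class NonRedundantCatalogue:
    records: List[StructuralVariant]
    presence: pd.DataFrame                  # bool, sv_id x accession
    call_to_record: Dict[int, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "sv_id": r.sv_id, "sv_type": r.sv_type, "ref_chrom": r.ref_chrom,
                "ref_start": r.ref_start, "ref_end": r.ref_end,
                "length": r.length,
                "copy_number": r.copy_number if r.copy_number is not None else "",
                "n_accessions": int(self.presence.loc[r.sv_id].sum()),
            })
        return pd.DataFrame(rows).set_index("sv_id")

    def serialize(self) -> bytes:
        """Canonical byte representation (used by stability checks)."""
        frame = self.to_frame()
        presence = self.presence.astype(int)
        return (frame.to_csv(sep="\t") + presence.to_csv(sep="\t")).encode()

    def type_counts(self) -> Dict[str, int]:
        out = {t: 0 for t in SV_TYPES}
        for r in self.records:
            out[r.sv_type] += 1
        return out


def _mergeable(a: StructuralVariant, b: StructuralVariant,
               bp_tol: int, reciprocal_overlap: float) -> bool:
    if a.sv_type != b.sv_type or a.ref_chrom != b.ref_chrom:
        return False
    if abs(a.ref_start - b.ref_start) > bp_tol or abs(a.ref_end - b.ref_end) > bp_tol:
        return False
    if a.sv_type == "PAV_ins":
        # zero-span insertion point: reciprocal criterion applies to lengths
        return min(a.length, b.length) / max(a.length, b.length) >= reciprocal_overlap
    inter = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
    if inter <= 0:
        return False
    return (inter / (a.ref_end - a.ref_start) >= reciprocal_overlap
            and inter / (b.ref_end - b.ref_start) >= reciprocal_overlap)


class _UnionFind:
    def __init__(self, n: int) -> None:
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


def merge_nonredundant(calls: Sequence[StructuralVariant],
                       bp_tol: int = DEFAULT_BP_TOL,
                       reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP,
                       accessions: Optional[Sequence[str]] = None
                       ) -> NonRedundantCatalogue:
    """Merge same-type calls across accessions by transitive closure of the
    breakpoint-distance + reciprocal-overlap criterion.

    Record coordinates are the cluster medoid (the member minimising total
    breakpoint distance to the others, ties broken lexicographically), so
    shuffling the input order leaves the catalogue byte-identical.
    """
    for c in calls:
        if c.sv_type not in SV_TYPES:
            raise ValueError(f"call of unknown type {c.sv_type!r}")
    order = sorted(range(len(calls)),
                   key=lambda i: (calls[i].sv_type, calls[i].ref_chrom,
                                  calls[i].ref_start, calls[i].ref_end,
                                  calls[i].accession))
    uf = _UnionFind(len(calls))
    # same-type, same-chrom calls sorted by start: only neighbours within
    # bp_tol in start can merge, so a sliding window suffices
    by_group: Dict[tuple, List[int]] = {}
    for i in order:
        by_group.setdefault((calls[i].sv_type, calls[i].ref_chrom), []).append(i)
    for idxs in by_group.values():
        for ai, i in enumerate(idxs):
            for j in idxs[ai + 1:]:
                if calls[j].ref_start - calls[i].ref_start > bp_tol:
                    break
                if _mergeable(calls[i], calls[j], bp_tol, reciprocal_overlap):
                    uf.union(i, j)

    clusters: Dict[int, List[int]] = {}
    for i in order:
        clusters.setdefault(uf.find(i), []).append(i)

    if accessions is None:
        accessions = sorted({c.accession for c in calls})
    records: List[StructuralVariant] = []
    members_of: List[List[int]] = []
    for root in clusters:
        members = clusters[root]
        medoid_idx = _medoid(calls, members)
        m = calls[medoid_idx]
        cn = None
        if m.sv_type == "CNV":
            cn = max(calls[i].copy_number or 2 for i in members)
        records.append(StructuralVariant(
            sv_type=m.sv_type, ref_chrom=m.ref_chrom, ref_start=m.ref_start,
            ref_end=m.ref_end, length=m.length, accession="*",
            copy_number=cn, partner_locus=m.partner_locus))
        members_of.append(members)

    # canonical ordering and id assignment
    rank = sorted(range(len(records)),
                  key=lambda i: (records[i].ref_chrom, records[i].ref_start,
                                 records[i].ref_end, records[i].sv_type))
    presence = np.zeros((len(records), len(accessions)), dtype=bool)
    acc_index = {a: k for k, a in enumerate(accessions)}
    call_to_record: Dict[int, str] = {}
    final_records: List[StructuralVariant] = []
    for new_pos, old_pos in enumerate(rank):
        rec = records[old_pos]
        rec.sv_id = f"SV{new_pos + 1:06d}"
        final_records.append(rec)
        for i in members_of[old_pos]:
            if calls[i].accession in acc_index:
                presence[new_pos, acc_index[calls[i].accession]] = True
            call_to_record[i] = rec.sv_id
    presence_df = pd.DataFrame(
        presence, index=[r.sv_id for r in final_records],
        columns=list(accessions))
    return NonRedundantCatalogue(records=final_records, presence=presence_df,
                                 call_to_record=call_to_record)


def _medoid(calls: Sequence[StructuralVariant], members: List[int]) -> int:
    def dist(i: int, j: int) -> int:
        a, b = calls[i], calls[j]
        return (abs(a.ref_start - b.ref_start) + abs(a.ref_end - b.ref_end)
                + abs(a.length - b.length))

    best = None
    for i in members:
        total = sum(dist(i, j) for j in members)
        key = (total, calls[i].ref_start, calls[i].ref_end, calls[i].length,
               calls[i].accession)
        if best is None or key < best[0]:
            best = (key, i)
    return best[1]


def size_spectrum(catalogue: NonRedundantCatalogue,
                  thresholds: Optional[Dict[str, float]] = None
                  ) -> pd.DataFrame:
    """Per-type binned length counts and proportions.

    The default bins split each type at its headline threshold (PAV 2 kb,
    INV 100 kb, CNV 4 kb, TRANS 20 kb): one "below" and one "at or above"
    bin. Types without records report NaN proportions (undefined, not 0/0).
    """
    if not catalogue.records:
        raise ValueError("empty catalogue has no size spectrum")
    thresholds = thresholds or DEFAULT_SPECTRUM_THRESHOLDS
    lengths: Dict[str, List[int]] = {t: [] for t in thresholds}
    for r in catalogue.records:
        key = "PAV" if r.sv_type.startswith("PAV") else r.sv_type
        lengths.setdefault(key, []).append(r.length)
    rows = []
    for sv_type, thr in thresholds.items():
        vals = np.asarray(lengths.get(sv_type, []))
        n = len(vals)
        below = int((vals < thr).sum()) if n else 0
        rows.append({
            "sv_type": sv_type, "threshold_bp": thr, "n": n,
            "n_below": below, "n_at_or_above": n - below,
            "prop_below": below / n if n else np.nan,
            "prop_at_or_above": (n - below) / n if n else np.nan,
        })
    return pd.DataFrame(rows).set_index("sv_type")
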