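"""SV calling from filtered one-to-one whole-genome alignment blocks.

The callers consume :class:`~pansv.core.AlignmentBlock` lists (one query
accession against a common reference) and emit typed
:class:`~pansv.core.StructuralVariant` calls:

* ``call_pav`` — presence/absence variation from gaps between consecutive
  blocks of the collinear chain (reference gap with no query counterpart ->
  absence/deletion; query gap with no reference counterpart -> presence/
  insertion anchored at the junction);
* ``call_inv`` — maximal runs of reverse-strand blocks longer than 1 kb;
* ``call_cnv`` — reference intervals covered by two or more distinct query
  segments (and the symmetric query-side case);
* ``call_trans`` — blocks whose reference chromosome contradicts their query
  chromosome's majority partner, or that are displaced far off the syntenic
  diagonal.

A gap whose sequence aligns elsewhere in the same accession (a duplicated or
relocated segment) is not a PAV; the callers cross-check candidate gaps
against genome-wide coverage so CNV and TRANS events are not double-reported
as insertions/deletions.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Sequence, Tuple

from .core import AlignmentBlock, StructuralVariant

log = logging.getLogger(__name__)

DEFAULT_MIN_BLOCK_LEN = 1000
DEFAULT_MIN_SV_LEN = 50
DEFAULT_GAP_RATIO = 5.0
DEFAULT_MIN_INV_LEN = 1000
DEFAULT_TRANS_DISPLACEMENT = 1_000_000
_GAP_COVERED_MAX = 0.5   # gap fraction aligned elsewhere above which no PAV


def filter_blocks(blocks: Iterable[AlignmentBlock],
                  min_len: int = DEFAULT_MIN_BLOCK_LEN) -> List[AlignmentBlock]:
    """Keep blocks strictly longer than ``min_len`` on the reference and
    normalise ordering to (accession, ref_chrom, ref_start, qry_start).

    The strict inequality follows the documented reading of "blocks longer
    than 1,000 bp": a block of exactly 1,000 bp is removed.
    """
    kept = [b for b in blocks if b.ref_span > min_len]
    kept.sort(key=lambda b: (b.accession, b.ref_chrom, b.ref_start,
                             b.qry_chrom, b.qry_start))
    return kept


def _group(blocks: Iterable[AlignmentBlock], *attrs: str
           ) -> Dict[tuple, List[AlignmentBlock]]:
    out: Dict[tuple, List[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        out[tuple(getattr(b, a) for a in attrs)].append(b)
    return out


def _chain(blocks: List[AlignmentBlock]) -> List[AlignmentBlock]:
    """Collinear chain: maximal increasing run in (ref_start, qry_start).

    Dynamic programme maximising (#blocks, aligned bp) lexicographically —
    the documented tie-break prefers larger blocks.
    """
    bs = sorted(blocks, key=lambda b: (b.ref_start, b.qry_start))
    n = len(bs)
    if n == 0:
        return []
    score = [(1, bs[i].ref_span) for i in range(n)]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if (bs[j].ref_start < bs[i].ref_start
                    and bs[j].qry_start < bs[i].qry_start
                    and bs[j].ref_end <= bs[i].ref_start + 1
                    and bs[j].qry_end <= bs[i].qry_start + 1):
                cand = (score[j][0] + 1, score[j][1] + bs[i].ref_span)
                if cand > score[i]:
                    score[i] = cand
                    prev[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain = []
    while best != -1:
        chain.append(bs[best])
        best = prev[best]
    return chain[::-1]


class _Coverage:
    """bp-level coverage lookup over a set of intervals (sweep-based)."""

    def __init__(self) -> None:
        self._iv: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
        self._merged: Dict[str, List[Tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        self._iv[chrom].append((start, end))
        self._merged.pop(chrom, None)

    def _merge(self, chrom: str) -> List[Tuple[int, int]]:
        if chrom not in self._merged:
            merged: List[Tuple[int, int]] = []
            for s, e in sorted(self._iv.get(chrom, [])):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._merged[chrom] = merged
        return self._merged[chrom]

    def covered_fraction(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        covered = 0
        for s, e in self._merge(chrom):
            if s >= end:
                break
            if e > start:
                covered += min(e, end) - max(s, start)
        return covered / (end - start)


def _coverage_maps(blocks: Sequence[AlignmentBlock]
                   ) -> Tuple[_Coverage, _Coverage]:
    ref_cov, qry_cov = _Coverage(), _Coverage()
    for b in blocks:
        ref_cov.add(b.ref_chrom, b.ref_start, b.ref_end)
        qry_cov.add(b.qry_chrom, b.qry_start, b.qry_end)
    return ref_cov, qry_cov


def call_pav(blocks: Sequence[AlignmentBlock],
             min_sv_len: int = DEFAULT_MIN_SV_LEN,
             gap_ratio: float = DEFAULT_GAP_RATIO) -> List[StructuralVariant]:
    """Call PAVs from junction gaps between consecutive chained blocks.

    For a junction with reference gap ``g_r`` and query gap ``g_q``:
    ``g_r >= min_sv_len`` and ``g_r >= gap_ratio * max(g_q, 1)`` is an
    absence (PAV_del) of length ``g_r``; the symmetric condition is a
    presence (PAV_ins) of length ``g_q`` anchored at the reference junction.
    Mixed gaps below the ratio produce no call and are logged.
    """
    calls: List[StructuralVariant] = []
    for (acc,), acc_blocks in sorted(_group(blocks, "accession").items()):
        ref_cov, qry_cov = _coverage_maps(acc_blocks)
        for (chrom,), chrom_blocks in sorted(
                _group(acc_blocks, "ref_chrom").items()):
            # restrict to the majority query partner chromosome
            partner_bp: Dict[str, int] = defaultdict(int)
            for b in chrom_blocks:
                partner_bp[b.qry_chrom] += b.ref_span
            partner = max(sorted(partner_bp), key=lambda c: partner_bp[c])
            syntenic = [b for b in chrom_blocks if b.qry_chrom == partner]
            chain = _chain(syntenic)
            skipped = len(syntenic) - len(chain)
            if skipped:
                # secondary alignments (CNV copies, relocated segments) are
                # expected off-chain; they feed the CNV/TRANS callers
                log.debug("%s/%s: %d block(s) off the collinear chain skipped",
                          acc, chrom, skipped)
            for a, b in zip(chain, chain[1:]):
                g_r = b.ref_start - a.ref_end
                g_q = b.qry_start - a.qry_end
                if g_r < 0 or g_q < 0:
                    log.warning("%s/%s: contradictory block order at %d, skipped",
                                acc, chrom, a.ref_end)
                    continue
                if g_r >= min_sv_len and g_r >= gap_ratio * max(g_q, 1):
                    if ref_cov.covered_fraction(
                            chrom, a.ref_end, b.ref_start) > _GAP_COVERED_MAX:
                        log.debug("%s/%s: ref gap at %d aligned elsewhere "
                                  "(relocated, not absent)", acc, chrom, a.ref_end)
                        continue
                    calls.append(StructuralVariant(
                        sv_type="PAV_del", ref_chrom=chrom,
                        ref_start=a.ref_end, ref_end=b.ref_start,
                        length=g_r, accession=acc))
                elif g_q >= min_sv_len and g_q >= gap_ratio * max(g_r, 1):
                    if qry_cov.covered_fraction(
                            partner, a.qry_end, b.qry_start) > _GAP_COVERED_MAX:
                        log.debug("%s/%s: qry gap at %d aligned elsewhere "
                                  "(duplicated, not novel)", acc, chrom, a.ref_end)
                        continue
                    calls.append(StructuralVariant(
                        sv_type="PAV_ins", ref_chrom=chrom,
                        ref_start=a.ref_end, ref_end=a.ref_end,
                        length=g_q, accession=acc))
                elif max(g_r, g_q) > 0:
                    log.debug("%s/%s: gap at %d below threshold (g_r=%d, g_q=%d)",
                              acc, chrom, a.ref_end, g_r, g_q)
    return calls


def call_inv(blocks: Sequence[AlignmentBlock],
             min_inv_len: int = DEFAULT_MIN_INV_LEN) -> List[StructuralVariant]:
    """Report maximal runs of reverse-strand blocks as single inversions.

    Only inversions spanning strictly more than ``min_inv_len`` (1 kb) on
    the reference are reported.
    """
    calls: List[StructuralVariant] = []
    for (acc, chrom, qchrom), grp in sorted(
            _group(blocks, "accession", "ref_chrom", "qry_chrom").items()):
        grp = sorted(grp, key=lambda b: (b.ref_start, b.qry_start))
        run: List[AlignmentBlock] = []
        for b in grp + [None]:  # sentinel flushes the final run
            if b is not None and b.strand == "-":
                run.append(b)
                continue
            if run:
                start, end = run[0].ref_start, max(r.ref_end for r in run)
                if end - start > min_inv_len:
                    calls.append(StructuralVariant(
                        sv_type="INV", ref_chrom=chrom, ref_start=start,
                        ref_end=end, length=end - start, accession=acc))
                run = []
    return calls


def call_cnv(blocks: Sequence[AlignmentBlock],
             min_sv_len: int = DEFAULT_MIN_SV_LEN) -> List[StructuralVariant]:
    """Call CNVs where the reference is covered by >= 2 distinct query
    segments of the same accession (copy gain), or symmetrically where one
    query segment covers >= 2 reference loci; the reference anchor is always
    the record locus."""
    calls: List[StructuralVariant] = []
    for (acc, chrom), grp in sorted(_group(blocks, "accession", "ref_chrom").items()):
        for start, end, depth in _multicovered(
                [(b.ref_start, b.ref_end) for b in grp]):
            if end - start >= min_sv_len:
                calls.append(StructuralVariant(
                    sv_type="CNV", ref_chrom=chrom, ref_start=start,
                    ref_end=end, length=end - start, accession=acc,
                    copy_number=depth))
    # query-side duplication (reference-relative copy loss in the query is
    # reported from the query multi-coverage, anchored on the first ref locus)
    for (acc, qchrom), grp in sorted(_group(blocks, "accession", "qry_chrom").items()):
        for qstart, qend, depth in _multicovered(
                [(b.qry_start, b.qry_end) for b in grp]):
            if qend - qstart < min_sv_len:
                continue
            anchors = sorted(
                (b for b in grp if b.qry_start < qend and b.qry_end > qstart),
                key=lambda b: (b.ref_chrom, b.ref_start))
            a = anchors[0]
            off = max(qstart - a.qry_start, 0)
            ref_anchor = (a.ref_start + off,
                          min(a.ref_end, a.ref_start + off + (qend - qstart)))
            already = any(c.ref_chrom == a.ref_chrom
                          and c.ref_start < ref_anchor[1]
                          and c.ref_end > ref_anchor[0]
                          and c.accession == acc for c in calls)
            if not already and ref_anchor[1] - ref_anchor[0] >= min_sv_len:
                calls.append(StructuralVariant(
                    sv_type="CNV", ref_chrom=a.ref_chrom,
                    ref_start=ref_anchor[0], ref_end=ref_anchor[1],
                    length=ref_anchor[1] - ref_anchor[0], accession=acc,
                    copy_number=depth))
    return calls


def _multicovered(intervals: List[Tuple[int, int]]
                  ) -> List[Tuple[int, int, int]]:
    """Maximal intervals with coverage depth >= 2; reported depth = max."""
    events: List[Tuple[int, int]] = []
    for s, e in intervals:
        events.append((s, 1))
        events.append((e, -1))
    events.sort()
    out: List[Tuple[int, int, int]] = []
    depth = 0
    start = None
    maxdepth = 0
    for pos, delta in events:
        new_depth = depth + delta
        if depth < 2 <= new_depth:
            start, maxdepth = pos, new_depth
        elif start is not None and new_depth >= 2:
            maxdepth = max(maxdepth, new_depth)
        elif depth >= 2 > new_depth and start is not None:
            if pos > start:
                out.append((start, pos, maxdepth))
            start = None
        depth = new_depth
    return out


def call_trans(blocks: Sequence[AlignmentBlock],
               displacement: int = DEFAULT_TRANS_DISPLACEMENT,
               merge_gap: int = 1000) -> List[StructuralVariant]:
    """Call translocations against each query chromosome's majority partner.

    A block is translocated if its reference chromosome differs from the
    majority reference partner of its query chromosome, or if it sits on the
    partner chromosome but more than ``displacement`` bp off the syntenic
    diagonal (median ref-minus-qry offset of the partner blocks). Contiguous
    translocated blocks (reference gap <= ``merge_gap``) merge into one
    record whose ``partner_locus`` is the query-side destination.
    """
    calls: List[StructuralVariant] = []
    for (acc, qchrom), grp in sorted(_group(blocks, "accession", "qry_chrom").items()):
        partner_bp: Dict[str, int] = defaultdict(int)
        for b in grp:
            partner_bp[b.ref_chrom] += b.ref_span
        partner = max(sorted(partner_bp), key=lambda c: partner_bp[c])
        offsets = sorted(b.ref_start - b.qry_start
                         for b in grp if b.ref_chrom == partner)
        median_off = offsets[len(offsets) // 2] if offsets else 0
        trans = []
        for b in grp:
            if b.ref_chrom != partner:
                trans.append(b)
            elif abs((b.ref_start - b.qry_start) - median_off) > displacement:
                trans.append(b)
        trans.sort(key=lambda b: (b.ref_chrom, b.ref_start))
        cluster: List[AlignmentBlock] = []
        for b in trans + [None]:
            if (b is not None and cluster
                    and b.ref_chrom == cluster[-1].ref_chrom
                    and b.ref_start - cluster[-1].ref_end <= merge_gap):
                cluster.append(b)
                continue
            if cluster:
                start = cluster[0].ref_start
                end = max(c.ref_end for c in cluster)
                qs = min(c.qry_start for c in cluster)
                qe = max(c.qry_end for c in cluster)
                calls.append(StructuralVariant(
                    sv_type="TRANS", ref_chrom=cluster[0].ref_chrom,
                    ref_start=start, ref_end=end, length=end - start,
                    accession=acc, partner_locus=(qchrom, qs, qe)))
            cluster = [b] if b is not None else []
    return calls


def call_all(blocks: Sequence[AlignmentBlock],
             min_block_len: int = DEFAULT_MIN_BLOCK_LEN,
             min_sv_len: int = DEFAULT_MIN_SV_LEN,
             gap_ratio: float = DEFAULT_GAP_RATIO,
             displacement: int = DEFAULT_TRANS_DISPLACEMENT
             ) -> List[StructuralVariant]:
    """Filter blocks then run every caller; returns the combined call set."""
    kept = filter_blocks(blocks, min_block_len)
    calls = call_pav(kept, min_sv_len, gap_ratio)
    calls += call_inv(kept)
    calls += call_cnv(kept, min_sv_len)
    calls += call_trans(kept, displacement)
    return calls
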