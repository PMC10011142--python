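"""Reference genome simulation and SV implanting with exhaustive truth.

The generator builds a random reference with non-overlapping gene models and
repeat tracks, draws a shared pool of SV events (PAV insertion/deletion,
tandem CNV, inversion, inter-chromosomal translocation), assigns each event
to a subset of accessions, and then derives, for every accession, the query
genome and the exact one-to-one alignment blocks an aligner would report at
zero noise. Every implanted event is recorded in exactly one
:class:`TruthRecord`, which downstream benchmarks treat as ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from ..core import AlignmentBlock, GeneModel
from .config import SimConfig, draw_sv_length

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")

MAX_PLACEMENT_RETRIES = 200


@dataclass
class TruthRecord:
    """One implanted SV event with its accession presence set."""

    sv_id: str
    sv_type: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    length: int
    accessions_present: Set[str]
    copy_number: Optional[int] = None
    dest_chrom: Optional[str] = None     # TRANS: destination chromosome
    dest_pos: Optional[int] = None       # TRANS: reference-frame insertion point
    linked_gene: Optional[str] = None
    expression_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.sv_type != "PAV_ins" and self.ref_start >= self.ref_end:
            raise ValueError(f"{self.sv_id}: ref_start must be < ref_end")
        if self.length <= 0:
            raise ValueError(f"{self.sv_id}: non-positive length")


@dataclass
class Reference:
    sequences: Dict[str, str]
    genes: List[GeneModel]
    repeats: List[Tuple[str, int, int]]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class SyntheticAccession:
    accession: str
    blocks: List[AlignmentBlock]
    sequences: Optional[Dict[str, str]] = None


@dataclass
class SyntheticPanGenome:
    reference: Reference
    truth: List[TruthRecord]
    accessions: Dict[str, SyntheticAccession] = field(default_factory=dict)

    def truth_for(self, accession: str) -> List[TruthRecord]:
        return [t for t in self.truth if accession in t.accessions_present]

    def all_blocks(self) -> List[AlignmentBlock]:
        out: List[AlignmentBlock] = []
        for acc in sorted(self.accessions):
            out.extend(self.accessions[acc].blocks)
        return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_reference(config: SimConfig) -> Reference:
    """Simulate the reference genome, gene models and repeat track.

    Genes are packed without overlap by partitioning each chromosome's slack
    uniformly between them; packing that cannot fit raises ``ValueError``.
    """
    rng = config.rng("reference")
    chroms = config.chroms
    sequences = {c: _random_seq(rng, config.ref_length) for c in chroms}

    genes: List[GeneModel] = []
    per_chrom = _split_counts(config.n_genes, len(chroms))
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        lo, hi = config.gene_length_range
        lengths = rng.integers(lo, hi + 1, size=n_here)
        min_gap = 200
        footprint = int(lengths.sum()) + min_gap * (n_here + 1)
        if footprint > config.ref_length:
            raise ValueError(
                f"cannot pack {n_here} genes of mean length ~{(lo + hi) // 2} bp "
                f"into a {config.ref_length} bp chromosome"
            )
        slack = config.ref_length - footprint
        # uniform random partition of the slack into n+1 gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=n_here)) if n_here else []
        pos = min_gap
        prev_cut = 0
        for i in range(n_here):
            pos += int(cuts[i] - prev_cut)
            prev_cut = int(cuts[i])
            start, end = pos, pos + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _draw_exons(rng, start, end, config.max_exons)
            cds_start = exons[0][0] if strand == "+" else exons[-1][1] - 3
            gid += 1
            genes.append(GeneModel(
                gene_id=f"gene{gid:04d}", chrom=chrom, start=start, end=end,
                strand=strand, exons=exons, cds_start=cds_start,
            ))
            pos = end + min_gap

    repeats = _draw_repeats(rng, chroms, config.ref_length, config.repeat_fraction)
    return Reference(sequences=sequences, genes=genes, repeats=repeats)


def _split_counts(total: int, n_bins: int) -> List[int]:
    base, rem = divmod(total, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


def _draw_exons(rng, start, end, max_exons) -> List[Tuple[int, int]]:
    n_exons = int(rng.integers(1, max_exons + 1))
    length = end - start
    if n_exons == 1 or length < 300 * n_exons:
        return [(start, end)]
    # alternate exon/intron segments of roughly equal size with jitter
    bounds = np.sort(rng.choice(
        np.arange(start + 50, end - 50), size=2 * n_exons - 2, replace=False))
    points = [start, *(int(b) for b in bounds), end]
    return [(points[i], points[i + 1]) for i in range(0, len(points) - 1, 2)]


def _draw_repeats(rng, chroms, chrom_length, fraction) -> List[Tuple[str, int, int]]:
    repeats = []
    for chrom in chroms:
        covered = 0
        target = fraction * chrom_length
        intervals = []
        guard = 0
        while covered < target and guard < 100_000:
            guard += 1
            length = int(rng.integers(500, 5001))
            start = int(rng.integers(0, chrom_length - length))
            intervals.append((start, start + length))
            covered += length
        intervals.sort()
        merged = []
        for s, e in intervals:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        repeats.extend((chrom, s, e) for s, e in merged)
    return repeats


# ------------------------------------------------------------------ SV pool


def _place_events(config: SimConfig, rng: np.random.Generator
                  ) -> List[TruthRecord]:
    """Draw the shared pool of non-overlapping events on the reference."""
    chroms = config.chroms
    sep = config.min_event_separation
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}

    def reserve(chrom: str, start: int, end: int) -> bool:
        for s, e in occupied[chrom]:
            if start - sep < e and s < end + sep:
                return False
        occupied[chrom].append((start, end))
        return True

    events: List[TruthRecord] = []
    idx = 0
    for sv_type in ("PAV_del", "PAV_ins", "CNV", "INV", "TRANS"):
        count = int(config.sv_rates.get(sv_type, 0))
        lo, hi, shape = config.sv_length_distributions[sv_type]
        for _ in range(count):
            placed = False
            for _attempt in range(MAX_PLACEMENT_RETRIES):
                length = draw_sv_length(rng, lo, hi, shape)
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                limit = config.ref_length - length - sep
                if limit <= sep:
                    continue
                start = int(rng.integers(sep, limit))
                span = (start, start if sv_type == "PAV_ins" else start + length)
                if not reserve(chrom, span[0], max(span[1], span[0] + 1)):
                    continue
                dest_chrom = dest_pos = None
                if sv_type == "TRANS":
                    if len(chroms) < 2:
                        raise ValueError("TRANS events require >= 2 chromosomes")
                    others = [c for c in chroms if c != chrom]
                    dest_chrom = others[int(rng.integers(0, len(others)))]
                    ok = False
                    for _a2 in range(MAX_PLACEMENT_RETRIES):
                        dest_pos = int(rng.integers(sep, config.ref_length - sep))
                        if reserve(dest_chrom, dest_pos, dest_pos + 1):
                            ok = True
                            break
                    if not ok:
                        raise RuntimeError("could not place TRANS destination")
                idx += 1
                events.append(TruthRecord(
                    sv_id=f"truth{idx:04d}", sv_type=sv_type, ref_chrom=chrom,
                    ref_start=span[0], ref_end=span[1], length=length,
                    accessions_present=set(),
                    copy_number=2 if sv_type == "CNV" else None,
                    dest_chrom=dest_chrom, dest_pos=dest_pos,
                ))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a {sv_type} event after "
                    f"{MAX_PLACEMENT_RETRIES} retries; reduce sv_rates or "
                    f"lengths, or enlarge ref_length"
                )
    events.sort(key=lambda t: (t.ref_chrom, t.ref_start, t.sv_id))
    return events


def _assign_accessions(events: Sequence[TruthRecord], config: SimConfig,
                       rng: np.random.Generator) -> None:
    for ev in events:
        carriers = {a for a in config.accessions
                    if rng.random() < config.sv_share_prob}
        if not carriers:
            carriers = {config.accessions[int(rng.integers(config.n_accessions))]}
        ev.accessions_present = carriers


def _link_genes(events: Sequence[TruthRecord], reference: Reference,
                config: SimConfig, flank: int = 5000) -> None:
    """Attach the nearest gene within ``flank`` and a cis expression effect."""
    effect = float(config.expression["cis_sv_log2fc"])
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in reference.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for ev in events:
        best, best_d = None, flank + 1
        for g in by_chrom.get(ev.ref_chrom, []):
            d = max(g.start - ev.ref_end, ev.ref_start - g.end, 0)
            if d < best_d:
                best, best_d = g, d
        if best is not None:
            ev.linked_gene = best.gene_id
            ev.expression_effect = effect


# -------------------------------------------------------------- implanting


def implant_svs(reference: Reference, config: SimConfig,
                build_sequences: bool = False,
                noise: float = 0.0) -> SyntheticPanGenome:
    """Implant the SV pool into every accession and emit truth + blocks.

    Alignment blocks are emitted directly from the event bookkeeping (the
    exact one-to-one synteny segments an aligner would recover at zero
    noise); ``noise`` > 0 trims block boundaries by half-normal amounts to
    emulate imprecise breakpoints. Every flanking block is guaranteed longer
    than 1 kb so none is lost to the caller's block-length filter.
    """
    rng = config.rng("implant")
    events = _place_events(config, rng)
    _assign_accessions(events, config, rng)
    _link_genes(events, reference, config)

    pan = SyntheticPanGenome(reference=reference, truth=events)
    for acc in config.accessions:
        acc_events = [e for e in events if acc in e.accessions_present]
        blocks, seqs = _derive_accession(reference, acc, acc_events, rng,
                                         build_sequences)
        if noise > 0:
            blocks = _jitter_blocks(blocks, rng, noise)
        pan.accessions[acc] = SyntheticAccession(
            accession=acc, blocks=blocks,
            sequences=seqs if build_sequences else None)
    return pan


def _derive_accession(reference: Reference, accession: str,
                      events: Sequence[TruthRecord], rng: np.random.Generator,
                      build_sequences: bool
                      ) -> Tuple[List[AlignmentBlock], Dict[str, str]]:
    chroms = list(reference.sequences)
    # schedule per chromosome: local events plus incoming TRANS insertions
    sched: Dict[str, List[Tuple[int, str, TruthRecord]]] = {c: [] for c in chroms}
    for ev in events:
        if ev.sv_type == "TRANS":
            sched[ev.ref_chrom].append((ev.ref_start, "trans_src", ev))
            sched[ev.dest_chrom].append((ev.dest_pos, "trans_dst", ev))
        else:
            sched[ev.ref_chrom].append((ev.ref_start, ev.sv_type, ev))
    blocks: List[AlignmentBlock] = []
    seqs: Dict[str, str] = {}

    for chrom in chroms:
        ref_seq = reference.sequences[chrom]
        ref_len = len(ref_seq)
        parts: List[str] = []
        ref_cur = qry_cur = 0

        def emit_syntenic(upto: int) -> None:
            nonlocal ref_cur, qry_cur
            if upto > ref_cur:
                span = upto - ref_cur
                blocks.append(AlignmentBlock(
                    ref_chrom=chrom, ref_start=ref_cur, ref_end=upto,
                    qry_chrom=chrom, qry_start=qry_cur, qry_end=qry_cur + span,
                    strand="+", accession=accession))
                if build_sequences:
                    parts.append(ref_seq[ref_cur:upto])
                ref_cur, qry_cur = upto, qry_cur + span

        for pos, kind, ev in sorted(sched[chrom], key=lambda t: t[0]):
            emit_syntenic(pos)
            if kind == "PAV_del":
                ref_cur = ev.ref_end
            elif kind == "PAV_ins":
                if build_sequences:
                    parts.append(_random_seq(rng, ev.length))
                qry_cur += ev.length
            elif kind == "CNV":
                span = ev.ref_end - ev.ref_start
                for _copy in range(ev.copy_number):
                    blocks.append(AlignmentBlock(
                        ref_chrom=chrom, ref_start=ev.ref_start,
                        ref_end=ev.ref_end, qry_chrom=chrom,
                        qry_start=qry_cur, qry_end=qry_cur + span,
                        strand="+", accession=accession))
                    if build_sequences:
                        parts.append(ref_seq[ev.ref_start:ev.ref_end])
                    qry_cur += span
                ref_cur = ev.ref_end
            elif kind == "INV":
                span = ev.ref_end - ev.ref_start
                blocks.append(AlignmentBlock(
                    ref_chrom=chrom, ref_start=ev.ref_start, ref_end=ev.ref_end,
                    qry_chrom=chrom, qry_start=qry_cur, qry_end=qry_cur + span,
                    strand="-", accession=accession))
                if build_sequences:
                    parts.append(
                        ref_seq[ev.ref_start:ev.ref_end][::-1].translate(_COMP))
                ref_cur, qry_cur = ev.ref_end, qry_cur + span
            elif kind == "trans_src":
                ref_cur = ev.ref_end  # sequence reappears on the destination
            elif kind == "trans_dst":
                blocks.append(AlignmentBlock(
                    ref_chrom=ev.ref_chrom, ref_start=ev.ref_start,
                    ref_end=ev.ref_end, qry_chrom=chrom,
                    qry_start=qry_cur, qry_end=qry_cur + ev.length,
                    strand="+", accession=accession))
                if build_sequences:
                    src = reference.sequences[ev.ref_chrom]
                    parts.append(src[ev.ref_start:ev.ref_end])
                qry_cur += ev.length
        emit_syntenic(ref_len)
        if build_sequences:
            seqs[chrom] = "".join(parts)
    return blocks, seqs


def _jitter_blocks(blocks: List[AlignmentBlock], rng: np.random.Generator,
                   noise: float) -> List[AlignmentBlock]:
    out = []
    for b in blocks:
        trim_l = int(abs(rng.normal(0, noise)))
        trim_r = int(abs(rng.normal(0, noise)))
        max_trim = min(b.ref_span, b.qry_span) - 1
        trim_l = min(trim_l, max_trim // 2)
        trim_r = min(trim_r, max_trim - trim_l - 1) if max_trim > trim_l else 0
        out.append(AlignmentBlock(
            ref_chrom=b.ref_chrom, ref_start=b.ref_start + trim_l,
            ref_end=b.ref_end - trim_r, qry_chrom=b.qry_chrom,
            qry_start=b.qry_start + trim_l, qry_end=b.qry_end - trim_r,
            strand=b.strand, accession=b.accession, identity=b.identity))
    return out
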