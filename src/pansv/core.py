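"""Shared domain types for pan-genome SV analysis.

Coordinates are 0-based half-open everywhere inside the package; 1-based
inclusive coordinates appear only at GFF3/VCF boundaries (see ``pansv.io``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SV_TYPES = ("PAV_ins", "PAV_del", "CNV", "INV", "TRANS")


@dataclass(frozen=True)
class AlignmentBlock:
    """One filtered one-to-one whole-genome alignment segment.

    ``ref_*`` anchors the block on the common reference; ``qry_*`` on the
    accession (query) genome. ``strand`` is '+' for collinear alignment and
    '-' for a reverse-complement match.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    strand: str
    accession: str
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start < 1 or self.qry_end - self.qry_start < 1:
            raise ValueError(
                f"malformed alignment block with non-positive span: {self}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_span(self) -> int:
        return self.qry_end - self.qry_start


@dataclass
class StructuralVariant:
    """A typed SV call anchored on the reference genome.

    Types follow the pan-genome vocabulary: PAV_ins (sequence present in the
    query, absent from the reference), PAV_del (absent from the query), CNV
    (copy-number gain), INV (inversion > 1 kb) and TRANS (translocation).
    For PAV_ins the reference interval is the zero-length insertion point
    widened to one bp for indexing; ``length`` carries the inserted span.
    """

    sv_type: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    length: int
    accession: str
    sv_id: Optional[str] = None
    copy_number: Optional[int] = None        # CNV only
    partner_locus: Optional[tuple] = None    # TRANS only: (chrom, start, end)

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.length <= 0:
            raise ValueError("SV length must be positive")

    def key(self) -> tuple:
        return (self.sv_type, self.ref_chrom, self.ref_start, self.ref_end)


@dataclass
class GeneModel:
    """A gene with exon structure, as read from / written to GFF3."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list = field(default_factory=list)  # [(start, end), ...] 0-based half-open
    cds_start: Optional[int] = None            # 0-based position of the CDS start codon

    def __post_init__(self) -> None:
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")
        self.exons = sorted(tuple(e) for e in self.exons)

    @property
    def introns(self) -> list:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    @property
    def tss(self) -> int:
        """Transcription start: leftmost bp on '+', rightmost on '-'."""
        return self.start if self.strand != "-" else self.end
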