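"""Readers and writers for the package's on-disk interfaces.

FASTA goes through Biopython, GFF3 reading through gffutils when available,
VCF through pysam. PAF is a plain 12+-column TSV and is mapped directly onto
:class:`~pansv.core.AlignmentBlock`. All in-memory coordinates are 0-based
half-open; GFF3 and VCF are converted to/from their 1-based conventions at
this boundary only.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AlignmentBlock, GeneModel, StructuralVariant

# ---------------------------------------------------------------- FASTA


def write_fasta(path: str, sequences: Dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------- GFF3


def write_gff3(path: str, genes: Sequence[GeneModel], source: str = "pansv") -> None:
    """Write gene/exon/CDS features; converts to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            if g.cds_start is not None:
                # minimal CDS record marking the start codon position
                cs = g.cds_start
                ce = min(cs + 3, g.end) if g.strand != "-" else cs + 3
                fh.write(
                    f"{g.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds;Parent={g.gene_id}\n"
                )


def read_gff3(path: str) -> List[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [(f.start - 1, f.end) for f in db.children(g, featuretype="exon")]
        cds = sorted(db.children(g, featuretype="CDS"), key=lambda f: f.start)
        cds_start = None
        if cds:
            cds_start = (cds[0].start - 1) if g.strand != "-" else (cds[-1].end - 1)
        genes.append(
            GeneModel(
                gene_id=g.id, chrom=g.seqid, start=g.start - 1, end=g.end,
                strand=g.strand if g.strand in "+-" else ".",
                exons=exons or [(g.start - 1, g.end)], cds_start=cds_start,
            )
        )
    return genes


# ---------------------------------------------------------------- BED


def write_bed(path: str, intervals: Iterable[tuple]) -> None:
    """Intervals are (chrom, start, end[, name]); already 0-based half-open."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


# ---------------------------------------------------------------- PAF

PAF_COLUMNS = [
    "qry_chrom", "qry_len", "qry_start", "qry_end", "strand",
    "ref_chrom", "ref_len", "ref_start", "ref_end",
    "n_match", "block_len", "mapq",
]


def write_paf(path: str, blocks: Sequence[AlignmentBlock],
              chrom_lengths: Dict[str, int] | None = None,
              qry_lengths: Dict[str, int] | None = None) -> None:
    chrom_lengths = chrom_lengths or {}
    qry_lengths = qry_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            span = min(b.ref_span, b.qry_span)
            n_match = int(round(span * b.identity))
            row = [
                b.qry_chrom, qry_lengths.get(b.qry_chrom, b.qry_end),
                b.qry_start, b.qry_end, b.strand,
                b.ref_chrom, chrom_lengths.get(b.ref_chrom, b.ref_end),
                b.ref_start, b.ref_end, n_match, max(b.ref_span, b.qry_span), 60,
                f"ac:Z:{b.accession}",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_paf(path: str, accession: str | None = None) -> List[AlignmentBlock]:
    """Parse PAF rows into alignment blocks.

    The accession is taken from an ``ac:Z:`` tag when present, otherwise from
    the ``accession`` argument.
    """
    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"PAF row with {len(parts)} < 12 columns")
            tag_acc = accession
            for tag in parts[12:]:
                if tag.startswith("ac:Z:"):
                    tag_acc = tag[5:]
            denom = min(int(parts[8]) - int(parts[7]), int(parts[3]) - int(parts[2]))
            blocks.append(
                AlignmentBlock(
                    qry_chrom=parts[0], qry_start=int(parts[2]), qry_end=int(parts[3]),
                    strand=parts[4],
                    ref_chrom=parts[5], ref_start=int(parts[7]), ref_end=int(parts[8]),
                    accession=tag_acc or "query",
                    identity=min(1.0, int(parts[9]) / max(denom, 1)),
                )
            )
    return blocks


# ---------------------------------------------------------------- MUMmer show-coords TSV

COORDS_COLUMN_MAP = {
    "ref_start": 0, "ref_end": 1, "qry_start": 2, "qry_end": 3,
    "ref_chrom": 7, "qry_chrom": 8,
}


def read_coords_tsv(path: str, accession: str,
                    column_map: Dict[str, int] | None = None) -> List[AlignmentBlock]:
    """Read a MUMmer ``show-coords -T`` style TSV (1-based inclusive, query
    reversed on '-' alignments) with a documented column map."""
    cmap = column_map or COORDS_COLUMN_MAP
    blocks = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(cmap.values()) or not parts[cmap["ref_start"]].isdigit():
                continue
            rs, re_ = int(parts[cmap["ref_start"]]), int(parts[cmap["ref_end"]])
            qs, qe = int(parts[cmap["qry_start"]]), int(parts[cmap["qry_end"]])
            strand = "+" if qe >= qs else "-"
            if strand == "-":
                qs, qe = qe, qs
            blocks.append(
                AlignmentBlock(
                    ref_chrom=parts[cmap["ref_chrom"]], ref_start=rs - 1, ref_end=re_,
                    qry_chrom=parts[cmap["qry_chrom"]], qry_start=qs - 1, qry_end=qe,
                    strand=strand, accession=accession,
                )
            )
    return blocks


# ---------------------------------------------------------------- VCF

_SVTYPE_ALT = {"PAV_del": "DEL", "PAV_ins": "INS", "INV": "INV", "CNV": "DUP"}


def write_vcf(path: str, records: Sequence[StructuralVariant],
              contig_lengths: Dict[str, int],
              presence: pd.DataFrame | None = None) -> None:
    """Write a VCF 4.3 with symbolic ALT alleles.

    PAV/INV/CNV become <DEL>/<INS>/<INV>/<DUP> records with SVTYPE, SVLEN,
    END (and CN for CNV); translocations are written as a breakend pair.
    If ``presence`` (SV x accession boolean frame) is given, accessions
    become samples with presence genotypes 1/1 vs 0/0.
    """
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant")
    # END is reserved in pysam and derived from each record's stop position
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("CN", 1, "Integer", "Copy number (CNV records)")
    header.info.add("MATEID", 1, "String", "ID of mate breakend")
    header.formats.add("GT", 1, "String", "Presence genotype")
    samples = list(presence.columns) if presence is not None else []
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(path, "w", header=header) as vcf:
        for i, sv in enumerate(records):
            rid = sv.sv_id or f"sv{i}"
            if sv.sv_type == "TRANS":
                pchrom, pstart, pend = sv.partner_locus
                for j, (c, p, mate_c, mate_p) in enumerate(
                    [(sv.ref_chrom, sv.ref_start, pchrom, pstart),
                     (pchrom, pstart, sv.ref_chrom, sv.ref_start)]
                ):
                    rec = vcf.new_record(
                        contig=c, start=p, stop=p + 1, alleles=("N", f"N[{mate_c}:{mate_p + 1}["),
                        id=f"{rid}_bnd{j}",
                    )
                    rec.info["SVTYPE"] = "BND"
                    rec.info["MATEID"] = f"{rid}_bnd{1 - j}"
                    _fill_gt(rec, samples, presence, rid)
                    vcf.write(rec)
                continue
            alt = _SVTYPE_ALT[sv.sv_type]
            rec = vcf.new_record(
                contig=sv.ref_chrom, start=sv.ref_start,
                stop=max(sv.ref_end, sv.ref_start + 1),
                alleles=("N", f"<{alt}>"), id=rid,
            )
            rec.info["SVTYPE"] = alt
            rec.info["SVLEN"] = -sv.length if alt == "DEL" else sv.length
            if sv.copy_number is not None:
                rec.info["CN"] = int(sv.copy_number)
            _fill_gt(rec, samples, presence, rid)
            vcf.write(rec)


def _fill_gt(rec, samples, presence, rid) -> None:
    if presence is None:
        return
    row = presence.loc[rid] if rid in presence.index else None
    for s in samples:
        present = bool(row[s]) if row is not None else False
        rec.samples[s]["GT"] = (1, 1) if present else (0, 0)


# ---------------------------------------------------------------- tables


def write_tsv(path: str, df: pd.DataFrame, index: bool = True) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
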