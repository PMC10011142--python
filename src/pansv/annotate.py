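"""SV-to-feature annotation.

Relates SVs to genomic context: the eleven SV-gene categories (deletion of
the CDS start / whole gene / exons / flanks, insertions into exons, introns
or flanks, duplications, and the any-SV "PresenceSVs" superset), repeat vs
non-repeat overlap summaries, and a one-tailed binomial test for gene-family
enrichment over intact-LTR intervals.

Overlap is half-open throughout: an SV abutting a feature does not overlap
it; one shared bp does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneModel, StructuralVariant

log = logging.getLogger(__name__)

DEFAULT_FLANK = 5_000

DELETION_PRIORITY = ("DELgene", "DELCDSstart", "DELexons", "DELup", "DELdown")
CATEGORIES = (
    "DELCDSstart", "DELdown", "DELexons", "DELgene", "DELup", "Dup",
    "INSdown", "INSexons", "INSintrons", "INSup", "PresenceSVs",
)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _flanks(gene: GeneModel, flank: int) -> Dict[str, Tuple[int, int]]:
    """Strand-aware 5 kb flanks: upstream is 5' of the gene."""
    strand = gene.strand
    if strand == ".":
        log.warning("gene %s is unstranded; treating as '+'", gene.gene_id)
        strand = "+"
    left = (gene.start - flank, gene.start)
    right = (gene.end, gene.end + flank)
    return {"up": left, "down": right} if strand == "+" else \
           {"up": right, "down": left}


def classify_sv_gene_context(svs: Sequence[StructuralVariant],
                             genes: Sequence[GeneModel],
                             flank: int = DEFAULT_FLANK,
                             multi_label: bool = False) -> pd.DataFrame:
    """Assign every (SV, gene) pair to its SV-gene category.

    Deletions follow the documented priority (whole gene > CDS start > exons
    > upstream > downstream flank) so that each pair receives one specific
    category; ``multi_label=True`` disables the priority and emits every
    matching deletion category for sensitivity checks. Insertions are
    classified by their insertion point; CNVs become ``Dup``. Every gene with
    at least one SV within its body or flanks additionally receives a
    ``PresenceSVs`` row.

    Returns a frame with columns sv_id, accession, gene_id, category.
    """
    trees: Dict[str, IntervalTree] = {}
    for gi, g in enumerate(genes):
        reach = max(flank, 0)
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - reach, g.end + reach, gi)

    rows: List[dict] = []
    for sv in svs:
        tree = trees.get(sv.ref_chrom)
        if tree is None:
            continue
        s, e = sv.ref_start, sv.ref_end
        if sv.sv_type == "PAV_ins":
            e = s + 1  # insertion point
        for hit in sorted(tree.overlap(s, e), key=lambda h: h.data):
            g = genes[hit.data]
            cats = _categories_for(sv, g, flank)
            in_reach = _overlaps(s, e, g.start - flank, g.end + flank)
            if not multi_label and len(cats) > 1:
                cats = cats[:1]
            for cat in cats:
                rows.append({"sv_id": sv.sv_id, "accession": sv.accession,
                             "gene_id": g.gene_id, "category": cat})
            if in_reach:
                rows.append({"sv_id": sv.sv_id, "accession": sv.accession,
                             "gene_id": g.gene_id, "category": "PresenceSVs"})
    df = pd.DataFrame(rows, columns=["sv_id", "accession", "gene_id", "category"])
    return df.drop_duplicates().sort_values(
        ["gene_id", "sv_id", "category"]).reset_index(drop=True)


def _categories_for(sv: StructuralVariant, gene: GeneModel,
                    flank: int) -> List[str]:
    flanks = _flanks(gene, flank)
    s, e = sv.ref_start, sv.ref_end
    if sv.sv_type == "CNV":
        if _overlaps(s, e, gene.start - flank, gene.end + flank):
            return ["Dup"]
        return []
    if sv.sv_type == "PAV_del":
        cats = []
        if s <= gene.start and e >= gene.end:
            cats.append("DELgene")
        if gene.cds_start is not None and s <= gene.cds_start < e:
            cats.append("DELCDSstart")
        elif gene.cds_start is None and _overlaps(s, e, gene.start, gene.end):
            log.warning("gene %s has no CDS start; DELCDSstart undefined",
                        gene.gene_id)
        if any(_overlaps(s, e, es, ee) for es, ee in gene.exons):
            cats.append("DELexons")
        if _overlaps(s, e, *flanks["up"]):
            cats.append("DELup")
        if _overlaps(s, e, *flanks["down"]):
            cats.append("DELdown")
        return sorted(cats, key=DELETION_PRIORITY.index)
    if sv.sv_type == "PAV_ins":
        p = s  # insertion point on the reference
        if any(es <= p < ee for es, ee in gene.exons):
            return ["INSexons"]
        if any(is_ <= p < ie for is_, ie in gene.introns):
            return ["INSintrons"]
        if flanks["up"][0] <= p < flanks["up"][1]:
            return ["INSup"]
        if flanks["down"][0] <= p < flanks["down"][1]:
            return ["INSdown"]
        return []
    return []  # INV/TRANS contribute to PresenceSVs only


# ------------------------------------------------------------- overlaps


@dataclass
class FeatureOverlapSummary:
    per_accession: pd.DataFrame  # columns: in_regions, outside_regions, total

    @property
    def totals(self) -> pd.Series:
        return self.per_accession.sum(axis=0)


def overlap_regions(svs: Sequence[StructuralVariant],
                    regions: pd.DataFrame,
                    chrom_lengths: Optional[Dict[str, int]] = None
                    ) -> FeatureOverlapSummary:
    """Count SVs overlapping a BED-style region set (>= 1 bp intersection),
    per accession. Regions need chrom/start/end columns, half-open."""
    trees: Dict[str, IntervalTree] = {}
    for _, row in regions.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]))
    counts: Dict[str, Dict[str, int]] = {}
    for sv in svs:
        if chrom_lengths is not None:
            limit = chrom_lengths.get(sv.ref_chrom)
            if limit is None or sv.ref_start < 0 or sv.ref_end > limit:
                raise ValueError(
                    f"SV {sv.sv_id or sv.key()} outside chromosome bounds")
        s, e = sv.ref_start, sv.ref_end
        if sv.sv_type == "PAV_ins":
            e = s + 1
        hit = bool(trees.get(sv.ref_chrom, IntervalTree()).overlap(s, e))
        acc = counts.setdefault(sv.accession, {"in_regions": 0,
                                               "outside_regions": 0})
        acc["in_regions" if hit else "outside_regions"] += 1
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(columns=["in_regions", "outside_regions"])
    df["total"] = df.sum(axis=1)
    return FeatureOverlapSummary(per_accession=df.sort_index())


# -------------------------------------------------- LTR binomial test


def family_ltr_overlap_test(family_gene_ids: Iterable[str],
                            genes: Sequence[GeneModel],
                            ltr_intervals: pd.DataFrame) -> dict:
    """One-tailed binomial test for a gene family's enrichment over intact
    LTR retrotransposons.

    The background proportion p0 is the fraction of all genes whose body
    overlaps an intact LTR interval; the returned p-value is
    P(X >= k | X ~ Binomial(n, p0)) for the k of n family genes overlapping.
    """
    family: Set[str] = set(family_gene_ids)
    n = sum(1 for g in genes if g.gene_id in family)
    if n == 0:
        raise ValueError("family has no genes in the annotation")
    trees: Dict[str, IntervalTree] = {}
    for _, row in ltr_intervals.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]))
    overlapping = {
        g.gene_id for g in genes
        if trees.get(g.chrom) and trees[g.chrom].overlap(g.start, g.end)
    }
    p0 = len(overlapping) / len(genes)
    k = len(overlapping & family)
    if p0 == 0:
        pvalue = 0.0 if k > 0 else 1.0
        fold = float("inf") if k > 0 else float("nan")
    else:
        pvalue = stats.binomtest(k, n, p0, alternative="greater").pvalue
        fold = (k / n) / p0
    return {"k": k, "n": n, "p0": p0, "fold": fold, "pvalue": pvalue}
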