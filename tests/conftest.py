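import numpy as np
import pandas as pd
import pytest

from pansv.core import AlignmentBlock, GeneModel, StructuralVariant
from pansv.expression import ExpressionMatrix
from pansv.sim import SimConfig, implant_svs, make_reference


def make_block(ref_start, ref_end, qry_start, qry_end, strand="+",
               ref_chrom="chr1", qry_chrom="chr1", accession="accA"):
    return AlignmentBlock(ref_chrom=ref_chrom, ref_start=ref_start,
                          ref_end=ref_end, qry_chrom=qry_chrom,
                          qry_start=qry_start, qry_end=qry_end,
                          strand=strand, accession=accession)


def make_sv(sv_type, start, end, length=None, accession="accA",
            chrom="chr1", **kw):
    return StructuralVariant(sv_type=sv_type, ref_chrom=chrom, ref_start=start,
                             ref_end=end, length=length or (end - start),
                             accession=accession, **kw)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def reference(sim_config):
    return make_reference(sim_config)


@pytest.fixture(scope="session")
def pangenome(sim_config, reference):
    return implant_svs(reference, sim_config)


@pytest.fixture
def simple_gene():
    # 10 kb '+' strand gene with two exons and a CDS start at the first exon
    return GeneModel(gene_id="g1", chrom="chr1", start=20_000, end=30_000,
                     strand="+", exons=[(20_000, 24_000), (26_000, 30_000)],
                     cds_start=20_100)


def expression_from_arrays(counts, accessions=None, condition=None,
                           gene_length=1000.0):
    """Wrap a genes x samples array as an ExpressionMatrix with flat
    metadata; used by tests that do not need the full simulator."""
    from pansv.expression import tpm_normalize

    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    n = counts.shape[1]
    meta = pd.DataFrame({
        "accession": accessions if accessions is not None else ["a"] * n,
        "tissue": "leaf",
        "condition": condition if condition is not None else ["control"] * n,
        "time": "1h",
        "replicate": range(n),
    }, index=counts.columns)
    lengths = pd.Series(gene_length, index=counts.index)
    return ExpressionMatrix(counts=counts, tpm=tpm_normalize(counts, lengths),
                            samples=meta, gene_lengths=lengths)
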