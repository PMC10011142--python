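"""Expression side: DEG calling, SV-proximity enrichment and the
heat-resistant-group fixed-SV screen.

Six accessions (the first four treated as heat-resistant, the last two as
heat-susceptible) get control/heat expression with three replicates. Genes
linked to an implanted SV receive a cis effect in carrier accessions only,
so the screen should surface SV-gene pairs whose expression tracks SV
presence — provided the SV is fixed in >= 3 HR accessions and absent from
both HS accessions.
"""

from pansv import catalogue, expression as ex, svcall
from pansv.sim import (
    ExpressionDesign, SimConfig, implant_svs, make_reference,
    simulate_expression,
)

cfg = SimConfig(seed=5)
reference = make_reference(cfg)
pan = implant_svs(reference, cfg)
accessions = cfg.accessions[:6]
hr, hs = accessions[:4], accessions[4:]

design = ExpressionDesign(accessions=accessions)
matrix, etruth = simulate_expression(reference.genes, pan.truth, design, cfg)
print(f"expression matrix: {matrix.counts.shape[0]} genes x "
      f"{matrix.counts.shape[1]} samples; "
      f"{len(etruth.heat_responsive)} genes truly heat-responsive")

heat = matrix.sample_names(accession=accessions[0], condition="heat")
ctrl = matrix.sample_names(accession=accessions[0], condition="control")
degs = ex.call_degs(matrix, heat, ctrl)
print(f"heat vs control in {accessions[0]}: {int(degs['is_deg'].sum())} DEGs "
      f"(|log2FC| >= 1, BH-adjusted p < 0.05)")

calls = [c for c in svcall.call_all(pan.all_blocks())
         if c.accession in accessions]
cat = catalogue.merge_nonredundant(calls, accessions=accessions)
responsive = ex.heat_responsive_genes(matrix)
screen = ex.screen_hr_fixed_svs(cat.presence, cat.records, hr, hs,
                                reference.genes, matrix,
                                heat_responsive=responsive)
print("\nscreen stage counts:", screen.stage_counts)
if len(screen.candidates):
    print(screen.candidates[["sv_id", "gene_id", "distance",
                             "wilcoxon_p", "q", "heat_responsive"]]
          .to_string(index=False))
# each candidate row is an SV fixed in the HR group whose neighbouring
# gene's expression differs between carrier and non-carrier accessions
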