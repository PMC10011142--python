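"""Negative-binomial expression simulation with cis-SV and heat effects."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ..core import GeneModel
from ..expression import ExpressionMatrix, tpm_normalize
from .config import SimConfig
from .genome import TruthRecord


@dataclass
class ExpressionDesign:
    """Accessions x conditions x replicates (default three biological
    replicates, control and heat)."""

    accessions: Sequence[str]
    conditions: Tuple[str, ...] = ("control", "heat")
    n_replicates: int = 3
    tissue: str = "leaf"
    time: str = "1h"

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least two replicates per condition")

    def samples(self) -> pd.DataFrame:
        rows = []
        for acc in self.accessions:
            for cond in self.conditions:
                for rep in range(1, self.n_replicates + 1):
                    rows.append({
                        "sample": f"{acc}_{self.tissue}_{cond}_{self.time}_r{rep}",
                        "accession": acc, "tissue": self.tissue,
                        "condition": cond, "time": self.time, "replicate": rep,
                    })
        return pd.DataFrame(rows).set_index("sample")


@dataclass
class ExpressionTruth:
    heat_responsive: Set[str] = field(default_factory=set)
    heat_log2fc: Dict[str, float] = field(default_factory=dict)
    cis_effects: Dict[str, Tuple[str, float, Set[str]]] = field(
        default_factory=dict)  # gene -> (sv_id, log2fc, carrier accessions)


def simulate_expression(genes: Sequence[GeneModel],
                        truth: Sequence[TruthRecord],
                        design: ExpressionDesign,
                        config: Optional[SimConfig] = None,
                        rng: Optional[np.random.Generator] = None
                        ) -> Tuple[ExpressionMatrix, ExpressionTruth]:
    """Simulate a counts + TPM matrix for the design.

    Baseline per-gene means are log-normal around ``mean_tpm``; counts are
    negative-binomial (gamma-Poisson) with dispersion ``nb_dispersion``.
    A configured fraction of genes responds to heat with +-``heat_log2fc``;
    genes linked to a truth SV receive ``expression_effect`` only in samples
    of carrier accessions (cis effect, both conditions).
    """
    config = config or SimConfig()
    rng = rng if rng is not None else config.rng("expression")
    params = config.expression
    samples = design.samples()
    gene_ids = [g.gene_id for g in genes]
    lengths = pd.Series({g.gene_id: g.end - g.start for g in genes})

    base = rng.lognormal(mean=np.log(params["mean_tpm"]), sigma=1.0,
                         size=len(gene_ids))
    etruth = ExpressionTruth()
    n_heat = int(round(params["heat_fraction"] * len(gene_ids)))
    heat_idx = rng.choice(len(gene_ids), size=n_heat, replace=False)
    for i in heat_idx:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        etruth.heat_responsive.add(gene_ids[i])
        etruth.heat_log2fc[gene_ids[i]] = sign * params["heat_log2fc"]
    for t in truth:
        if t.linked_gene is not None and t.expression_effect != 0.0:
            etruth.cis_effects[t.linked_gene] = (
                t.sv_id, t.expression_effect, set(t.accessions_present))

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    phi = params["nb_dispersion"]
    lib = params["library_size"]
    counts = np.empty((len(gene_ids), len(samples)), dtype=np.int64)
    base_weight = base * lengths.to_numpy() / 1000.0  # expected reads scale

    for col, (sample, meta) in enumerate(samples.iterrows()):
        lfc = np.zeros(len(gene_ids))
        if meta["condition"] == "heat":
            for g, effect in etruth.heat_log2fc.items():
                lfc[gene_pos[g]] += effect
        for g, (_sv, effect, carriers) in etruth.cis_effects.items():
            if meta["accession"] in carriers:
                lfc[gene_pos[g]] += effect
        mu = base_weight * 2.0 ** lfc
        mu = mu / mu.sum() * lib
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        else:
            lam = mu
        counts[:, col] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples.index)
    tpm = tpm_normalize(counts_df, lengths)
    return ExpressionMatrix(counts=counts_df, tpm=tpm, samples=samples,
                            gene_lengths=lengths), etruth
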