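"""Structured population simulation for fdSV scans and PAV-GWAS.

Emulates a diploid-equivalent population genotyped for presence/absence SVs:
two climate groups (tropical / temperate) with background drift between
them, a configured subset of strongly group-differentiated SVs (optionally
clustered in one locus, as a selective sweep would leave), a latitude
gradient aligned with the climate groups, kinship structure from the shared
drift, one causal SV with a configurable trait-variance share, a polygenic
background consistent with the kinship, and injected missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Set

import numpy as np
import pandas as pd

from ..popgen import SVGenotypeMatrix
from .config import SimConfig


@dataclass
class PopulationTruth:
    differentiated: Set[str] = field(default_factory=set)
    cluster_region: Optional[tuple] = None     # (chrom, start, end)
    causal_sv: Optional[str] = None
    causal_effect: float = 0.0


def simulate_population(config: Optional[SimConfig] = None,
                        rng: Optional[np.random.Generator] = None,
                        **overrides):
    """Simulate genotypes + phenotypes; returns (SVGenotypeMatrix,
    PhenotypeTable frame, PopulationTruth).

    ``overrides`` update the config's population block (e.g.
    ``group_delta_f=0``, ``causal_h2=0`` for null simulations).
    """
    config = config or SimConfig()
    params = dict(config.population)
    params.update(overrides)
    rng = rng if rng is not None else config.rng("population")

    delta = float(params["group_delta_f"])
    if not 0.0 <= delta <= 1.0:
        raise ValueError("group_delta_f must lie in [0, 1]")
    n_ind = int(params["n_individuals"])
    n_svs = int(params["n_svs"])
    n_diff = int(params["n_differentiated"])
    chrom_len = int(params["chrom_length"])
    fst = float(params["fst"])
    miss = float(params["missing_rate"])

    individuals = [f"ind{i + 1:04d}" for i in range(n_ind)]
    half = n_ind // 2
    climate = np.array(["tropical"] * half + ["temperate"] * (n_ind - half))
    domestication = rng.choice(["wild", "landrace", "improved"], size=n_ind,
                               p=[0.2, 0.5, 0.3])

    sv_ids = [f"psv{i + 1:05d}" for i in range(n_svs)]
    base_f = rng.uniform(0.1, 0.9, size=n_svs)
    # background drift between groups (Balding-Nichols style)
    f_groups = {}
    for gname in ("tropical", "temperate"):
        if fst > 0:
            a = base_f * (1 - fst) / fst
            b = (1 - base_f) * (1 - fst) / fst
            f_groups[gname] = rng.beta(a, b)
        else:
            f_groups[gname] = base_f.copy()

    # positions; differentiated subset optionally clustered in one window
    pos = np.sort(rng.integers(0, chrom_len, size=n_svs))
    truth = PopulationTruth()
    diff_idx = np.array([], dtype=int)
    if n_diff > 0 and delta > 0:
        if params.get("cluster_differentiated", True):
            center = int(rng.integers(chrom_len // 4, 3 * chrom_len // 4))
            lo, hi = center - 50_000, center + 50_000
            cluster_pos = np.sort(rng.integers(lo, hi, size=n_diff))
            replace = rng.choice(n_svs, size=n_diff, replace=False)
            pos[replace] = cluster_pos
            order = np.argsort(pos, kind="stable")
            inverse = np.empty_like(order)
            inverse[order] = np.arange(n_svs)
            pos = pos[order]
            for name in f_groups:
                f_groups[name] = f_groups[name][order]
            diff_idx = np.sort(inverse[replace])
            truth.cluster_region = ("chr1", int(lo), int(hi))
        else:
            diff_idx = np.sort(rng.choice(n_svs, size=n_diff, replace=False))
        f_groups["tropical"][diff_idx] = 0.5 + delta / 2.0
        f_groups["temperate"][diff_idx] = 0.5 - delta / 2.0
        truth.differentiated = {sv_ids[i] for i in diff_idx}

    geno = np.empty((n_svs, n_ind), dtype=float)
    for gname in ("tropical", "temperate"):
        cols = np.where(climate == gname)[0]
        f = f_groups[gname]
        geno[:, cols] = rng.binomial(2, f[:, None], size=(n_svs, len(cols)))

    # trait: causal SV + polygenic background on the genotype structure
    causal_h2 = float(params.get("causal_h2", 0.0))
    poly_h2 = float(params.get("polygenic_h2", 0.0))
    y = np.zeros(n_ind)
    if poly_h2 > 0:
        Z = (geno - geno.mean(axis=1, keepdims=True))
        sd = geno.std(axis=1)
        keep = sd > 0
        Z = Z[keep] / sd[keep, None]
        u = Z.T @ rng.normal(0.0, np.sqrt(poly_h2 / keep.sum()), size=keep.sum())
        y += u
    if causal_h2 > 0:
        candidates = [i for i in range(n_svs) if i not in set(diff_idx)
                      and 0.3 <= geno[i].mean() / 2 <= 0.7]
        ci = int(rng.choice(candidates))
        truth.causal_sv = sv_ids[ci]
        dose = geno[ci]
        beta = np.sqrt(causal_h2 / max(dose.var(), 1e-12))
        truth.causal_effect = float(beta)
        y += beta * dose
    noise_var = max(1.0 - causal_h2 - poly_h2, 0.05)
    y += rng.normal(0.0, np.sqrt(noise_var), size=n_ind)

    latitude = np.where(
        climate == "tropical", rng.normal(10.0, 5.0, n_ind),
        rng.normal(35.0, 5.0, n_ind))
    if params.get("latitude_gradient", True) and len(diff_idx) > 0:
        # carriers of the differentiated SVs sit lower-latitude on average
        latitude = latitude - 2.0 * (geno[diff_idx[0]] - 1.0)

    if miss > 0:
        mask = rng.random(geno.shape) < miss
        geno[mask] = np.nan

    gm = SVGenotypeMatrix(
        genotypes=pd.DataFrame(geno, index=sv_ids, columns=individuals),
        positions=pd.DataFrame({"chrom": "chr1", "pos": pos}, index=sv_ids))
    phen = pd.DataFrame({
        "trait": y, "latitude": latitude, "climate_group": climate,
        "domestication_group": domestication,
    }, index=individuals)
    return gm, phen, truth
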