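"""Expression-side association analyses.

Differential expression calls (|log2FC| >= 1, BH-adjusted p < 0.05), SV
proximity enrichment near expression-altered genes, DEG shares among
SV-adjacent vs SV-free genes, transcription-factor / target correlation
screening, and the heat-resistant-group fixed-SV candidate pipeline.

The differential test is a negative-binomial Wald test with
method-of-moments dispersion and a t reference (n1 + n2 - 2 df), a compact
in-package replacement for an external DE tool: the downstream contracts
(thresholding, BH correction, category enrichment) only require calibrated
p-values and the exact fold-change rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, StructuralVariant

log = logging.getLogger(__name__)

DEG_LOG2FC_MIN = 1.0
DEG_PADJ_MAX = 0.05
DEFAULT_RHO_MIN = 0.6
DEFAULT_P_MAX = 0.05
DEFAULT_FLANK = 5_000


@dataclass
class ExpressionMatrix:
    """Gene x sample abundances with per-sample metadata.

    ``counts`` are raw counts, ``tpm`` the length-normalised abundances;
    ``samples`` has one row per column of the matrices with accession /
    tissue / condition / time / replicate fields.
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample metadata does not match matrix columns")

    def sample_names(self, **criteria) -> List[str]:
        mask = pd.Series(True, index=self.samples.index)
        for key, value in criteria.items():
            if value is None:
                continue
            col = self.samples[key]
            mask &= col.isin(value) if isinstance(value, (list, set, tuple)) \
                else (col == value)
        return list(self.samples.index[mask])


def tpm_normalize(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Counts -> transcripts per million: count / gene length, scaled to 1e6
    per sample."""
    rate = counts.div(gene_lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------------ DEGs


def call_degs(matrix: ExpressionMatrix, group1: Sequence[str],
              group2: Sequence[str], log2fc_min: float = DEG_LOG2FC_MIN,
              padj_max: float = DEG_PADJ_MAX) -> pd.DataFrame:
    """Call DEGs between two sample groups.

    log2FC is computed on mean library-size-normalised counts with a
    pseudocount of 1; a gene is a DEG iff |log2FC| >= 1 and BH-adjusted
    p < 0.05. All-zero genes are excluded (and logged), not reported.
    """
    g1, g2 = list(group1), list(group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need at least two replicates")
    counts = matrix.counts[g1 + g2]
    lib = counts.sum(axis=0)
    norm = counts.div(lib / lib.mean(), axis=1)
    nonzero = norm.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        log.info("call_degs: %d all-zero genes excluded", n_dropped)
    norm = norm.loc[nonzero]

    x1, x2 = norm[g1].to_numpy(), norm[g2].to_numpy()
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = np.log2(m1 + 1.0) - np.log2(m2 + 1.0)

    # method-of-moments NB dispersion pooled across the two groups
    n1, n2 = x1.shape[1], x2.shape[1]
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    pooled_mean = (n1 * m1 + n2 * m2) / (n1 + n2)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.clip((pooled_var - pooled_mean) / pooled_mean**2, 0.0, None)
    phi = np.nan_to_num(phi)

    def nb_var_of_mean(m, n):
        return (m + phi * m**2) / n

    # delta method on log2(mean + 1)
    se = np.sqrt(nb_var_of_mean(m1, n1) / (m1 + 1.0) ** 2
                 + nb_var_of_mean(m2, n2) / (m2 + 1.0) ** 2) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n1 + n2 - 2)
    padj = bh_adjust(pvals)
    out = pd.DataFrame({
        "log2fc": log2fc, "p": pvals, "padj": padj,
        "is_deg": (np.abs(log2fc) >= log2fc_min) & (padj < padj_max),
    }, index=norm.index)
    out.index.name = "gene_id"
    return out


# ------------------------------------------- SV proximity enrichment


def sv_proximity_enrichment(assignments: pd.DataFrame,
                            altered: Dict[str, Set[str]],
                            universe: Set[str],
                            n_shuffles: int = 1000, seed: int = 0
                            ) -> pd.DataFrame:
    """Fold enrichment of each SV-gene category in expression-altered genes.

    For every accession and category, the observed share of category genes
    in that accession's altered set is compared with shares from random
    gene-label permutations (draws of equal-sized gene sets from the
    universe). p is the one-sided permutation p-value; q the BH adjustment
    across all category x accession cells.
    """
    rng = np.random.default_rng(seed)
    uni = sorted(universe)
    rows = []
    for (acc, cat), grp in assignments.groupby(["accession", "category"]):
        genes = sorted(set(grp["gene_id"]) & set(uni))
        if not genes:
            log.info("enrichment: category %s/%s has no genes, skipped",
                     acc, cat)
            continue
        alt = altered.get(acc, set())
        observed = np.mean([g in alt for g in genes])
        k = len(genes)
        shuffled = np.empty(n_shuffles)
        alt_arr = np.array([g in alt for g in uni])
        for s in range(n_shuffles):
            pick = rng.choice(len(uni), size=k, replace=False)
            shuffled[s] = alt_arr[pick].mean()
        baseline = shuffled.mean()
        fold = observed / baseline if baseline > 0 else np.nan
        pperm = (1.0 + np.sum(shuffled >= observed)) / (1.0 + n_shuffles)
        rows.append({"accession": acc, "category": cat, "n_genes": k,
                     "observed_share": observed, "expected_share": baseline,
                     "fold": fold, "p": pperm})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def deg_proportion_by_sv(degs: pd.DataFrame, sv_genes: Set[str],
                         nsv_genes: Set[str]) -> dict:
    """DEG share among SV-adjacent genes vs SV-free genes."""
    overlap = sv_genes & nsv_genes
    if overlap:
        raise ValueError(f"SV and nSV sets overlap: {sorted(overlap)[:5]}")

    def share(gene_set: Set[str]):
        tested = degs.index.intersection(sorted(gene_set))
        if len(tested) == 0:
            return None, 0, 0
        n_deg = int(degs.loc[tested, "is_deg"].sum())
        return n_deg / len(tested), n_deg, len(tested)

    sv_share, sv_deg, sv_n = share(sv_genes)
    nsv_share, nsv_deg, nsv_n = share(nsv_genes)
    diff = None if sv_share is None or nsv_share is None else sv_share - nsv_share
    return {"sv_share": sv_share, "sv_deg": sv_deg, "sv_n": sv_n,
            "nsv_share": nsv_share, "nsv_deg": nsv_deg, "nsv_n": nsv_n,
            "difference": diff}


# ------------------------------------------------ TF-target correlation


def correlate_tf_targets(tf_expr: pd.DataFrame, target_expr: pd.DataFrame,
                         rho_min: float = DEFAULT_RHO_MIN,
                         p_max: float = DEFAULT_P_MAX) -> dict:
    """Pearson correlation screen between TF and target expression vectors.

    Vectors are paired across matched samples (columns). A (TF, target)
    pair passes iff rho >= rho_min and the two-sided p < p_max. Constant
    vectors are excluded with a log message. Returns the per-pair table and
    the per-target-set pass share in percent (one decimal).
    """
    common = tf_expr.columns.intersection(target_expr.columns)
    if len(common) < 4:
        raise ValueError("need at least 4 paired samples")
    rows = []
    for tf, tf_vec in tf_expr[common].iterrows():
        if np.isclose(tf_vec.std(), 0):
            log.info("TF %s has constant expression; excluded", tf)
            continue
        for tgt, tgt_vec in target_expr[common].iterrows():
            if np.isclose(tgt_vec.std(), 0):
                continue
            rho, p = stats.pearsonr(tf_vec, tgt_vec)
            rows.append({"tf": tf, "target": tgt, "rho": rho, "p": p,
                         "passes": bool(rho >= rho_min and p < p_max)})
    pairs = pd.DataFrame(rows)
    passing_targets = set(pairs.loc[pairs["passes"], "target"]) if not pairs.empty else set()
    n_targets = pairs["target"].nunique() if not pairs.empty else 0
    share = pass_share(len(passing_targets), n_targets) if n_targets else None
    return {"pairs": pairs, "n_targets": n_targets,
            "n_passing_targets": len(passing_targets), "share_pct": share}


def pass_share(n_passing: int, n_total: int) -> float:
    """Share of passing genes as a percentage with one decimal (e.g. 325 of
    540 -> 60.2)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_passing / n_total, 1)


# ------------------------------------------- HR fixed-SV screen


@dataclass
class ScreenResult:
    candidates: pd.DataFrame
    stage_counts: Dict[str, int] = field(default_factory=dict)


def screen_hr_fixed_svs(presence: pd.DataFrame,
                        records: Sequence[StructuralVariant],
                        hr_accessions: Sequence[str],
                        hs_accessions: Sequence[str],
                        genes: Sequence[GeneModel],
                        matrix: ExpressionMatrix,
                        flank: int = DEFAULT_FLANK,
                        q_max: float = 0.05,
                        min_hr_presence: int = 3,
                        condition: Optional[str] = "control",
                        heat_responsive: Optional[Set[str]] = None,
                        pathway_sets: Optional[Dict[str, Set[str]]] = None
                        ) -> ScreenResult:
    """Screen for SVs fixed in the heat-resistant (HR) group whose nearby
    genes shift expression with SV presence.

    Pipeline stages, each with a logged count:

    1. keep catalogue SVs present in >= ``min_hr_presence`` HR accessions
       and in no HS accession;
    2. attach genes overlapping the SV or within ``flank`` bp;
    3. per (SV, gene), a two-tailed Wilcoxon rank-sum test (exact for < 8
       observations per side, normal approximation with tie correction
       otherwise) compares the gene's expression between samples of
       SV-carrying and non-carrying accessions (per-replicate TPM of the
       chosen ``condition``; ``condition=None`` pools all samples);
    4. BH across all tested pairs; keep q < ``q_max``;
    5. flag heat-responsive genes and annotate pathway membership shares.
    """
    hr, hs = list(hr_accessions), list(hs_accessions)
    stage: Dict[str, int] = {"input_svs": len(records)}
    by_id = {r.sv_id: r for r in records}

    fixed = []
    for sv_id in presence.index:
        row = presence.loc[sv_id]
        hr_count = int(row[hr].sum())
        hs_count = int(row[hs].sum())
        if hr_count >= min_hr_presence and hs_count == 0:
            fixed.append((sv_id, hr_count))
    stage["hr_fixed_svs"] = len(fixed)
    log.info("screen stage 1: %d SV(s) fixed in >= %d HR accessions",
             len(fixed), min_hr_presence)

    pairs: List[dict] = []
    gene_by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)
    for sv_id, hr_count in fixed:
        sv = by_id[sv_id]
        s, e = sv.ref_start, max(sv.ref_end, sv.ref_start + 1)
        for g in gene_by_chrom.get(sv.ref_chrom, []):
            dist = max(g.start - e, s - g.end, 0)
            if dist <= flank:
                pairs.append({"sv_id": sv_id, "gene_id": g.gene_id,
                              "distance": dist, "hr_presence_count": hr_count})
    stage["sv_gene_pairs"] = len(pairs)
    log.info("screen stage 2: %d (SV, gene) pair(s) within %d bp",
             len(pairs), flank)

    tested: List[dict] = []
    all_acc = sorted(set(matrix.samples["accession"]))
    for pair in pairs:
        row = presence.loc[pair["sv_id"]]
        carriers = [a for a in all_acc if a in row.index and row[a]]
        noncarriers = [a for a in all_acc if a not in carriers]
        if len(carriers) < 2 or len(noncarriers) < 2:
            log.info("screen: pair (%s, %s) untestable "
                     "(%d vs %d accessions)", pair["sv_id"], pair["gene_id"],
                     len(carriers), len(noncarriers))
            continue
        x = _gene_values(matrix, pair["gene_id"], carriers, condition)
        y = _gene_values(matrix, pair["gene_id"], noncarriers, condition)
        if x is None or y is None:
            continue
        method = "exact" if (len(x) < 8 and len(y) < 8
                             and len(np.unique(np.concatenate([x, y])))
                             == len(x) + len(y)) else "asymptotic"
        p = stats.mannwhitneyu(x, y, alternative="two-sided",
                               method=method).pvalue
        tested.append({**pair, "hs_presence_count": 0, "wilcoxon_p": float(p)})
    stage["tested_pairs"] = len(tested)
    log.info("screen stage 3: %d pair(s) tested", len(tested))

    df = pd.DataFrame(tested)
    if not df.empty:
        df["q"] = bh_adjust(df["wilcoxon_p"].to_numpy())
        df = df[df["q"] < q_max].reset_index(drop=True)
    stage["significant_pairs"] = len(df)
    log.info("screen stage 4: %d pair(s) at q < %g", len(df), q_max)

    if not df.empty:
        hr_set = heat_responsive or set()
        df["heat_responsive"] = df["gene_id"].isin(sorted(hr_set))
        if pathway_sets:
            for name, members in pathway_sets.items():
                df[f"in_{name}"] = df["gene_id"].isin(sorted(members))
    stage["candidate_genes"] = df["gene_id"].nunique() if not df.empty else 0
    log.info("screen stage 5: %d candidate gene(s)", stage["candidate_genes"])
    return ScreenResult(candidates=df, stage_counts=stage)


def _gene_values(matrix: ExpressionMatrix, gene_id: str,
                 accessions: List[str], condition: Optional[str]
                 ) -> Optional[np.ndarray]:
    if gene_id not in matrix.tpm.index:
        return None
    cols = matrix.sample_names(accession=accessions, condition=condition)
    if len(cols) < 2:
        return None
    return matrix.tpm.loc[gene_id, cols].to_numpy(dtype=float)


def heat_responsive_genes(matrix: ExpressionMatrix,
                          log2fc_min: float = DEG_LOG2FC_MIN,
                          padj_max: float = DEG_PADJ_MAX) -> Set[str]:
    """Genes DEG for heat vs control in at least one accession x tissue x
    time stratum with >= 2 replicates per side."""
    out: Set[str] = set()
    meta = matrix.samples
    strata_cols = [c for c in ("accession", "tissue", "time") if c in meta.columns]
    for _, stratum in meta.groupby(strata_cols):
        heat = stratum.index[stratum["condition"] == "heat"]
        ctrl = stratum.index[stratum["condition"] == "control"]
        if len(heat) < 2 or len(ctrl) < 2:
            continue
        degs = call_degs(matrix, list(heat), list(ctrl), log2fc_min, padj_max)
        out |= set(degs.index[degs["is_deg"]])
    return out
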