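"""Population-scale SV analyses.

Genotype filtering (MAF/missingness), the frequency-differentiation (fdSV)
sliding-window sweep scan with top-1% selection, pathway chi-squared
enrichment, a mixed-linear-model PAV-GWAS with simple-matching kinship
(EMMA-style spectral REML on the null model, then per-marker generalised
least squares), and diversity statistics (windowed nucleotide diversity,
Shannon index, windowed density correlations).

Genotypes are presence dosages in {0, 1, 2} with NaN for missing; allele
frequency at an SV is mean(dosage)/2 over non-missing individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

DEFAULT_MAF_MIN = 0.05
DEFAULT_MISS_MAX = 0.1
DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 10_000
DEFAULT_DELTA_F_MIN = 0.5
DEFAULT_TOP_PERCENT = 1.0
DEFAULT_N_PCS = 3
DEFAULT_GWAS_THRESHOLD = 5.0


@dataclass
class SVGenotypeMatrix:
    """SV x individual presence dosages with reference positions."""

    genotypes: pd.DataFrame            # float with NaN = missing
    positions: pd.DataFrame            # sv_id -> chrom, pos

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.positions.index):
            raise ValueError("genotype and position indices differ")

    @property
    def individuals(self) -> List[str]:
        return list(self.genotypes.columns)

    def allele_freq(self) -> pd.Series:
        return self.genotypes.mean(axis=1, skipna=True) / 2.0

    def minor_allele_freq(self) -> pd.Series:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> pd.Series:
        return self.genotypes.isna().mean(axis=1)

    def subset(self, sv_ids: Sequence[str]) -> "SVGenotypeMatrix":
        ids = list(sv_ids)
        return SVGenotypeMatrix(self.genotypes.loc[ids],
                                self.positions.loc[ids])


def filter_genotypes(gm: SVGenotypeMatrix,
                     maf_min: float = DEFAULT_MAF_MIN,
                     miss_max: float = DEFAULT_MISS_MAX
                     ) -> Tuple[SVGenotypeMatrix, Dict[str, int]]:
    """Remove SVs with minor allele frequency < ``maf_min`` or missing rate
    > ``miss_max`` (strict inequalities: the boundary values are retained).
    Monomorphic SVs fail the MAF rule and are counted separately."""
    maf = gm.minor_allele_freq()
    miss = gm.missing_rate()
    mono = maf == 0
    keep = (maf >= maf_min) & (miss <= miss_max)
    removed = {
        "low_maf": int(((maf < maf_min) & ~mono).sum()),
        "monomorphic": int(mono.sum()),
        "high_missing": int(((miss > miss_max) & (maf >= maf_min)).sum()),
        "kept": int(keep.sum()),
    }
    return gm.subset(list(gm.genotypes.index[keep])), removed


# ------------------------------------------------------------- fdSV scan


@dataclass
class FdsvScanResult:
    windows: pd.DataFrame       # chrom,start,end,statistic,n_svs,percentile,is_sweep
    fdsv: pd.DataFrame          # per-SV delta_f with fdSV flag
    sweep_regions: List[Tuple[str, int, int]]


def fdsv_scan(gm: SVGenotypeMatrix, groups: pd.Series,
              window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP,
              delta_f_min: float = DEFAULT_DELTA_F_MIN,
              top_percent: float = DEFAULT_TOP_PERCENT) -> FdsvScanResult:
    """Sliding-window scan for group-differentiated SVs.

    Per SV, delta_f = |f_groupA - f_groupB| with missing genotypes excluded
    per group; an SV is an fdSV iff delta_f >= ``delta_f_min``. The window
    statistic is the mean delta_f of the SVs inside; windows without SVs are
    excluded from ranking. Sweep regions are the top ``top_percent`` % of
    ranked windows, merged when they overlap or abut. Swapping the two group
    labels leaves every statistic unchanged.
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a_ind = groups.index[groups == labels[0]]
    b_ind = groups.index[groups == labels[1]]
    if len(a_ind) == 0 or len(b_ind) == 0:
        raise ValueError("both groups must be non-empty")
    fa = gm.genotypes[list(a_ind)].mean(axis=1, skipna=True) / 2.0
    fb = gm.genotypes[list(b_ind)].mean(axis=1, skipna=True) / 2.0
    delta = (fa - fb).abs()
    fdsv = pd.DataFrame({
        "chrom": gm.positions["chrom"], "pos": gm.positions["pos"],
        f"freq_{labels[0]}": fa, f"freq_{labels[1]}": fb, "delta_f": delta,
        "is_fdsv": delta >= delta_f_min,
    })

    rows = []
    for chrom, chrom_svs in fdsv.groupby("chrom"):
        pos = chrom_svs["pos"].to_numpy()
        dvals = chrom_svs["delta_f"].to_numpy()
        span = int(pos.max()) + 1
        for start in range(0, max(span - window + step, 1), step):
            end = start + window
            inside = (pos >= start) & (pos < end)
            if not inside.any():
                continue
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "statistic": float(dvals[inside].mean()),
                         "n_svs": int(inside.sum())})
    windows = pd.DataFrame(rows)
    if windows.empty:
        return FdsvScanResult(windows=windows, fdsv=fdsv, sweep_regions=[])
    windows["percentile"] = windows["statistic"].rank(pct=True) * 100.0
    n_top = max(1, int(np.ceil(len(windows) * top_percent / 100.0)))
    cutoff = windows["statistic"].nlargest(n_top).min()
    windows["is_sweep"] = windows["statistic"] >= cutoff
    windows = windows.sort_values(["chrom", "start"]).reset_index(drop=True)

    regions: List[Tuple[str, int, int]] = []
    for _, w in windows[windows["is_sweep"]].iterrows():
        if regions and regions[-1][0] == w["chrom"] \
                and w["start"] <= regions[-1][2]:
            regions[-1] = (w["chrom"], regions[-1][1],
                           max(regions[-1][2], int(w["end"])))
        else:
            regions.append((w["chrom"], int(w["start"]), int(w["end"])))
    return FdsvScanResult(windows=windows, fdsv=fdsv, sweep_regions=regions)


def genes_in_regions(genes, regions: Sequence[Tuple[str, int, int]]) -> Set[str]:
    out: Set[str] = set()
    for g in genes:
        for chrom, start, end in regions:
            if g.chrom == chrom and g.start < end and start < g.end:
                out.add(g.gene_id)
                break
    return out


# -------------------------------------------------- pathway enrichment


def pathway_enrichment(sweep_genes: Set[str],
                       pathway_sets: Dict[str, Set[str]],
                       universe: Set[str]) -> pd.DataFrame:
    """Pearson chi-squared test (continuity correction off) of each pathway's
    representation among sweep genes vs the background universe; switches to
    Fisher's exact test (logged) when an expected cell drops below 1."""
    if not sweep_genes <= universe:
        raise ValueError("sweep genes must be contained in the universe")
    rows = []
    for name, members in pathway_sets.items():
        members = members & universe
        if not members:
            raise ValueError(f"pathway {name!r} has no genes in the universe")
        in_s_in_p = len(sweep_genes & members)
        in_s_out_p = len(sweep_genes) - in_s_in_p
        out_sweep = universe - sweep_genes
        out_s_in_p = len(out_sweep & members)
        out_s_out_p = len(out_sweep) - out_s_in_p
        table = np.array([[in_s_in_p, in_s_out_p], [out_s_in_p, out_s_out_p]])
        expected = stats.contingency.expected_freq(table)
        if (expected < 1).any():
            log.info("pathway %s: expected cell < 1, using Fisher exact", name)
            _, p = stats.fisher_exact(table)
            chi2 = np.nan
            method = "fisher"
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            method = "chi2"
        rows.append({"pathway": name, "sweep_in_pathway": in_s_in_p,
                     "sweep_total": len(sweep_genes), "chi2": chi2, "p": p,
                     "method": method})
    return pd.DataFrame(rows).set_index("pathway")


# ------------------------------------------------- kinship, PCs, GWAS


def build_kinship_and_pcs(gm: SVGenotypeMatrix, n_pcs: int = DEFAULT_N_PCS,
                          max_missing_individual: float = 0.5
                          ) -> Tuple[pd.DataFrame, pd.DataFrame, List[str]]:
    """Simple-matching kinship K and top principal components S.

    K_ij is the share of markers at which individuals i and j carry the
    identical genotype call, over pairwise-complete markers. PCs come from
    the SV-wise mean-imputed, centred genotype matrix. Individuals missing
    more than half their calls are excluded (logged)."""
    geno = gm.genotypes
    ind_missing = geno.isna().mean(axis=0)
    excluded = list(geno.columns[ind_missing > max_missing_individual])
    if excluded:
        log.warning("kinship: excluding %d individual(s) with > %.0f%% "
                    "missing calls", len(excluded), 100 * max_missing_individual)
        geno = geno.drop(columns=excluded)
    X = geno.to_numpy(dtype=float).T          # individuals x markers
    valid = ~np.isnan(X)
    matches = np.zeros((X.shape[0], X.shape[0]))
    for value in (0.0, 1.0, 2.0):
        ind = (X == value).astype(float)
        matches += ind @ ind.T
    denom = valid.astype(float) @ valid.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(denom > 0, matches / denom, 0.0)
    K_df = pd.DataFrame(K, index=geno.columns, columns=geno.columns)

    col_means = np.nanmean(X, axis=0)
    X_imp = np.where(np.isnan(X), col_means[None, :], X)
    X_centered = X_imp - X_imp.mean(axis=0, keepdims=True)
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X_centered)
    S_df = pd.DataFrame(pcs, index=geno.columns,
                        columns=[f"PC{i + 1}" for i in range(n_pcs)])
    return K_df, S_df, excluded


def _reml_null(y: np.ndarray, C: np.ndarray, K: np.ndarray) -> dict:
    """Spectral REML for y = C b + g + e, g ~ N(0, sg2 K), e ~ N(0, se2 I).

    Profiles out the overall scale and maximises over the heritability ratio
    h = sg2 / (sg2 + se2) on a bounded scalar search."""
    n, q = C.shape
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    ystar = U.T @ y
    Cstar = U.T @ C

    def neg_restricted_ll(h: float) -> float:
        d = h * w + (1.0 - h)
        d = np.clip(d, 1e-10, None)
        Wd = 1.0 / d
        A = Cstar.T @ (Cstar * Wd[:, None])
        b = np.linalg.solve(A, Cstar.T @ (ystar * Wd))
        r = ystar - Cstar @ b
        rss = float(np.sum(r * r * Wd))
        sign, logdet_A = np.linalg.slogdet(A)
        return 0.5 * ((n - q) * np.log(rss) + np.sum(np.log(d)) + logdet_A)

    from scipy.optimize import minimize_scalar
    grid = np.linspace(0.0, 0.999, 21)
    h0 = grid[int(np.argmin([neg_restricted_ll(h) for h in grid]))]
    lo, hi = max(h0 - 0.05, 0.0), min(h0 + 0.05, 0.999)
    res = minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded")
    h = float(res.x)
    d = np.clip(h * w + (1.0 - h), 1e-10, None)
    Wd = 1.0 / d
    A = Cstar.T @ (Cstar * Wd[:, None])
    b = np.linalg.solve(A, Cstar.T @ (ystar * Wd))
    r = ystar - Cstar @ b
    sigma2 = float(np.sum(r * r * Wd)) / (n - q)
    return {"h": h, "sigma_g2": h * sigma2, "sigma_e2": (1 - h) * sigma2,
            "eigvals": w, "eigvecs": U, "weights": Wd}


def pav_gwas_mlm(y: pd.Series, gm: SVGenotypeMatrix, K: pd.DataFrame,
                 S: pd.DataFrame,
                 threshold_logp: float = DEFAULT_GWAS_THRESHOLD,
                 reml_per_marker: bool = False) -> pd.DataFrame:
    """Mixed-linear-model association of each SV with a quantitative trait.

    Model: y = X a + S b + g + e with g ~ N(0, sg2 K), e ~ N(0, se2 I).
    Variance components are estimated once by REML on the null model (no
    marker) through the spectral decomposition of K and reused for every
    marker (population-parameters-previously-determined approximation);
    ``reml_per_marker=True`` re-estimates them per marker for validation on
    small marker sets. Missing genotypes are mean-imputed per marker. A
    marker is significant iff -log10(p) > ``threshold_logp``.
    """
    ids = [i for i in gm.individuals if i in y.index and i in K.index]
    n = len(ids)
    if n <= S.shape[1] + 2:
        raise ValueError("too few individuals for the fixed-effect design")
    yv = y.loc[ids].to_numpy(dtype=float)
    C = np.column_stack([np.ones(n), S.loc[ids].to_numpy(dtype=float)])
    Km = K.loc[ids, ids].to_numpy(dtype=float)
    X = gm.genotypes[ids].to_numpy(dtype=float).T    # n x m
    col_means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_means[None, :], X)

    null = _reml_null(yv, C, Km)
    rows = []
    if reml_per_marker:
        for j, sv_id in enumerate(gm.genotypes.index):
            beta, se, p = _single_marker_reml(yv, C, Km, X[:, j])
            rows.append((sv_id, beta, se, p))
    else:
        U, Wd = null["eigvecs"], null["weights"]
        ystar = U.T @ yv
        Cstar = U.T @ C
        Xstar = U.T @ X
        A = Cstar.T @ (Cstar * Wd[:, None])
        A_inv = np.linalg.inv(A)
        b_vec = Cstar.T @ (ystar * Wd)
        yWy = float(np.sum(ystar * ystar * Wd))
        Uj = Cstar.T @ (Xstar * Wd[:, None])            # q x m
        sj = np.einsum("ij,ij->j", Xstar, Xstar * Wd[:, None])
        tj = Xstar.T @ (ystar * Wd)
        AinvU = A_inv @ Uj
        schur = sj - np.einsum("ij,ij->j", Uj, AinvU)
        q = C.shape[1]
        dof = n - q - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_x = (tj - AinvU.T @ b_vec) / schur
            beta_c = A_inv @ (b_vec[:, None] - Uj * beta_x[None, :])
            rss = yWy - (np.einsum("ij,i->j", beta_c, b_vec) + tj * beta_x)
            sigma2_j = rss / dof
            se = np.sqrt(sigma2_j / schur)
            tstat = beta_x / se
        for j, sv_id in enumerate(gm.genotypes.index):
            if not np.isfinite(tstat[j]) or schur[j] <= 1e-12:
                log.info("gwas: marker %s has a singular design, skipped", sv_id)
                rows.append((sv_id, np.nan, np.nan, np.nan))
                continue
            p = 2.0 * stats.t.sf(abs(float(tstat[j])), df=dof)
            rows.append((sv_id, float(beta_x[j]), float(se[j]), p))

    out = pd.DataFrame(rows, columns=["sv_id", "beta", "se", "p"]).set_index("sv_id")
    with np.errstate(divide="ignore"):
        out["logp"] = -np.log10(out["p"])
    out["significant"] = out["logp"] > threshold_logp
    out.attrs["variance_components"] = {
        "sigma_g2": null["sigma_g2"], "sigma_e2": null["sigma_e2"],
        "h": null["h"]}
    return out


def _single_marker_reml(y, C, K, x) -> Tuple[float, float, float]:
    D = np.column_stack([C, x])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        return np.nan, np.nan, np.nan
    fit = _reml_null(y, D, K)
    U, Wd = fit["eigvecs"], fit["weights"]
    Dstar, ystar = U.T @ D, U.T @ y
    A = Dstar.T @ (Dstar * Wd[:, None])
    A_inv = np.linalg.inv(A)
    beta = A_inv @ (Dstar.T @ (ystar * Wd))
    r = ystar - Dstar @ beta
    dof = len(y) - D.shape[1]
    sigma2 = float(np.sum(r * r * Wd)) / dof
    se = float(np.sqrt(sigma2 * A_inv[-1, -1]))
    tstat = beta[-1] / se
    return float(beta[-1]), se, 2.0 * stats.t.sf(abs(float(tstat)), df=dof)


def genomic_inflation(pvalues: Sequence[float]) -> float:
    """lambda_GC: median association chi-squared over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ------------------------------------------------- diversity statistics


def pi_windows(haplotypes: pd.DataFrame, positions: pd.Series,
               window: int) -> pd.DataFrame:
    """Windowed nucleotide diversity for a 0/1 haplotype table (sites x
    samples).

    pi in a window is the mean pairwise difference per surveyed site:
    sum over sites of 2 p (1 - p) n/(n-1), divided by the number of sites in
    the window. Windows without markers are excluded."""
    H = haplotypes.to_numpy(dtype=float)
    n = H.shape[1]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    p = H.mean(axis=1)
    per_site = 2.0 * p * (1.0 - p) * n / (n - 1)
    pos = positions.to_numpy()
    rows = []
    for start in range(0, int(pos.max()) + 1, window):
        inside = (pos >= start) & (pos < start + window)
        if not inside.any():
            continue
        rows.append({"start": start, "end": start + window,
                     "n_sites": int(inside.sum()),
                     "pi": float(per_site[inside].mean())})
    return pd.DataFrame(rows)


def shannon_index(haplotypes: pd.DataFrame) -> float:
    """Shannon diversity aggregated as the sum of per-locus -sum p ln p over
    allele frequencies (documented convention)."""
    p = haplotypes.to_numpy(dtype=float).mean(axis=1)
    total = 0.0
    for freq in p:
        for q in (freq, 1.0 - freq):
            if q > 0:
                total -= q * np.log(q)
    return float(total)


def windowed_density_correlation(positions_a: Sequence[int],
                                 positions_b: Sequence[int],
                                 window: int, span: Optional[int] = None
                                 ) -> Tuple[float, float]:
    """Spearman correlation between two cohorts' windowed marker densities."""
    pa, pb = np.asarray(positions_a), np.asarray(positions_b)
    span = span or int(max(pa.max(), pb.max())) + 1
    edges = np.arange(0, span + window, window)
    da, _ = np.histogram(pa, bins=edges)
    db, _ = np.histogram(pb, bins=edges)
    rho, p = stats.spearmanr(da, db)
    return float(rho), float(p)
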