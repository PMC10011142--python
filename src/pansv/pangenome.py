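"""Pan-genome gene-family partitioning and saturation analysis.

The gene-family matrix (families x accessions, member counts) is an input —
orthology clustering itself is upstream. Families present in every accession
are core, in exactly one are private, and everything in between (2 to n-1
accessions) is dispensable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

MAX_EXHAUSTIVE_ACCESSIONS = 8


def _presence(matrix: pd.DataFrame) -> np.ndarray:
    if matrix.shape[1] < 2:
        raise ValueError("need at least two accessions")
    pres = matrix.to_numpy() > 0
    occupancy = pres.sum(axis=1)
    if (occupancy == 0).any():
        empties = matrix.index[occupancy == 0].tolist()
        raise ValueError(f"families with zero occupancy: {empties[:5]}")
    return pres


def classify_families(matrix: pd.DataFrame) -> dict:
    """Partition families into core / dispensable / private.

    Returns the per-family labels, the partition sizes, and for every
    accession the composition fractions over families present in it.
    """
    pres = _presence(matrix)
    n = matrix.shape[1]
    occupancy = pres.sum(axis=1)
    labels = np.where(occupancy == n, "core",
                      np.where(occupancy == 1, "private", "dispensable"))
    labels = pd.Series(labels, index=matrix.index, name="label")
    composition = {}
    for j, acc in enumerate(matrix.columns):
        here = labels[pres[:, j]]
        total = len(here)
        composition[acc] = {
            lab: (here == lab).sum() / total if total else np.nan
            for lab in ("core", "dispensable", "private")
        }
    sizes = labels.value_counts().reindex(
        ["core", "dispensable", "private"], fill_value=0).to_dict()
    return {"labels": labels, "sizes": sizes,
            "composition": pd.DataFrame(composition).T}


def saturation_curve(matrix: pd.DataFrame, n_permutations: int = 1000,
                     seed: int = 0, exhaustive: bool = False,
                     order: Optional[list] = None) -> pd.DataFrame:
    """Pan/core gene-family saturation over accession orderings.

    pan(k) counts families present in at least one of the first k accessions
    of an ordering, core(k) those present in all of them; added(k) =
    pan(k) - pan(k-1). With ``exhaustive=True`` every ordering is enumerated
    (feasible up to 8 accessions); with ``order`` a single fixed ordering is
    used; otherwise ``n_permutations`` random orderings are sampled, and
    means and standard deviations across orderings are reported.
    """
    pres = _presence(matrix)
    n = matrix.shape[1]
    if order is not None:
        cols = list(matrix.columns)
        orders = [np.array([cols.index(a) for a in order])]
    elif exhaustive:
        if n > MAX_EXHAUSTIVE_ACCESSIONS:
            raise ValueError(
                f"exhaustive enumeration limited to {MAX_EXHAUSTIVE_ACCESSIONS}"
                f" accessions, got {n}")
        orders = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in range(n_permutations)]

    pan = np.empty((len(orders), n), dtype=np.int64)
    core = np.empty_like(pan)
    for i, ordr in enumerate(orders):
        cum_any = np.cumsum(pres[:, ordr], axis=1) > 0
        cum_all = np.cumprod(pres[:, ordr], axis=1) > 0
        pan[i] = cum_any.sum(axis=0)
        core[i] = cum_all.sum(axis=0)
    added = np.diff(pan, axis=1, prepend=0)
    return pd.DataFrame({
        "k": np.arange(1, n + 1),
        "pan_mean": pan.mean(axis=0), "pan_sd": pan.std(axis=0, ddof=0),
        "core_mean": core.mean(axis=0), "core_sd": core.std(axis=0, ddof=0),
        "added_mean": added.mean(axis=0),
    }).set_index("k")


def added_family_ratio(added_at_k: int, total_families: int) -> float:
    """Percentage of all families added at step k, rounded to two decimals."""
    if total_families <= 0:
        raise ValueError("total_families must be positive")
    return round(100.0 * added_at_k / total_families, 2)


# ---------------------------------------------------------- simulation


def simulate_family_matrix(n_families: int, fractions: dict,
                           accessions: list, rng: np.random.Generator
                           ) -> pd.DataFrame:
    """Family-count matrix with configured core/dispensable/private shares."""
    n_acc = len(accessions)
    counts = np.zeros((n_families, n_acc), dtype=np.int64)
    n_core = int(round(fractions["core"] * n_families))
    n_priv = int(round(fractions["private"] * n_families))
    n_disp = n_families - n_core - n_priv
    row = 0
    for _ in range(n_core):
        counts[row] = rng.integers(1, 4, size=n_acc)
        row += 1
    for _ in range(n_disp):
        occ = int(rng.integers(2, n_acc))  # 2 .. n-1 accessions
        cols = rng.choice(n_acc, size=occ, replace=False)
        counts[row, cols] = rng.integers(1, 4, size=occ)
        row += 1
    for _ in range(n_priv):
        counts[row, int(rng.integers(n_acc))] = int(rng.integers(1, 4))
        row += 1
    return pd.DataFrame(
        counts, index=[f"fam{i + 1:05d}" for i in range(n_families)],
        columns=accessions)
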