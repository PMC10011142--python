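"""k-mer frequency histogram simulation for the genome-survey estimator.

Rather than materialising reads, the simulator tracks, for every k-mer start
position of the genome, how many reads cover it — which is exactly the
k-mer count when reads are error-free substrings of a genome whose k-mers
are unique. Sequencing errors are modelled as binomial thinning of the true
observations (an error anywhere in a k-mer corrupts it, probability
1 - (1-e)^k) with the corrupted copies re-entering the histogram as
singletons, the regime the low-frequency term B of the genome-size formula
is designed to remove.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..estimators import KmerHistogram


def simulate_kmer_histogram(genome_size: int, depth: float,
                            read_length: int, k: int = 17,
                            error_rate: float = 0.0,
                            coverage: str = "uniform",
                            rng: Optional[np.random.Generator] = None,
                            seed: int = 0) -> KmerHistogram:
    """Simulate the k-mer frequency histogram of a sequencing run.

    ``coverage="uniform"`` spreads the read starts evenly (every genome
    k-mer observed floor(D) or ceil(D) times, D the per-k-mer depth);
    ``coverage="random"`` draws read starts uniformly at random, giving a
    Poisson-shaped frequency peak. Assumes all genome k-mers are distinct.
    """
    if k > read_length:
        raise ValueError("k-mer size exceeds the read length")
    if not 0 <= error_rate < 1:
        raise ValueError("error rate must lie in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_reads = int(round(genome_size * depth / read_length))
    kmers_per_read = read_length - k + 1
    n_positions = genome_size - k + 1
    total_obs = n_reads * kmers_per_read

    if coverage == "uniform":
        base, extra = divmod(total_obs, n_positions)
        cov = np.full(n_positions, base, dtype=np.int64)
        if extra:
            cov[rng.choice(n_positions, size=extra, replace=False)] += 1
    elif coverage == "random":
        starts = rng.integers(0, genome_size - read_length + 1, size=n_reads)
        diff = np.zeros(n_positions + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        ends = np.minimum(starts + kmers_per_read, n_positions)
        np.add.at(diff, ends, -1)
        cov = np.cumsum(diff[:-1])
    else:
        raise ValueError(f"unknown coverage mode {coverage!r}")

    n_error_obs = 0
    if error_rate > 0:
        keep_p = (1.0 - error_rate) ** k
        kept = rng.binomial(cov, keep_p)
        n_error_obs = int(cov.sum() - kept.sum())
        cov = kept

    hist = np.bincount(cov)
    counts = {int(d): int(c) for d, c in enumerate(hist) if d > 0 and c > 0}
    if n_error_obs:
        counts[1] = counts.get(1, 0) + n_error_obs  # erroneous singletons
    return KmerHistogram(counts=counts, n_reads=n_reads,
                         read_length=read_length, k=k)
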