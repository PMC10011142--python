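"""Closed-form estimators used throughout the analysis.

Four small calculators: k-mer genome-size estimation (Lander-Waterman style),
LTR retrotransposon insertion-time dating under the Jukes-Cantor model,
transcription-factor proportion, and relative electrical conductivity (REC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

DEFAULT_SUBSTITUTION_RATE = 1.3e-8  # substitutions per site per year
JC_SATURATION = 0.75


@dataclass
class KmerHistogram:
    """k-mer frequency histogram with the read tallies the genome-size
    formula consumes.

    ``counts`` maps k-mer depth -> number of distinct k-mers observed at that
    depth. ``n_reads`` (N) and ``read_length`` (L) describe the sequencing
    run; ``k`` is the k-mer size (default 17 bp).
    """

    counts: Dict[int, int]
    n_reads: int
    read_length: float
    k: int = 17

    @property
    def low_frequency_kmers(self) -> int:
        """B: total number of k-mer observations in k-mers with frequency <= 1."""
        return sum(d * c for d, c in self.counts.items() if d <= 1)

    @property
    def peak_depth(self) -> int:
        """D: modal depth of the frequency curve, excluding the error peak
        at depth <= 1."""
        informative = {d: c for d, c in self.counts.items() if d > 1}
        if not informative:
            raise ValueError("histogram has no k-mers with depth > 1")
        return max(sorted(informative), key=lambda d: informative[d])

    def genome_size(self) -> "GenomeSizeEstimate":
        return genome_size_kmer(
            self.n_reads, self.read_length, self.k,
            self.low_frequency_kmers, self.peak_depth,
        )


@dataclass(frozen=True)
class GenomeSizeEstimate:
    genome_size: int      # rounded bp
    raw: float            # unrounded estimate


def genome_size_kmer(n_reads: int, read_length: float, k: int,
                     low_freq_kmers: int, peak_depth: float) -> GenomeSizeEstimate:
    """Estimate genome size G = (N * (L - k + 1) - B) / D.

    N is the number of reads, L the mean read length, k the k-mer size, B the
    number of low-frequency (error) k-mer observations and D the peak depth
    of the k-mer frequency curve.
    """
    if peak_depth <= 0:
        raise ValueError("peak depth D must be positive")
    if k > read_length:
        raise ValueError("k-mer size exceeds the read length")
    effective = n_reads * (read_length - k + 1) - low_freq_kmers
    if effective < 0:
        raise ValueError("negative effective k-mer count (B > N*(L-k+1))")
    raw = effective / peak_depth
    return GenomeSizeEstimate(genome_size=int(round(raw)), raw=raw)


def ltr_insertion_time(lam: float,
                       rate: float = DEFAULT_SUBSTITUTION_RATE) -> Tuple[float, float]:
    """Date an LTR retrotransposon insertion from 5'/3' LTR divergence.

    ``lam`` is the observed per-site nucleotide divergence between the two
    LTR copies. The Jukes-Cantor distance is K = -0.75 * ln(1 - 4*lam/3) and
    the insertion time T = K / (2 r) years, with r substitutions per site per
    year. Returns (K, T).
    """
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if not 0 <= lam < JC_SATURATION:
        raise ValueError(
            f"divergence {lam} outside the Jukes-Cantor domain [0, 0.75)"
        )
    K = -0.75 * math.log(1.0 - 4.0 * lam / 3.0)
    T = K / (2.0 * rate)
    return K, T


def jc_expected_divergence(time_years: float,
                           rate: float = DEFAULT_SUBSTITUTION_RATE) -> float:
    """Forward Jukes-Cantor expectation: E[lambda] for two LTR copies that
    diverged ``time_years`` ago (K = 2 r T). Exact inverse of
    :func:`ltr_insertion_time`."""
    K = 2.0 * rate * time_years
    return 0.75 * (1.0 - math.exp(-4.0 * K / 3.0))


def tf_proportion(n_tf: int, n_total: int) -> float:
    """Proportion of transcription-factor genes, N_TF / N_total."""
    if n_total <= 0:
        raise ValueError("total gene count must be positive")
    if not 0 <= n_tf <= n_total:
        raise ValueError("N_TF must lie in [0, N_total]")
    return n_tf / n_total


def rec(s1: float, s2: float) -> float:
    """Relative electrical conductivity, REC = S1/S2 x 100%.

    S1 is the conductivity of the leaf soak before boiling, S2 after boiling
    (total electrolytes).
    """
    if s2 <= 0:
        raise ValueError("S2 must be positive")
    return 100.0 * s1 / s2
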