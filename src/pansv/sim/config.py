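"""Simulation configuration.

One :class:`SimConfig` drives every generator. A single root seed is expanded
into independent per-submodule streams (reference, SV implanting, expression,
population, k-mer, LTR) so that changing one stage never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import numpy as np
import yaml


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-submodule stream derived from the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) % (2**31),
                               spawn_key=(zlib.crc32(label.encode()),))
    )


def _default_sv_rates() -> Dict[str, int]:
    # events in the shared pool; each accession carries a random subset
    return {"PAV_ins": 20, "PAV_del": 20, "CNV": 6, "INV": 4, "TRANS": 2}


def _default_sv_lengths() -> Dict[str, Tuple[int, int, float]]:
    # (min bp, max bp, shape); lengths are drawn log-uniform^shape in [min, max]
    return {
        "PAV_ins": (50, 3000, 1.0),
        "PAV_del": (50, 3000, 1.0),
        "CNV": (1100, 4000, 1.0),  # copy blocks must survive the 1 kb filter
        "INV": (1500, 20000, 1.0),
        "TRANS": (2000, 10000, 1.0),
    }


def _default_expression() -> Dict[str, float]:
    return {
        "mean_tpm": 20.0,          # scale of the log-normal baseline
        "nb_dispersion": 0.1,      # NB variance = mu + phi * mu^2
        "heat_fraction": 0.3,      # fraction of genes that respond to heat
        "heat_log2fc": 2.0,        # |log2FC| applied under heat (random sign)
        "cis_sv_log2fc": 2.0,      # cis effect of a linked SV when present
        "library_size": 2e5,       # expected counts per sample
    }


def _default_population() -> Dict[str, float]:
    return {
        "n_individuals": 200,
        "n_svs": 2000,
        "n_differentiated": 20,    # SVs with group-differentiated frequency
        "group_delta_f": 0.8,      # |f_tropical - f_temperate| for those SVs
        "cluster_differentiated": True,
        "chrom_length": 10_000_000,
        "fst": 0.05,               # background drift between the two groups
        "missing_rate": 0.02,
        "polygenic_h2": 0.3,
        "causal_h2": 0.15,         # trait variance explained by the causal SV
        "latitude_gradient": True,
    }


def _default_kmer() -> Dict[str, float]:
    return {"depth": 30.0, "read_length": 100, "k": 17, "error_rate": 0.0}


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic pan-genome.

    Defaults emulate a desk-scale version of an eleven-accession pan-genome:
    ten query accessions against one reference, a shared pool of implanted
    SV events, three biological replicates per expression condition, and a
    two-group structured population of 200 diploid-equivalent individuals.
    """

    seed: int = 0
    ref_length: int = 1_000_000          # bp per chromosome
    n_chroms: int = 2
    n_accessions: int = 10
    sv_rates: Dict[str, int] = field(default_factory=_default_sv_rates)
    sv_length_distributions: Dict[str, Tuple[int, int, float]] = field(
        default_factory=_default_sv_lengths)
    sv_share_prob: float = 0.6           # P(an accession carries a pool event)
    min_event_separation: int = 2000     # keeps every flanking block > 1 kb
    n_genes: int = 200
    gene_length_range: Tuple[int, int] = (1000, 4000)
    max_exons: int = 4
    repeat_fraction: float = 0.4
    n_families: int = 2000
    family_fractions: Dict[str, float] = field(
        default_factory=lambda: {"core": 0.50, "dispensable": 0.45, "private": 0.05})
    expression: Dict[str, float] = field(default_factory=_default_expression)
    population: Dict[str, float] = field(default_factory=_default_population)
    kmer: Dict[str, float] = field(default_factory=_default_kmer)

    def __post_init__(self) -> None:
        if self.ref_length < 10_000:
            raise ValueError("ref_length must be at least 10 kb")
        # a partial sv_rates dict means "only these types" (others zero);
        # partial length distributions keep defaults for unnamed types
        rates = {k: 0 for k in _default_sv_rates()}
        rates.update(self.sv_rates)
        self.sv_rates = rates
        lengths = _default_sv_lengths()
        lengths.update({k: tuple(v) for k, v in
                        self.sv_length_distributions.items()})
        self.sv_length_distributions = lengths
        total = sum(self.family_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"family_fractions must sum to 1, got {total}")
        for name, count in self.sv_rates.items():
            if count < 0:
                raise ValueError(f"negative SV count for {name}")
        for name, (lo, hi, shape) in self.sv_length_distributions.items():
            if not (0 < lo <= hi):
                raise ValueError(f"bad length range for {name}: ({lo}, {hi})")

    def rng(self, label: str) -> np.random.Generator:
        return derive_rng(self.seed, label)

    @property
    def accessions(self) -> list:
        return [f"acc{i + 1:02d}" for i in range(self.n_accessions)]

    @property
    def chroms(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    # -- YAML round trip -------------------------------------------------

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("sv_length_distributions", "gene_length_range"):
            if key in data and isinstance(data[key], dict):
                data[key] = {k: tuple(v) for k, v in data[key].items()}
            elif key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def draw_sv_length(rng: np.random.Generator, lo: int, hi: int,
                   shape: float = 1.0) -> int:
    """Log-uniform length draw with a shape exponent (shape > 1 skews short)."""
    u = rng.random() ** shape
    return int(round(lo * (hi / lo) ** u)) if hi > lo else lo
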