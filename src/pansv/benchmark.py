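"""Truth-recovery benchmarking of SV calls against implanted events."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

from .core import StructuralVariant
from .sim.genome import TruthRecord

DEFAULT_MATCH_TOL = 100


@dataclass
class RecoveryStats:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


def _matches(call: StructuralVariant, truth: TruthRecord, tol: int) -> bool:
    if call.ref_chrom != truth.ref_chrom:
        return False
    if call.sv_type == "PAV_ins":
        return (abs(call.ref_start - truth.ref_start) <= tol
                and abs(call.length - truth.length) <= tol)
    return (abs(call.ref_start - truth.ref_start) <= tol
            and abs(call.ref_end - truth.ref_end) <= tol)


def truth_recovery(calls: Sequence[StructuralVariant],
                   truths: Sequence[TruthRecord],
                   tol: int = DEFAULT_MATCH_TOL
                   ) -> Dict[str, RecoveryStats]:
    """Per-type precision/recall/F1, matching per accession within ``tol``.

    Each (accession, truth) pair may consume at most one call and vice
    versa; PAV types are evaluated together under a "PAV" key as well as
    separately. TRANS truths match calls at the source locus.
    """
    by_type: Dict[str, RecoveryStats] = {}
    types = sorted({t.sv_type for t in truths} | {c.sv_type for c in calls})
    for sv_type in types:
        t_pool: List[tuple] = [
            (acc, t) for t in truths if t.sv_type == sv_type
            for acc in sorted(t.accessions_present)]
        c_pool = [c for c in calls if c.sv_type == sv_type]
        used = [False] * len(t_pool)
        tp = 0
        for call in c_pool:
            for i, (acc, truth) in enumerate(t_pool):
                if used[i] or acc != call.accession:
                    continue
                if _matches(call, truth, tol):
                    used[i] = True
                    tp += 1
                    break
        by_type[sv_type] = RecoveryStats(
            true_positives=tp, false_positives=len(c_pool) - tp,
            false_negatives=len(t_pool) - tp)
    pav_keys = [k for k in ("PAV_ins", "PAV_del") if k in by_type]
    if pav_keys:
        by_type["PAV"] = RecoveryStats(
            true_positives=sum(by_type[k].true_positives for k in pav_keys),
            false_positives=sum(by_type[k].false_positives for k in pav_keys),
            false_negatives=sum(by_type[k].false_negatives for k in pav_keys))
    return by_type
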