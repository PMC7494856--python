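"""Scoring of predicted phases against a ground-truth haplotype.

The headline accuracy measure is the switch-error rate: the percentage of
consecutive assessable SNP pairs within blocks whose predicted relative
orientation disagrees with the truth's.  It is invariant to which haplotype
is labelled h0 (a block and its complement score identically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .model import PhasedBlock, SNPPanel


@dataclass
class PhasingMetrics:
    n_snps_phased: int = 0
    switch_errors: int = 0
    assessable_pairs: int = 0
    switch_error_rate: float = float("nan")  # percentage
    total_span_kb: float = 0.0

    def summary(self) -> str:
        ser = (
            "undefined"
            if math.isnan(self.switch_error_rate)
            else f"{self.switch_error_rate:.2f}%"
        )
        return (
            f"SNPs phased: {self.n_snps_phased}; switch errors: "
            f"{self.switch_errors}/{self.assessable_pairs} pairs ({ser}); "
            f"span: {self.total_span_kb:.1f} kb"
        )


def switch_error_rate(
    predicted: Sequence[PhasedBlock],
    truth: Dict[Tuple[str, int], int],
    panel: SNPPanel,
) -> PhasingMetrics:
    """Pooled switch-error rate of predicted blocks against an oriented truth.

    Per block, SNPs without truth are skipped; between each consecutive
    assessable pair a switch is recorded when the predicted relative
    orientation (parallel vs switched) differs from the truth's.  The rate is
    100 * switches / assessable pairs pooled over blocks; with no assessable
    pair anywhere it is reported as NaN with zero denominators.
    """
    switches = 0
    pairs = 0
    for block in predicted:
        assessable: List[Tuple[int, int]] = []  # (predicted allele, truth allele)
        for s, a in zip(block.snp_indices, block.h0):
            snp = panel.get(block.chrom, s)
            t = truth.get((block.chrom, snp.pos))
            if t is not None:
                assessable.append((a, t))
        for (a1, t1), (a2, t2) in zip(assessable, assessable[1:]):
            pairs += 1
            if (a1 == a2) != (t1 == t2):
                switches += 1
    rate = 100.0 * switches / pairs if pairs else float("nan")
    metrics = block_span_and_counts(predicted, panel)
    metrics.switch_errors = switches
    metrics.assessable_pairs = pairs
    metrics.switch_error_rate = rate
    return metrics


def block_span_and_counts(
    predicted: Sequence[PhasedBlock], panel: SNPPanel
) -> PhasingMetrics:
    """Completeness metrics: total SNPs phased and summed block span in kb."""
    n_snps = sum(b.size for b in predicted)
    span = 0.0
    for b in predicted:
        first = panel.get(b.chrom, b.snp_indices[0]).pos
        last = panel.get(b.chrom, b.snp_indices[-1]).pos
        span += (last - first) / 1000.0
    return PhasingMetrics(n_snps_phased=n_snps, total_span_kb=span)


def metrics_table(metrics: PhasingMetrics):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "n_snps_phased": metrics.n_snps_phased,
                "switch_errors": metrics.switch_errors,
                "assessable_pairs": metrics.assessable_pairs,
                "switch_error_rate_pct": metrics.switch_error_rate,
                "total_span_kb": metrics.total_span_kb,
            }
        ]
    )
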