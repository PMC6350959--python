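"""Small exact statistics used around the screen: clutch percentages,
across-experiment mean/SD, and relative qPCR quantification by ΔΔCt.

Rounding of percentages is half-up (so 25.7069… prints as 25.7 at one
decimal and 6.31… as 6 at zero decimals).  ΔΔCt assumes amplification
efficiency 2 (a perfect doubling per cycle): fold change = 2^(−ΔΔCt)
with ΔΔCt = (Ct_target − Ct_reference)_sample − (Ct_target − Ct_reference)_calibrator.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


@dataclass(frozen=True)
class ClutchCount:
    """Affected embryos out of a clutch total."""

    affected: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError("clutch total must be >= 1")
        if not 0 <= self.affected <= self.total:
            raise ValueError("affected must be within [0, total]")


@dataclass(frozen=True)
class CtMeasurements:
    """Cycle thresholds for target and reference gene in sample and calibrator."""

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_sample,
            self.ct_reference_sample,
            self.ct_target_calibrator,
            self.ct_reference_calibrator,
        ):
            if not math.isfinite(v):
                raise ValueError("Ct values must be finite")


def clutch_percentage(c: ClutchCount, decimals: int = 1) -> float:
    """Percentage of affected embryos, rounded half-up to ``decimals``."""
    pct = Decimal(100 * c.affected) / Decimal(c.total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def summarize_clutches(
    percentages: list[float],
) -> tuple[float, float | None, int]:
    """Mean, sample standard deviation (n−1; None for a single value) and n."""
    if not percentages:
        raise ValueError("no percentages given")
    mean = statistics.fmean(percentages)
    sd = statistics.stdev(percentages) if len(percentages) >= 2 else None
    return mean, sd, len(percentages)


def ddct_fold_change(m: CtMeasurements) -> float:
    """Relative expression 2^(−ΔΔCt), target normalised to the reference
    gene and to the calibrator condition."""
    ddct = (m.ct_target_sample - m.ct_reference_sample) - (
        m.ct_target_calibrator - m.ct_reference_calibrator
    )
    return 2.0 ** (-ddct)
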