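"""Four-level access classification from the ratio distribution.

Thresholds come from the covered block groups' ratio distribution: the top
1% of ratios (typically block groups adjacent to major medical centers,
whose tiny served populations give extreme leverage) are dropped, the mean
and SD are computed over the remainder, and the "average access" band is
mean +/- 0.5 SD.  The excluded block groups are only removed from the
moment computation — they remain classified and counted (they land in
ABOVE_AVERAGE).

Levels:
    NO_ACCESS      outside every catchment
    BELOW_AVERAGE  0 < ratio < mean - band*sd
    AVERAGE        mean - band*sd <= ratio <= mean + band*sd   (closed band)
    ABOVE_AVERAGE  ratio > mean + band*sd

The top-fraction exclusion is applied to both the mean and the SD: mixing
an outlier-trimmed mean with an untrimmed SD would be an incoherent
estimator pair.  The SD is the sample standard deviation (ddof=1).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .accessibility import AccessRecord

__all__ = ["AccessLevel", "Thresholds", "compute_thresholds", "classify", "classify_records"]


class AccessLevel(enum.Enum):
    NO_ACCESS = "no_access"
    BELOW_AVERAGE = "below_average"
    AVERAGE = "average"
    ABOVE_AVERAGE = "above_average"


LEVEL_ORDER = [
    AccessLevel.NO_ACCESS,
    AccessLevel.BELOW_AVERAGE,
    AccessLevel.AVERAGE,
    AccessLevel.ABOVE_AVERAGE,
]


@dataclass(frozen=True)
class Thresholds:
    """Access-band parameters derived from covered block-group ratios."""

    mean: float
    sd: float
    band: float
    exclude_top_fraction: float
    n_used: int
    n_excluded: int

    @property
    def lower(self) -> float:
        return self.mean - self.band * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.band * self.sd

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "band": self.band,
            "exclude_top_fraction": self.exclude_top_fraction,
            "lower": self.lower,
            "upper": self.upper,
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
        }


def compute_thresholds(
    ratios,
    exclude_top_fraction: float = 0.01,
    band: float = 0.5,
) -> Thresholds:
    """Trimmed-moment access band from covered block-group ratios.

    Sorts the ratios, drops the top ceil(exclude_top_fraction * n), and
    computes the unweighted mean and sample SD of the remainder.
    """
    arr = np.asarray(sorted(float(r) for r in ratios))
    n = arr.size
    if n < 2:
        raise ValueError(f"need at least 2 covered block-group ratios, got {n}")
    if not 0 <= exclude_top_fraction < 1:
        raise ValueError(f"exclude_top_fraction must be in [0, 1), got {exclude_top_fraction}")
    n_excluded = math.ceil(exclude_top_fraction * n) if exclude_top_fraction > 0 else 0
    kept = arr[: n - n_excluded]
    if kept.size < 2:
        raise ValueError("top-fraction exclusion left fewer than 2 ratios")
    mean = float(np.mean(kept))
    sd = float(np.std(kept, ddof=1))
    return Thresholds(
        mean=mean,
        sd=sd,
        band=float(band),
        exclude_top_fraction=float(exclude_top_fraction),
        n_used=int(kept.size),
        n_excluded=int(n_excluded),
    )


def classify(record: AccessRecord, thresholds: Thresholds) -> AccessLevel:
    """Assign one of the four access levels to a block-group record.

    The AVERAGE band is closed on both sides; a ratio exactly at a band
    edge is AVERAGE.  Block groups excluded from the moment computation
    are still classified here (they exceed ``upper`` and land in
    ABOVE_AVERAGE).
    """
    if not record.covered:
        return AccessLevel.NO_ACCESS
    r = record.ratio
    if r < thresholds.lower:
        return AccessLevel.BELOW_AVERAGE
    if r <= thresholds.upper:
        return AccessLevel.AVERAGE
    return AccessLevel.ABOVE_AVERAGE


def classify_records(
    records: list[AccessRecord], thresholds: Thresholds
) -> dict[str, AccessLevel]:
    """Level per block-group id for a batch of records."""
    return {rec.blockgroup_id: classify(rec, thresholds) for rec in records}
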