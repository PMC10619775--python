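"""Block-group bed-to-population ratios (beds per 100,000 adults served).

Each facility i with beds b_i and served population P_i (summed adult
population of the block groups in its catchment) has ratio

    r_i = 100000 * b_i / P_i .

The default block-group ratio is the two-step floating catchment area
(2SFCA) form: the sum of r_i over every facility accessible to the block
group.  This form satisfies an exact conservation identity used as the
module's correctness oracle:

    sum_j pop_j * ratio_j = 100000 * sum_i b_i      (over facilities with P_i > 0)

A second reading, ``union_pool``, pools the beds of all accessible
facilities over the population of the union of their catchments; it is
retained as a sensitivity variant.  The two coincide when a single
facility covers everything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .catchment import BlockGroup, CatchmentIndex, Facility

__all__ = ["AccessRecord", "facility_ratio", "block_ratio", "compute_access_records", "VARIANTS"]

log = logging.getLogger(__name__)

VARIANTS = ("sum_of_facility_ratios", "union_pool")


@dataclass(frozen=True)
class AccessRecord:
    """Per-block-group accessibility: covered flag and beds/100k ratio.

    ``ratio`` is None when the block group is outside every catchment.
    """

    blockgroup_id: str
    covered: bool
    ratio: float | None
    threshold_minutes: float


def facility_ratio(facility: Facility, index: CatchmentIndex) -> float | None:
    """Beds per 100,000 adults served, or None if the facility serves nobody.

    A facility whose catchment contains no populated block group has an
    undefined ratio; it is dropped from downstream sums (never treated as
    an infinite ratio) with a logged warning.
    """
    served_pop = index.served_population.get(facility.id, 0)
    if served_pop <= 0:
        log.warning(
            "facility %s serves no populated block group at T=%g min; excluded from ratios",
            facility.id,
            index.threshold_minutes,
        )
        return None
    return 100000.0 * facility.adult_icu_beds / served_pop


def block_ratio(
    block_group: BlockGroup,
    index: CatchmentIndex,
    facilities_by_id: dict[str, Facility],
    variant: str = "sum_of_facility_ratios",
    *,
    _facility_ratios: dict[str, float | None] | None = None,
    _block_pops: dict[str, int] | None = None,
) -> AccessRecord:
    """Accessibility record for one populated block group.

    The two keyword caches let batch callers avoid recomputing per-facility
    ratios and population lookups; single calls may omit them.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown ratio variant {variant!r}; expected one of {VARIANTS}")
    if not block_group.populated:
        raise ValueError(f"block group {block_group.id!r} has zero population")

    accessible = index.accessible.get(block_group.id, set())
    if not accessible:
        return AccessRecord(block_group.id, False, None, index.threshold_minutes)

    if variant == "sum_of_facility_ratios":
        if _facility_ratios is None:
            _facility_ratios = {
                fid: facility_ratio(facilities_by_id[fid], index) for fid in accessible
            }
        total = 0.0
        for fid in accessible:
            r = _facility_ratios.get(fid)
            if r is not None:
                total += r
        ratio = total
    else:  # union_pool
        beds = sum(facilities_by_id[fid].adult_icu_beds for fid in accessible)
        union_ids: set[str] = set()
        for fid in accessible:
            union_ids |= index.served[fid]
        if _block_pops is None:
            raise ValueError("union_pool variant requires _block_pops (id -> pop_total)")
        union_pop = sum(_block_pops[j] for j in union_ids)
        ratio = 100000.0 * beds / union_pop

    return AccessRecord(block_group.id, True, ratio, index.threshold_minutes)


def compute_access_records(
    block_groups: list[BlockGroup],
    facilities: list[Facility],
    index: CatchmentIndex,
    variant: str = "sum_of_facility_ratios",
) -> list[AccessRecord]:
    """Access records for every populated block group, in input order."""
    facilities_by_id = {f.id: f for f in facilities}
    ratios = {f.id: facility_ratio(f, index) for f in facilities}
    pops = {bg.id: bg.pop_total for bg in block_groups if bg.populated}
    return [
        block_ratio(
            bg, index, facilities_by_id, variant, _facility_ratios=ratios, _block_pops=pops
        )
        for bg in block_groups
        if bg.populated
    ]
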