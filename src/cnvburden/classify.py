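"""Partition retained case deletions into the four spectrum classes.

Classes, in precedence order:

1. ``hotspot_recurrent`` — the call covers >= 50% of a known genomic
   rearrangement hotspot critical region (NAHR-mediated recurrent deletion);
2. ``shared_nonhotspot`` — non-hotspot, but overlaps (>= 1 bp) a retained
   control deletion;
3. ``case_only_genic`` — case-only and overlapping >= 1 protein-coding gene;
4. ``case_only_nongenic`` — case-only, no gene touched.

The partition is exhaustive and mutually exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .core import CnvCall, GeneAnnotation, RegionSet, overlap_bp

log = logging.getLogger(__name__)


class DeletionClass(str, Enum):
    HOTSPOT_RECURRENT = "hotspot_recurrent"
    CASE_ONLY_GENIC = "case_only_genic"
    CASE_ONLY_NONGENIC = "case_only_nongenic"
    SHARED_NONHOTSPOT = "shared_nonhotspot"


CLASS_ORDER = [
    DeletionClass.HOTSPOT_RECURRENT,
    DeletionClass.CASE_ONLY_GENIC,
    DeletionClass.CASE_ONLY_NONGENIC,
    DeletionClass.SHARED_NONHOTSPOT,
]


def assign_hotspot(
    call: CnvCall,
    hotspots: RegionSet,
    min_region_fraction: float = 0.50,
) -> Optional[str]:
    """Label a call with the hotspot whose critical region it covers.

    A call qualifies for a hotspot when it covers at least
    ``min_region_fraction`` of the *region's* length (recurrent deletions
    span the whole critical region, so a small incidental overlap does not
    qualify). If several hotspots qualify, the one with the greatest covered
    fraction wins; exact ties resolve to the first in genomic order.
    """
    best: Optional[tuple[float, tuple, str]] = None
    for r in hotspots:
        frac = overlap_bp(call.interval, r.interval) / r.interval.length
        if frac >= min_region_fraction:
            key = (r.interval.chrom.rjust(2, "0"), r.interval.start)
            if best is None or frac > best[0] or (frac == best[0] and key < best[1]):
                best = (frac, key, r.label)
    return None if best is None else best[2]


@dataclass(frozen=True)
class ClassifiedDeletion:
    call: CnvCall
    klass: DeletionClass
    hotspot_label: Optional[str] = None


@dataclass
class SpectrumResult:
    """Class assignments plus the count/percentage summary of the spectrum."""

    assignments: list[ClassifiedDeletion]

    @property
    def counts(self) -> dict[DeletionClass, int]:
        out = {k: 0 for k in CLASS_ORDER}
        for a in self.assignments:
            out[a.klass] += 1
        return out

    @property
    def percentages(self) -> dict[DeletionClass, float]:
        n = len(self.assignments)
        return {k: (100.0 * v / n if n else 0.0) for k, v in self.counts.items()}

    def __len__(self) -> int:
        return len(self.assignments)


def classify_case_deletions(
    case_calls: Sequence[CnvCall],
    control_calls: Sequence[CnvCall],
    annotation: GeneAnnotation,
    hotspots: RegionSet,
    min_region_fraction: float = 0.50,
) -> SpectrumResult:
    """Assign every retained case deletion to exactly one spectrum class.

    ``control_calls`` must already be filtered; an empty control set is
    allowed (the shared class is then empty, with a warning).
    """
    if not control_calls:
        log.warning("control call set empty; shared_nonhotspot class will be empty")
    ctrl_trees: dict[str, IntervalTree] = {}
    for c in control_calls:
        ctrl_trees.setdefault(c.interval.chrom, IntervalTree()).addi(
            c.interval.start, c.interval.end
        )
    assignments = []
    for call in case_calls:
        label = assign_hotspot(call, hotspots, min_region_fraction)
        if label is not None:
            klass = DeletionClass.HOTSPOT_RECURRENT
        else:
            tree = ctrl_trees.get(call.interval.chrom)
            if tree is not None and tree.overlap(call.interval.start, call.interval.end):
                klass = DeletionClass.SHARED_NONHOTSPOT
            elif annotation.genes_overlapping(call.interval):
                klass = DeletionClass.CASE_ONLY_GENIC
            else:
                klass = DeletionClass.CASE_ONLY_NONGENIC
        assignments.append(ClassifiedDeletion(call, klass, label))
    return SpectrumResult(assignments)
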