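"""Sample- and call-level QC defining the large/rare microdeletion analysis set.

A deletion enters the burden analysis iff it passes four gates: size >= 400 kb,
probe support >= 200, cohort-wide carrier frequency < 1% (computed on
single-linkage clusters of calls at >= 50% reciprocal overlap), and <= 10% of
its length inside known CNV-artifact regions. Samples with excessive deletion
counts (> 50 deletions of > 40 kb / > 20 probes) are removed beforehand, a
standard guard against hypervariable or degraded DNA samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    DELETION,
    CnvCall,
    RegionSet,
    SampleRecord,
    reciprocal_overlap,
    union_overlap_bp,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the microdeletion screen.

    Defaults reproduce the standard screen for large, rare, confidently
    called deletions on SNP 6.0-style arrays. Boundary semantics: size and
    probe gates are inclusive (>=); the frequency gate (< 1%) and the
    artifact-overlap gate (> 10% rejected) are strict.
    """

    min_size_kb: float = 400.0
    min_probes: int = 200
    max_cohort_freq: float = 0.01
    max_artifact_overlap: float = 0.10
    sample_max_deletions: int = 50
    sample_del_min_kb: float = 40.0
    sample_del_min_probes: int = 20
    recurrence_min_reciprocal: float = 0.50

    def __post_init__(self):
        if min(self.min_size_kb, self.min_probes, self.sample_max_deletions) <= 0:
            raise ValueError("thresholds must be > 0")
        for f in (self.max_cohort_freq, self.max_artifact_overlap,
                  self.recurrence_min_reciprocal):
            if not 0 < f <= 1:
                raise ValueError("fractions must be in (0, 1]")


@dataclass
class RecurrenceCluster:
    """A single-linkage cluster of mutually overlapping deletion calls."""

    members: list[CnvCall]
    carrier_count: int
    frequency: float


def flag_hypervariable_samples(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    params: FilterParams = FilterParams(),
) -> tuple[set[str], dict[str, int]]:
    """Identify samples with excessive autosomal deletion counts.

    A sample is excluded iff its number of deletions with size strictly
    > ``sample_del_min_kb`` and probes strictly > ``sample_del_min_probes``
    exceeds ``sample_max_deletions`` (strict). Returns the excluded ids and
    the per-sample qualifying counts for the run log.
    """
    known = {s.sample_id for s in samples}
    counts: dict[str, int] = {}
    for c in calls:
        if c.sample_id not in known:
            raise ValueError(f"call sample {c.sample_id!r} absent from sample table")
        if (
            c.state == DELETION
            and c.size_kb > params.sample_del_min_kb
            and c.probe_count > params.sample_del_min_probes
        ):
            counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    excluded = {sid for sid, n in counts.items() if n > params.sample_max_deletions}
    if excluded:
        log.info("excluded %d hypervariable sample(s)", len(excluded))
    return excluded, counts


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_recurrence(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    params: FilterParams = FilterParams(),
) -> list[RecurrenceCluster]:
    """Group deletion calls into recurrence clusters and compute frequencies.

    Two calls are linked when their reciprocal overlap is >=
    ``recurrence_min_reciprocal`` in both directions; clusters are the
    connected components (single linkage). Frequency is the number of
    distinct carriers in a cluster divided by the total sample count
    (cases + controls), regardless of whether those samples carry calls.
    """
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("empty sample table")
    idx = sorted(
        range(len(calls)),
        key=lambda i: (calls[i].interval.chrom, calls[i].interval.start),
    )
    uf = _UnionFind(len(calls))
    # sweep: within a chromosome only calls whose starts precede this end can overlap
    active: list[int] = []
    cur_chrom = None
    for i in idx:
        ci = calls[i].interval
        if ci.chrom != cur_chrom:
            active, cur_chrom = [], ci.chrom
        active = [j for j in active if calls[j].interval.end > ci.start]
        for j in active:
            fa, fb = reciprocal_overlap(ci, calls[j].interval)
            if min(fa, fb) >= params.recurrence_min_reciprocal:
                uf.union(i, j)
        active.append(i)
    groups: dict[int, list[int]] = {}
    for i in range(len(calls)):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for members_idx in groups.values():
        members = [calls[i] for i in sorted(members_idx)]
        carriers = len({c.sample_id for c in members})
        clusters.append(RecurrenceCluster(members, carriers, carriers / n_samples))
    clusters.sort(key=lambda cl: (cl.members[0].interval.chrom,
                                  cl.members[0].interval.start))
    return clusters


@dataclass
class FilterTally:
    """Per-gate rejection counts; each call is charged to its first failing gate."""

    state: int = 0
    size: int = 0
    probes: int = 0
    frequency: int = 0
    artifact: int = 0

    def total(self) -> int:
        return self.state + self.size + self.probes + self.frequency + self.artifact

    def as_dict(self) -> dict[str, int]:
        return {
            "state": self.state, "size": self.size, "probes": self.probes,
            "frequency": self.frequency, "artifact": self.artifact,
        }


def apply_deletion_filters(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    regions_artifact: Optional[RegionSet],
    params: FilterParams = FilterParams(),
) -> tuple[list[CnvCall], FilterTally]:
    """Apply the size / probes / frequency / artifact gates.

    The retained set is the conjunction of all gates (order-independent);
    the tally attributes each rejected call to the first failing gate in the
    fixed order state -> size -> probes -> frequency -> artifact. Input
    order of retained calls is preserved.
    """
    tally = FilterTally()
    artifact_ivs = regions_artifact.intervals() if regions_artifact else []
    if regions_artifact is not None and len(artifact_ivs) == 0:
        log.warning("artifact region set is empty; artifact filter skipped")

    deletions = [c for c in calls if c.state == DELETION]
    freq: dict[int, float] = {}
    if deletions:
        clusters = cluster_recurrence(deletions, samples, params)
        by_id = {id(c): cl.frequency for cl in clusters for c in cl.members}
        freq = by_id

    retained: list[CnvCall] = []
    for c in calls:
        if c.state != DELETION:
            tally.state += 1
            continue
        if c.size_kb < params.min_size_kb:
            tally.size += 1
            continue
        if c.probe_count < params.min_probes:
            tally.probes += 1
            continue
        if freq[id(c)] >= params.max_cohort_freq:
            tally.frequency += 1
            continue
        if artifact_ivs:
            frac = union_overlap_bp(c.interval, artifact_ivs) / c.interval.length
            if frac > params.max_artifact_overlap:
                tally.artifact += 1
                continue
        retained.append(c)
    return retained, tally
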