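"""Domain types and interval algebra for microdeletion burden analysis.

All genomic coordinates are held internally as 0-based half-open intervals
on autosomes ("1".."22"); readers normalise from the declared input dialect
(see :mod:`cnvburden.io`). Lengths are therefore simply ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from intervaltree import IntervalTree

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

DELETION = "deletion"
DUPLICATION = "duplication"
OTHER = "other"

#: aliases accepted in CNV table ``state`` columns, incl. PLINK copy-number codes
STATE_ALIASES = {
    "del": DELETION, "deletion": DELETION, "loss": DELETION, "0": DELETION,
    "1": DELETION,
    "dup": DUPLICATION, "duplication": DUPLICATION, "gain": DUPLICATION,
    "3": DUPLICATION, "4": DUPLICATION,
}


class FormatError(ValueError):
    """A file does not conform to its declared format (e.g. missing column)."""


class RecordError(ValueError):
    """A single record violates an invariant; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def normalize_chrom(chrom: str) -> str:
    """Strip any ``chr`` prefix; chromosome labels are bare ("1".."22", "X"...)."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a single chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if not self.start < self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap expressed as a fraction of each interval's length.

    Returns ``(fraction_of_a, fraction_of_b)``, both in [0, 1]. Two calls are
    conventionally treated as the same variant when both fractions reach a
    threshold (50% in the recurrence filter).
    """
    ov = overlap_bp(a, b)
    return ov / a.length, ov / b.length


def union_overlap_bp(interval: GenomicInterval, others: Sequence[GenomicInterval]) -> int:
    """Base pairs of ``interval`` covered by the union of ``others``.

    Used for the artifact-region filter, where several artifact regions may
    tile one call and double counting must be avoided.
    """
    segs = sorted(
        (max(interval.start, o.start), min(interval.end, o.end))
        for o in others
        if o.chrom == interval.chrom and o.start < interval.end and o.end > interval.start
    )
    total, cur_s, cur_e = 0, None, None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


@dataclass(frozen=True)
class CnvCall:
    """One copy-number call in one individual.

    Only ``state == "deletion"`` enters the burden analysis; duplications are
    parsed but excluded downstream.
    """

    sample_id: str
    interval: GenomicInterval
    probe_count: int
    state: str = DELETION

    def __post_init__(self):
        if self.probe_count < 0:
            raise ValueError("probe_count must be >= 0")

    @property
    def size_kb(self) -> float:
        return self.interval.length / 1000.0


@dataclass(frozen=True)
class SampleRecord:
    """A study participant with cohort label and optional phenotype fields."""

    sample_id: str
    cohort: str  # "case" | "control"
    sex: Optional[str] = None
    syndrome: Optional[str] = None

    def __post_init__(self):
        if self.cohort not in ("case", "control"):
            raise ValueError(f"cohort must be case|control, got {self.cohort!r}")


def cohort_sizes(samples: Sequence[SampleRecord]) -> tuple[int, int]:
    """(N_case, N_control); sample ids must be unique."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in sample table")
    n_case = sum(1 for s in samples if s.cohort == "case")
    return n_case, len(samples) - n_case


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene represented by its largest-transcript span."""

    symbol: str
    span: GenomicInterval
    brain_expressed: bool = False


class GeneAnnotation:
    """Indexed collection of gene models supporting fast interval queries.

    'A deletion affects a gene' means >= 1 bp overlap with the gene's
    largest-transcript span.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.symbol in self._genes:
                raise ValueError(f"duplicate gene symbol {g.symbol!r}")
            if g.span.chrom not in AUTOSOMES:
                raise ValueError(f"gene {g.symbol} not on an autosome: {g.span.chrom}")
            self._genes[g.symbol] = g
            self._trees.setdefault(g.span.chrom, IntervalTree()).addi(
                g.span.start, g.span.end, g.symbol
            )

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._genes

    def __getitem__(self, symbol: str) -> GeneModel:
        return self._genes[symbol]

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self._genes)

    def genes_overlapping(self, interval: GenomicInterval) -> list[str]:
        """Symbols of genes whose span shares >= 1 bp with ``interval``, sorted."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(interval.start, interval.end))

    def brain_expressed_symbols(self) -> frozenset[str]:
        return frozenset(s for s, g in self._genes.items() if g.brain_expressed)


def genes_overlapping(interval: GenomicInterval, annotation: GeneAnnotation) -> list[str]:
    """Functional alias for :meth:`GeneAnnotation.genes_overlapping`."""
    return annotation.genes_overlapping(interval)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. neurodevelopmental-disorder genes)."""

    name: str
    symbols: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.symbols)

    def resolve(self, annotation: GeneAnnotation) -> tuple[frozenset[str], list[str]]:
        """Split symbols into (present-in-annotation, unknown).

        Unknown symbols are reported to the caller, never silently dropped.
        """
        known = frozenset(s for s in self.symbols if s in annotation)
        unknown = sorted(self.symbols - known)
        return known, unknown

    def __or__(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(f"{self.name}|{other.name}", self.symbols | other.symbols)


@dataclass(frozen=True)
class Region:
    """A labelled genomic region, optionally tagged with a candidate gene."""

    label: str
    interval: GenomicInterval
    gene: Optional[str] = None


@dataclass
class RegionSet:
    """A named list of labelled regions (hotspots, artifact regions...)."""

    name: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self):
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate region labels in {self.name!r}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def intervals(self) -> list[GenomicInterval]:
        return [r.interval for r in self.regions]
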