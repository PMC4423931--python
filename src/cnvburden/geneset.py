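"""Gene-set carrier burden, matched control gene sets, and term enrichment.

The carrier statistic asks whether individuals whose deletions hit at least
one gene of a set (e.g. neurodevelopmental-disorder genes) are commoner in
cases than controls. To guard against generic genic burden masquerading as
set-specific signal, matched control sets are sampled from the annotation
after excluding the analysis sets and genes in rearrangement-hotspot or
artifact regions. Overrepresentation of deleted genes against term libraries
uses the hypergeometric upper tail with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import assign_hotspot
from .core import (
    CnvCall,
    GeneAnnotation,
    GeneSet,
    RegionSet,
    SampleRecord,
    overlap_bp,
)
from .stats import BurdenResult, burden_test, carrier_table

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentParams:
    """Configuration of the gene-set layer.

    ``random_set_size`` / ``nonbrain_set_size`` default to the sizes of the
    two customary control assemblies (3,256 random autosomal genes; 3,837
    genes not expressed in brain). The seed is mandatory: control-set
    sampling must be reproducible.
    """

    random_set_size: int = 3256
    nonbrain_set_size: int = 3837
    exclusion_sets: tuple[str, ...] = ()
    rng_seed: int = 0
    fdr_threshold: float = 0.05
    min_term_genes: int = 3

    def __post_init__(self):
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0,1)")


def set_predicate(gene_set_symbols: frozenset[str], annotation: GeneAnnotation):
    """Predicate: call overlaps >= 1 gene of the (resolved) set."""

    def pred(call: CnvCall) -> bool:
        return any(
            s in gene_set_symbols for s in annotation.genes_overlapping(call.interval)
        )

    return pred


def carrier_burden_by_set(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    annotation: GeneAnnotation,
    gene_set: GeneSet,
) -> BurdenResult:
    """Carrier burden for deletions hitting >= 1 gene of ``gene_set``.

    Unresolvable symbols are logged, not dropped silently; an empty set
    after resolution is an error.
    """
    resolved, unknown = gene_set.resolve(annotation)
    if unknown:
        log.warning(
            "gene set %r: %d symbol(s) not in annotation: %s%s",
            gene_set.name, len(unknown), ", ".join(unknown[:5]),
            "..." if len(unknown) > 5 else "",
        )
    if not resolved:
        raise ValueError(f"gene set {gene_set.name!r} empty after resolution")
    table = carrier_table(calls, samples, set_predicate(resolved, annotation))
    return burden_test(table, label=gene_set.name)


def _genes_in_regions(annotation: GeneAnnotation, regions: Optional[RegionSet]) -> set[str]:
    if regions is None:
        return set()
    hit: set[str] = set()
    for r in regions:
        hit.update(annotation.genes_overlapping(r.interval))
    return hit


def sample_control_gene_set(
    annotation: GeneAnnotation,
    size: int,
    exclusions: Sequence[GeneSet] = (),
    rng_seed: int = 0,
    name: str = "control",
    exclude_regions: Sequence[Optional[RegionSet]] = (),
    pool: Optional[frozenset[str]] = None,
) -> GeneSet:
    """Sample a control gene set uniformly without replacement.

    The eligible pool is the annotation (or ``pool``) minus every exclusion
    set and minus genes overlapping any region in ``exclude_regions``
    (hotspots, artifact regions). Reproducible given ``rng_seed``.
    """
    eligible = set(pool if pool is not None else annotation.symbols)
    for ex in exclusions:
        eligible -= ex.symbols
    for regs in exclude_regions:
        eligible -= _genes_in_regions(annotation, regs)
    if size > len(eligible):
        raise ValueError(
            f"control-set pool too small: need {size}, have {len(eligible)} "
            f"(deficit {size - len(eligible)})"
        )
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(sorted(eligible), size=size, replace=False)
    return GeneSet(name, frozenset(chosen.tolist()))


def hotspot_excluded_burden(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    annotation: GeneAnnotation,
    nd_set: GeneSet,
    asd_set: GeneSet,
    hotspots: RegionSet,
    min_region_fraction: float = 0.50,
) -> BurdenResult:
    """ND/ASD burden outside the recurrent hotspot deletions.

    The combined set is (ND union ASD) minus every gene overlapped by an
    *observed* hotspot-class deletion (in either cohort); individuals
    carrying a hotspot-class deletion are removed from both cohorts, and the
    burden of the reduced set is computed on the reduced cohorts.
    """
    hotspot_calls = [
        c for c in calls if assign_hotspot(c, hotspots, min_region_fraction) is not None
    ]
    removed_genes: set[str] = set()
    for c in hotspot_calls:
        removed_genes.update(annotation.genes_overlapping(c.interval))
    combined = GeneSet(
        f"{nd_set.name}|{asd_set.name}-nonhotspot",
        (nd_set.symbols | asd_set.symbols) - removed_genes,
    )
    hotspot_carriers = {c.sample_id for c in hotspot_calls}
    reduced_samples = [s for s in samples if s.sample_id not in hotspot_carriers]
    reduced_calls = [c for c in calls if c.sample_id not in hotspot_carriers]
    return carrier_burden_by_set(reduced_calls, reduced_samples, annotation, combined)


@dataclass
class TermEnrichment:
    term: str
    p: float
    p_adj: float
    overlap: tuple[str, ...]
    significant: bool


def overrepresentation_bh(
    deleted_genes: GeneSet,
    library: Sequence[GeneSet],
    background_n: int,
    fdr_threshold: float = 0.05,
    min_term_genes: int = 3,
    control_significant: Optional[set[str]] = None,
) -> list[TermEnrichment]:
    """Hypergeometric term overrepresentation with BH FDR adjustment.

    A term is significant when adjusted p < ``fdr_threshold``, the overlap
    has at least ``min_term_genes`` genes (i.e. more than two), and — when a
    set of terms significant in a control list is supplied — the term is not
    among them.
    """
    if not library:
        raise ValueError("empty term library")
    k_draw = len(deleted_genes.symbols)
    pvals, overlaps = [], []
    for term in library:
        m = len(term.symbols)
        if m > background_n:
            raise ValueError(f"term {term.name!r} larger than background")
        ov = tuple(sorted(deleted_genes.symbols & term.symbols))
        # upper tail: P(X >= |overlap|) for X ~ Hypergeom(N, m, k_draw)
        p = float(sps.hypergeom.sf(len(ov) - 1, background_n, m, k_draw)) if ov else 1.0
        pvals.append(min(1.0, p))
        overlaps.append(ov)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    results = []
    for term, p, pa, ov in zip(library, pvals, p_adj, overlaps):
        sig = (
            pa < fdr_threshold
            and len(ov) >= min_term_genes
            and (control_significant is None or term.name not in control_significant)
        )
        results.append(TermEnrichment(term.name, p, float(pa), ov, sig))
    results.sort(key=lambda r: (r.p_adj, r.term))
    return results
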