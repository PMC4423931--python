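"""Model/Results interface tying the pipeline stages together.

:class:`MicrodeletionBurdenModel` is built from a CNV call set, a sample
table and the annotation resources; ``fit()`` runs sample QC, the
large/rare-deletion filter, spectrum classification and the battery of
carrier-burden comparisons, returning a :class:`BurdenAnalysisResults`
object that carries the estimates, their confidence intervals and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .classify import (
    DeletionClass,
    SpectrumResult,
    assign_hotspot,
    classify_case_deletions,
)
from .core import (
    CnvCall,
    GeneAnnotation,
    GeneSet,
    RegionSet,
    SampleRecord,
    cohort_sizes,
)
from .geneset import (
    EnrichmentParams,
    carrier_burden_by_set,
    hotspot_excluded_burden,
    sample_control_gene_set,
    set_predicate,
)
from .qc import FilterParams, FilterTally, apply_deletion_filters, flag_hypervariable_samples
from .stats import (
    BurdenResult,
    ContingencyTable,
    MannWhitneyResult,
    burden_test,
    carrier_table,
    mann_whitney,
)


class MicrodeletionBurdenModel:
    """Case-control burden model for large, rare autosomal microdeletions.

    Parameters
    ----------
    calls, samples
        Raw CNV calls and the sample/phenotype table.
    annotation
        Gene annotation (largest-transcript spans with brain-expression
        flags); required for genic / gene-set comparisons.
    hotspots, artifacts
        Rearrangement-hotspot critical regions and the CNV-artifact region
        list.
    gene_sets
        Analysis gene sets (e.g. neurodevelopmental and ASD-related lists),
        keyed by name; each gets a burden row.
    filter_params, enrichment_params
        QC thresholds and control-gene-set configuration.
    """

    def __init__(
        self,
        calls: Sequence[CnvCall],
        samples: Sequence[SampleRecord],
        annotation: Optional[GeneAnnotation] = None,
        hotspots: Optional[RegionSet] = None,
        artifacts: Optional[RegionSet] = None,
        gene_sets: Optional[dict[str, GeneSet]] = None,
        filter_params: FilterParams = FilterParams(),
        enrichment_params: EnrichmentParams = EnrichmentParams(),
        min_region_fraction: float = 0.50,
        control_gene_sets: bool = True,
    ):
        self.calls = list(calls)
        self.samples = list(samples)
        self.annotation = annotation
        self.hotspots = hotspots
        self.artifacts = artifacts
        self.gene_sets = dict(gene_sets or {})
        self.filter_params = filter_params
        self.enrichment_params = enrichment_params
        self.min_region_fraction = min_region_fraction
        self.control_gene_sets = control_gene_sets

    @classmethod
    def from_files(
        cls,
        cnv_path,
        sample_path,
        gene_path=None,
        hotspot_path=None,
        artifact_path=None,
        gene_set_paths: Optional[dict[str, str]] = None,
        dialect: str = "1-based",
        **kwargs,
    ) -> "MicrodeletionBurdenModel":
        from . import io as cio

        return cls(
            calls=cio.read_cnv_table(cnv_path, dialect=dialect),
            samples=cio.read_sample_table(sample_path),
            annotation=cio.read_gene_annotation(gene_path) if gene_path else None,
            hotspots=cio.read_region_bed(hotspot_path, "hotspots") if hotspot_path else None,
            artifacts=cio.read_region_bed(artifact_path, "artifacts") if artifact_path else None,
            gene_sets={
                name: cio.read_gene_set(p, name)
                for name, p in (gene_set_paths or {}).items()
            },
            **kwargs,
        )

    def fit(self) -> "BurdenAnalysisResults":
        # sample-level QC
        excluded, per_sample_counts = flag_hypervariable_samples(
            self.calls, self.samples, self.filter_params
        )
        samples = [s for s in self.samples if s.sample_id not in excluded]
        calls = [c for c in self.calls if c.sample_id not in excluded]

        retained, tally = apply_deletion_filters(
            calls, samples, self.artifacts, self.filter_params
        )
        cohort = {s.sample_id: s.cohort for s in samples}
        case_calls = [c for c in retained if cohort[c.sample_id] == "case"]
        control_calls = [c for c in retained if cohort[c.sample_id] == "control"]

        spectrum = None
        if self.annotation is not None and self.hotspots is not None:
            spectrum = classify_case_deletions(
                case_calls, control_calls, self.annotation, self.hotspots,
                self.min_region_fraction,
            )

        burden_rows: dict[str, BurdenResult] = {}
        burden_rows["any"] = burden_test(
            carrier_table(retained, samples, lambda c: True), label="any"
        )
        if self.annotation is not None:
            ann = self.annotation
            burden_rows["refseq_genic"] = burden_test(
                carrier_table(
                    retained, samples,
                    lambda c: bool(ann.genes_overlapping(c.interval)),
                ),
                label="refseq_genic",
            )
            brain = ann.brain_expressed_symbols()
            burden_rows["brain_expressed"] = burden_test(
                carrier_table(retained, samples, set_predicate(brain, ann)),
                label="brain_expressed",
            )
        hotspot_rows: dict[str, BurdenResult] = {}
        if self.hotspots is not None:
            frac = self.min_region_fraction
            hs = self.hotspots
            burden_rows["hotspot"] = burden_test(
                carrier_table(
                    retained, samples,
                    lambda c: assign_hotspot(c, hs, frac) is not None,
                ),
                label="hotspot",
            )
            for region in hs:
                label = region.label
                hotspot_rows[label] = burden_test(
                    carrier_table(
                        retained, samples,
                        lambda c, lab=label: assign_hotspot(c, hs, frac) == lab,
                    ),
                    label=label,
                )
            hotspot_rows["Total"] = burden_rows["hotspot"]

        if self.annotation is not None:
            for name, gs in self.gene_sets.items():
                burden_rows[name] = carrier_burden_by_set(
                    retained, samples, self.annotation, gs
                )
            if self.control_gene_sets:
                self._add_control_set_rows(burden_rows, retained, samples)

        hotspot_excluded = None
        if (
            self.annotation is not None
            and self.hotspots is not None
            and len(self.gene_sets) >= 2
        ):
            sets = list(self.gene_sets.values())
            hotspot_excluded = hotspot_excluded_burden(
                retained, samples, self.annotation, sets[0], sets[1],
                self.hotspots, self.min_region_fraction,
            )

        sizes_case = [c.size_kb for c in case_calls]
        sizes_control = [c.size_kb for c in control_calls]
        size_comparison = (
            mann_whitney(sizes_case, sizes_control)
            if sizes_case and sizes_control
            else None
        )

        return BurdenAnalysisResults(
            model=self,
            samples=samples,
            excluded_samples=excluded,
            per_sample_deletion_counts=per_sample_counts,
            retained_calls=retained,
            filter_tally=tally,
            spectrum=spectrum,
            burden_rows=burden_rows,
            hotspot_rows=hotspot_rows,
            hotspot_excluded=hotspot_excluded,
            size_comparison=size_comparison,
        )

    def _add_control_set_rows(self, burden_rows, retained, samples) -> None:
        ep = self.enrichment_params
        ann = self.annotation
        exclusions = list(self.gene_sets.values())
        exclude_regions = [r for r in (self.hotspots, self.artifacts) if r is not None]
        n_random = min(ep.random_set_size, max(0, len(ann) // 4))
        if n_random > 0:
            try:
                rand_set = sample_control_gene_set(
                    ann, n_random, exclusions, ep.rng_seed, "random_control",
                    exclude_regions,
                )
                burden_rows["random_control"] = carrier_burden_by_set(
                    retained, samples, ann, rand_set
                )
            except ValueError:
                pass
        nonbrain_pool = ann.symbols - ann.brain_expressed_symbols()
        n_nonbrain = min(ep.nonbrain_set_size, max(0, len(nonbrain_pool) // 2))
        if n_nonbrain > 0:
            try:
                nb_set = sample_control_gene_set(
                    ann, n_nonbrain, exclusions, ep.rng_seed + 1, "nonbrain_control",
                    exclude_regions, pool=frozenset(nonbrain_pool),
                )
                burden_rows["nonbrain_control"] = carrier_burden_by_set(
                    retained, samples, ann, nb_set
                )
            except ValueError:
                pass


@dataclass
class BurdenAnalysisResults:
    """Fitted results: filtered call set, spectrum, and all burden comparisons."""

    model: MicrodeletionBurdenModel
    samples: list[SampleRecord]
    excluded_samples: set[str]
    per_sample_deletion_counts: dict[str, int]
    retained_calls: list[CnvCall]
    filter_tally: FilterTally
    spectrum: Optional[SpectrumResult]
    burden_rows: dict[str, BurdenResult]
    hotspot_rows: dict[str, BurdenResult]
    hotspot_excluded: Optional[BurdenResult]
    size_comparison: Optional[MannWhitneyResult]

    @property
    def n_case(self) -> int:
        return cohort_sizes(self.samples)[0]

    @property
    def n_control(self) -> int:
        return cohort_sizes(self.samples)[1]

    def burden_table(self) -> pd.DataFrame:
        from .pipeline import burden_rows_frame

        return burden_rows_frame(self.burden_rows)

    def hotspot_table(self) -> pd.DataFrame:
        from .pipeline import burden_rows_frame

        return burden_rows_frame(self.hotspot_rows)

    def spectrum_table(self) -> pd.DataFrame:
        if self.spectrum is None:
            return pd.DataFrame(columns=["class", "count", "percent"])
        counts, pcts = self.spectrum.counts, self.spectrum.percentages
        return pd.DataFrame(
            [
                {"class": k.value, "count": counts[k], "percent": round(pcts[k], 1)}
                for k in counts
            ]
        )

    def summary(self) -> str:
        """Human-readable analysis summary."""
        from .pipeline import format_or_ci, format_p

        lines = []
        lines.append("Microdeletion burden analysis")
        lines.append("=" * 64)
        lines.append(
            f"Cohorts: {self.n_case} cases / {self.n_control} controls"
            + (f" ({len(self.excluded_samples)} hypervariable sample(s) excluded)"
               if self.excluded_samples else "")
        )
        lines.append(
            f"Retained deletions: {len(self.retained_calls)} "
            f"(rejected by gate: {self.filter_tally.as_dict()})"
        )
        if self.spectrum is not None and len(self.spectrum):
            lines.append("")
            lines.append("Spectrum of case deletions:")
            counts, pcts = self.spectrum.counts, self.spectrum.percentages
            for k, v in counts.items():
                lines.append(f"  {k.value:<22s} {v:>4d}  ({pcts[k]:.1f}%)")
        lines.append("")
        lines.append(
            f"{'comparison':<20s} {'case':>6s} {'ctrl':>6s} {'test':>7s} "
            f"{'P':>10s}  {'OR (95% CI)':<20s} {'AR%':>6s}"
        )
        lines.append("-" * 84)
        for name, r in self.burden_rows.items():
            lines.append(
                f"{name:<20s} {r.table.a:>6d} {r.table.c:>6d} {r.test:>7s} "
                f"{format_p(r.p_two_sided):>10s}  "
                f"{format_or_ci(r.or_point, r.ci_low, r.ci_high):<20s} "
                f"{r.attributable_risk_pct:>6.1f}"
            )
        if self.size_comparison is not None:
            sc = self.size_comparison
            lines.append("")
            lines.append(
                f"Deletion size (kb): case median {sc.median_case:.0f} "
                f"(IQR {sc.iqr_case[0]:.0f}-{sc.iqr_case[1]:.0f}) vs control "
                f"{sc.median_control:.0f} (IQR {sc.iqr_control[0]:.0f}-"
                f"{sc.iqr_control[1]:.0f}); Mann-Whitney P = {sc.p_two_sided:.2e}"
            )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.burden_table().to_csv(out / "burden_table.tsv", sep="\t", index=False)
        self.hotspot_table().to_csv(out / "hotspot_table.tsv", sep="\t", index=False)
        self.spectrum_table().to_csv(out / "spectrum.tsv", sep="\t", index=False)
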