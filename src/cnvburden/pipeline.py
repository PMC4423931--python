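"""Pipeline orchestration, report formatting, and the fixture-bypass mode.

``run_full_analysis`` drives filter -> classify -> burden -> gene-set ->
network from a single config mapping (YAML-friendly), writing report tables
whose layout mirrors the customary burden-analysis presentation: one row per
comparison with carrier counts, test, P, OR with 95% CI, and attributable
risk. A "counts bypass" mode accepts pre-tabulated carrier counts so the
statistics layer can be exercised directly on published tables without the
raw cohort.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .geneset import EnrichmentParams
from .model import BurdenAnalysisResults, MicrodeletionBurdenModel
from .network import build_ppi, seed_connectivity_test
from .qc import FilterParams
from .stats import BurdenResult, ContingencyTable, burden_test

log = logging.getLogger(__name__)


def format_p(p: float) -> str:
    """Scientific notation with 2 decimals of mantissa, e.g. ``1.77E-07``."""
    if p >= 0.001:
        return f"{p:.3g}"
    return f"{p:.2E}"


def format_or(or_point: float) -> str:
    if math.isinf(or_point):
        return "Inf"
    if math.isnan(or_point):
        return "NA"
    return f"{or_point:.2f}"


def format_or_ci(or_point: float, lo: float, hi: float) -> str:
    """``1.91; 1.48-2.46`` style; degenerate tables give e.g. ``Inf; 9.7-Inf``."""

    def b(x: float) -> str:
        if math.isinf(x):
            return "Inf"
        return f"{x:.1f}" if (x >= 10 or math.isinf(or_point) or or_point == 0) else f"{x:.2f}"

    return f"{format_or(or_point)}; {b(lo)}-{b(hi)}"


def burden_rows_frame(rows: dict[str, BurdenResult]) -> pd.DataFrame:
    """Tabulate burden results, one comparison per row."""
    recs = []
    for name, r in rows.items():
        recs.append(
            {
                "comparison": name,
                "case_carriers": r.table.a,
                "case_n": r.table.n_case,
                "control_carriers": r.table.c,
                "control_n": r.table.n_control,
                "carrier_pct_case": round(r.carrier_pct_case, 1),
                "carrier_pct_control": round(r.carrier_pct_control, 1),
                "test": r.test,
                "p_value": format_p(r.p_two_sided),
                "or_ci": format_or_ci(r.or_point, r.ci_low, r.ci_high),
                "attributable_risk_pct": round(r.attributable_risk_pct, 1),
            }
        )
    return pd.DataFrame(
        recs,
        columns=["comparison", "case_carriers", "case_n", "control_carriers",
                 "control_n", "carrier_pct_case", "carrier_pct_control", "test",
                 "p_value", "or_ci", "attributable_risk_pct"],
    )


def format_table1(rows: dict[str, BurdenResult]) -> str:
    """Render the burden table as TSV text (header always present)."""
    return burden_rows_frame(rows).to_csv(sep="\t", index=False)


def burden_from_counts(counts: pd.DataFrame) -> dict[str, BurdenResult]:
    """Fixture-bypass: burden statistics from pre-tabulated carrier counts.

    ``counts`` needs columns ``label a b c d`` (case carriers/non-carriers,
    control carriers/non-carriers) and may force the test with a ``test``
    column (``chi2``/``fisher``).
    """
    rows: dict[str, BurdenResult] = {}
    for rec in counts.itertuples(index=False):
        table = ContingencyTable(int(rec.a), int(rec.b), int(rec.c), int(rec.d))
        forced = getattr(rec, "test", None)
        forced = forced if isinstance(forced, str) and forced else None
        rows[str(rec.label)] = burden_test(table, label=str(rec.label), test=forced)
    return rows


@dataclass
class PipelineConfig:
    """File paths, thresholds and options for a full run."""

    cnv: Optional[str] = None
    samples: Optional[str] = None
    genes: Optional[str] = None
    hotspots: Optional[str] = None
    artifacts: Optional[str] = None
    gene_sets: dict[str, str] = field(default_factory=dict)
    ppi: Optional[str] = None
    network_seeds: Optional[str] = None  # gene list for the connectivity test
    counts_table: Optional[str] = None  # bypass mode
    dialect: str = "1-based"
    out_dir: str = "cnvburden_out"
    rng_seed: int = 0
    n_perm: int = 1000
    filter_params: dict = field(default_factory=dict)
    enrichment_params: dict = field(default_factory=dict)
    min_region_fraction: float = 0.50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def build_filter_params(self) -> FilterParams:
        return FilterParams(**self.filter_params)

    def build_enrichment_params(self) -> EnrichmentParams:
        ep = dict(self.enrichment_params)
        ep.setdefault("rng_seed", self.rng_seed)
        return EnrichmentParams(**ep)


@dataclass
class ReportBundle:
    results: Optional[BurdenAnalysisResults]
    burden_rows: dict[str, BurdenResult]
    network: Optional[dict]
    out_dir: Path


def run_full_analysis(config: PipelineConfig) -> ReportBundle:
    """Run every configured stage and write the report files.

    Writes ``burden_table.tsv``, ``hotspot_table.tsv``, ``spectrum.tsv``,
    optionally ``network.json``, and ``run_log.json`` recording thresholds,
    seeds and the per-filter rejection tally. Any stage failure removes
    partial outputs and re-raises with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "configure"
    try:
        results: Optional[BurdenAnalysisResults] = None
        if config.counts_table:
            stage = "counts-bypass"
            counts = pd.read_csv(config.counts_table, sep="\t")
            burden_rows = burden_from_counts(counts)
        else:
            stage = "load"
            if not (config.cnv and config.samples):
                raise ValueError("cnv and samples paths are required (or counts_table)")
            model = MicrodeletionBurdenModel.from_files(
                config.cnv, config.samples, config.genes, config.hotspots,
                config.artifacts, config.gene_sets, dialect=config.dialect,
                filter_params=config.build_filter_params(),
                enrichment_params=config.build_enrichment_params(),
                min_region_fraction=config.min_region_fraction,
            )
            stage = "fit"
            results = model.fit()
            burden_rows = results.burden_rows

        stage = "report"
        p = out / "burden_table.tsv"
        burden_rows_frame(burden_rows).to_csv(p, sep="\t", index=False)
        written.append(p)
        if results is not None:
            p = out / "hotspot_table.tsv"
            results.hotspot_table().to_csv(p, sep="\t", index=False)
            written.append(p)
            p = out / "spectrum.tsv"
            results.spectrum_table().to_csv(p, sep="\t", index=False)
            written.append(p)

        network = None
        if config.ppi and config.network_seeds:
            stage = "network"
            graph = build_ppi(config.ppi)
            with open(config.network_seeds) as fh:
                seeds = [s.strip() for s in fh if s.strip() and not s.startswith("#")]
            res = seed_connectivity_test(
                graph, seeds, n_perm=config.n_perm, rng_seed=config.rng_seed
            )
            network = {
                "n_seeds": len(res.seed_genes),
                "direct_edge_count": res.direct_edge_count,
                "p_network": res.p_network,
                "n_perm": res.n_perm,
                "per_gene_p": dict(sorted(res.per_gene_p.items())),
                "dropped_seeds": sorted(res.dropped_seeds),
            }
            p = out / "network.json"
            p.write_text(json.dumps(network, indent=2))
            written.append(p)

        stage = "log"
        run_log = {
            "rng_seed": config.rng_seed,
            "dialect": config.dialect,
            "filter_params": asdict(config.build_filter_params()),
            "enrichment_params": asdict(config.build_enrichment_params()),
            "min_region_fraction": config.min_region_fraction,
        }
        if results is not None:
            run_log["filter_tally"] = results.filter_tally.as_dict()
            run_log["excluded_samples"] = sorted(results.excluded_samples)
            run_log["n_case"] = results.n_case
            run_log["n_control"] = results.n_control
        p = out / "run_log.json"
        p.write_text(json.dumps(run_log, indent=2))
        written.append(p)
        return ReportBundle(results, burden_rows, network, out)
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
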