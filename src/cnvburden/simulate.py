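"""Synthetic case-control CNV cohorts with known ground truth.

The generator emulates the conditions of a genome-wide microdeletion screen
in a common-epilepsy case-control design: ~1,366 cases vs ~5,234 controls;
recurrent deletions at seven rearrangement hotspots with per-cohort carrier
rates matching the observed ones; gene-set-targeted deletions planted at a
chosen carrier odds ratio; an equal-rate background of rare qualifying
deletions; benign common deletion polymorphisms (frequency >= 1%) that the
frequency filter must remove; and sub-size / low-probe / artifact-region /
duplication decoys that the other QC gates must remove. Deletion sizes are
log-normal (median 650 kb, between the reported case and control medians);
probe counts are ~0.6 per kb with Poisson noise, the SNP 6.0 array's
approximate marker density.

The effect model is carrier-probability based: for a planted odds ratio OR
and control carrier rate r, cases carry with probability
r*OR / (1 - r + r*OR), so the expected carrier 2x2 table has odds ratio OR.

Every planted deletion is recorded in a truth table with its category and
whether it should survive the QC filter; planted qualifying deletions avoid
artifact regions so truth labels and filter outcomes cannot disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DELETION,
    DUPLICATION,
    CnvCall,
    GeneAnnotation,
    GeneModel,
    GeneSet,
    GenomicInterval,
    Region,
    RegionSet,
    SampleRecord,
    union_overlap_bp,
)
from . import io as cio

#: GRCh37/hg19 autosome lengths, bp
HG19_AUTOSOMES: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}


@dataclass(frozen=True)
class HotspotDef:
    """A rearrangement hotspot with per-cohort carrier rates."""

    label: str
    chrom: str
    start: int
    end: int
    case_rate: float
    control_rate: float
    gene: Optional[str] = None


def default_hotspot_defs(n_case: int = 1366, n_control: int = 5234) -> tuple[HotspotDef, ...]:
    """The seven canonical hotspots with carrier rates from the observed counts."""
    rows = [
        ("1q21.1", "1", 146_500_000, 147_500_000, 1, 1, "GJA8"),
        ("15q11.2", "15", 22_800_000, 23_100_000, 13, 14, "CYFIP1"),
        ("15q13.3", "15", 31_300_000, 32_500_000, 11, 0, "CHRNA7"),
        ("16p13.11", "16", 15_000_000, 16_300_000, 6, 2, "NDE1"),
        ("16p12", "16", 21_900_000, 22_500_000, 3, 2, None),
        ("16p11.2", "16", 29_600_000, 30_200_000, 1, 1, "PRRT2"),
        ("22q11.2", "22", 18_800_000, 21_600_000, 3, 0, "SNAP29"),
    ]
    return tuple(
        HotspotDef(label, c, s, e, k_case / n_case, k_ctrl / n_control, gene)
        for label, c, s, e, k_case, k_ctrl, gene in rows
    )


@dataclass(frozen=True)
class SetDef:
    """A planted risk gene set: size, control carrier rate and carrier OR."""

    name: str
    gene_count: int
    case_or: float
    control_rate: float


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of the synthetic cohort; seed is mandatory."""

    rng_seed: int
    n_case: int = 1366
    n_control: int = 5234
    genome: tuple[tuple[str, int], ...] = tuple(HG19_AUTOSOMES.items())
    n_genes: int = 18299
    brain_expressed_frac: float = 8878 / 18299
    hotspot_defs: tuple[HotspotDef, ...] = field(default_factory=default_hotspot_defs)
    #: None -> two risk sets sized proportionally to n_genes (1,547 and 1,669
    #: out of 18,299 at full scale) with ORs 4.6 / 4.1 and the observed
    #: control carrier rates
    set_defs: Optional[tuple[SetDef, ...]] = None
    baseline_carrier_rate_control: float = 0.03
    baseline_carrier_rate_case: Optional[float] = None  # None -> same as control
    size_lognormal_median_kb: float = 650.0
    size_lognormal_sigma: float = 0.55
    probe_density_per_kb: float = 0.6
    common_polymorphism_freq: float = 0.05
    n_common_polymorphisms: int = 3
    noise_small_deletion_rate: float = 0.3
    lowprobe_decoy_rate: float = 0.03
    artifact_decoy_rate: float = 0.02
    duplication_rate: float = 0.05
    n_artifact_regions: int = 12
    ppi_n_nodes: int = 500
    ppi_mean_degree: float = 6.0
    ppi_set_edge_prob: float = 0.15

    def __post_init__(self):
        for r in (self.baseline_carrier_rate_control, self.common_polymorphism_freq,
                  self.brain_expressed_frac):
            if not 0 <= r <= 1:
                raise ValueError("rates/fractions must be in [0,1]")
        if self.set_defs is None:
            object.__setattr__(
                self, "set_defs",
                (
                    SetDef("nd_like", max(2, round(1547 / 18299 * self.n_genes)),
                           4.6, 51 / 5234),
                    SetDef("asd_like", max(2, round(1669 / 18299 * self.n_genes)),
                           4.1, 43 / 5234),
                ),
            )
        if any(s.case_or <= 0 for s in self.set_defs):
            raise ValueError("planted ORs must be > 0")


def case_rate_for_or(control_rate: float, odds_ratio: float) -> float:
    """Carrier probability in cases giving the requested carrier OR."""
    r = control_rate
    return r * odds_ratio / (1 - r + r * odds_ratio)


@dataclass
class AnnotationBundle:
    """Annotation-side outputs of the generator, shared across cohorts."""

    params: SimulationParams
    annotation: GeneAnnotation
    hotspots: RegionSet
    artifacts: RegionSet
    gene_sets: dict[str, GeneSet]
    ppi_edges: list[tuple[str, str]]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_gene_annotation(self.annotation, out / "genes.tsv")
        cio.write_region_bed(self.hotspots, out / "hotspots.bed")
        cio.write_region_bed(self.artifacts, out / "artifacts.bed")
        for name, gs in sorted(self.gene_sets.items()):
            cio.write_gene_set(gs, out / f"geneset_{name}.txt")
        cio.write_ppi_edges(self.ppi_edges, out / "ppi_edges.tsv")


def _annotation_rng(params: SimulationParams) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.rng_seed, 0]))


def _cohort_rng(params: SimulationParams) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.rng_seed, 1]))


def simulate_annotation(params: SimulationParams) -> AnnotationBundle:
    """Generate genes, hotspot/artifact regions, gene sets and a PPI graph.

    Gene spans are non-overlapping by construction: each chromosome is cut
    into per-gene slots (count proportional to chromosome length) and one
    gene is placed uniformly inside its slot.
    """
    rng = _annotation_rng(params)
    genome = dict(params.genome)
    total = sum(genome.values())
    # largest-remainder apportionment of genes to chromosomes
    quotas = {c: params.n_genes * l / total for c, l in genome.items()}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = params.n_genes - sum(counts.values())
    for c in sorted(genome, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    if any(counts[c] > genome[c] // 2000 for c in genome):
        raise ValueError("genome too small for n_genes")

    genes: list[GeneModel] = []
    gid = 0
    for chrom in genome:
        k = counts[chrom]
        if k == 0:
            continue
        slot = genome[chrom] // k
        lengths = np.exp(rng.normal(math.log(20_000), 1.0, size=k))
        lengths = np.clip(lengths, 1_000, 0.8 * slot).astype(np.int64)
        offsets = (rng.random(k) * (slot - lengths)).astype(np.int64)
        for i in range(k):
            start = i * slot + int(offsets[i])
            genes.append(
                GeneModel(
                    symbol=f"G{gid:06d}",
                    span=GenomicInterval(chrom, start, start + int(lengths[i])),
                )
            )
            gid += 1
    # exactly round(frac * n) genes flagged brain-expressed
    n_brain = int(round(params.brain_expressed_frac * len(genes)))
    brain_idx = set(rng.choice(len(genes), size=n_brain, replace=False).tolist())
    genes = [
        GeneModel(g.symbol, g.span, brain_expressed=(i in brain_idx))
        for i, g in enumerate(genes)
    ]
    annotation = GeneAnnotation(genes)

    hotspots = RegionSet(
        "hotspots",
        [
            Region(h.label, GenomicInterval(h.chrom, h.start, h.end), h.gene)
            for h in params.hotspot_defs
        ],
    )

    # artifact regions: fixed-size regions at deterministic positions away from
    # hotspots (placed at 60-70% of each chromosome arm, round-robin)
    chroms = list(genome)
    art_regions = []
    for i in range(params.n_artifact_regions):
        chrom = chroms[i % len(chroms)]
        pos = int(genome[chrom] * (0.60 + 0.01 * (i // len(chroms))))
        art_regions.append(
            Region(f"artifact_{i + 1}", GenomicInterval(chrom, pos, pos + 1_000_000))
        )
    artifacts = RegionSet("artifacts", art_regions)

    symbols = sorted(annotation.symbols)
    gene_sets: dict[str, GeneSet] = {}
    taken: set[str] = set()
    for sd in params.set_defs:
        if sd.gene_count > len(symbols) - len(taken):
            raise ValueError(f"set {sd.name!r}: not enough genes left to sample")
        pool = sorted(set(symbols) - taken)
        chosen = rng.choice(pool, size=sd.gene_count, replace=False)
        gene_sets[sd.name] = GeneSet(sd.name, frozenset(chosen.tolist()))
        taken.update(chosen.tolist())

    # PPI: background random graph plus elevated connectivity inside the first set
    n_nodes = min(params.ppi_n_nodes, len(symbols))
    nodes = sorted(rng.choice(symbols, size=n_nodes, replace=False).tolist())
    p_bg = min(1.0, params.ppi_mean_degree / max(1, n_nodes - 1))
    edges: set[tuple[str, str]] = set()
    node_arr = np.array(nodes)
    iu, ju = np.triu_indices(n_nodes, k=1)
    mask = rng.random(len(iu)) < p_bg
    for a, b in zip(node_arr[iu[mask]], node_arr[ju[mask]]):
        edges.add((a, b))
    if params.set_defs and params.ppi_set_edge_prob > 0:
        first = sorted(gene_sets[params.set_defs[0].name].symbols & set(nodes))
        if len(first) >= 2:
            fi, fj = np.triu_indices(len(first), k=1)
            fmask = rng.random(len(fi)) < params.ppi_set_edge_prob
            farr = np.array(first)
            for a, b in zip(farr[fi[fmask]], farr[fj[fmask]]):
                edges.add((a, b))
    ppi_edges = sorted(edges)

    return AnnotationBundle(params, annotation, hotspots, artifacts, gene_sets, ppi_edges)


@dataclass
class CohortData:
    """Cohort-side outputs: calls, samples, and the planted-truth table."""

    params: SimulationParams
    calls: list[CnvCall]
    samples: list[SampleRecord]
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_cnv_table(self.calls, out / "calls.tsv")
        cio.write_sample_table(self.samples, out / "samples.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


_SYNDROMES = ["CAE", "JAE", "GAE", "JME", "EGMA", "EGTCS"]
_SYNDROME_P = np.array([398, 191, 9, 540, 94, 134], dtype=float)
_SYNDROME_P /= _SYNDROME_P.sum()


def _draw_sizes(rng, k, params: SimulationParams, min_bp: Optional[int] = None) -> np.ndarray:
    mu = math.log(params.size_lognormal_median_kb * 1000)
    sizes = np.exp(rng.normal(mu, params.size_lognormal_sigma, size=k))
    if min_bp is not None:
        for _ in range(200):
            low = sizes < min_bp
            if not low.any():
                break
            sizes[low] = np.exp(rng.normal(mu, params.size_lognormal_sigma, size=int(low.sum())))
        sizes = np.maximum(sizes, min_bp)
    return sizes.astype(np.int64)


def _draw_probes(rng, sizes_bp: np.ndarray, params: SimulationParams,
                 min_probes: Optional[int] = None) -> np.ndarray:
    lam = params.probe_density_per_kb * sizes_bp / 1000.0
    probes = rng.poisson(lam)
    if min_probes is not None:
        # truncated Poisson: planted qualifying deletions must clear the QC floor
        for _ in range(200):
            low = probes < min_probes
            if not low.any():
                break
            probes[low] = rng.poisson(lam[low])
        probes = np.maximum(probes, min_probes)
    return probes.astype(np.int64)


def simulate_cohort(
    params: SimulationParams,
    bundle: AnnotationBundle,
    cohort_seed: Optional[int] = None,
) -> CohortData:
    """Draw a case-control cohort of CNV calls against a generated annotation.

    ``cohort_seed`` overrides the cohort-side stream so that replicate
    cohorts can be drawn against a single annotation bundle; by default the
    stream is derived from ``params.rng_seed`` and the bundle must have been
    generated with the same seed.
    """
    if bundle.params.rng_seed != params.rng_seed:
        raise ValueError("annotation bundle was generated with a different seed")
    rng = (
        _cohort_rng(params)
        if cohort_seed is None
        else np.random.default_rng(np.random.SeedSequence([cohort_seed, 1]))
    )
    genome = dict(params.genome)
    chroms = list(genome)
    chrom_p = np.array([genome[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()
    artifact_ivs = bundle.artifacts.intervals()

    n_case, n_control = params.n_case, params.n_control
    n = n_case + n_control
    width = len(str(n))
    sample_ids = [f"case_{i + 1:0{width}d}" for i in range(n_case)] + [
        f"ctrl_{i + 1:0{width}d}" for i in range(n_control)
    ]
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_case] = True
    sexes = np.where(
        rng.random(n) < np.where(is_case, 853 / 1366, 2559 / 5234), "F", "M"
    )
    syndromes = rng.choice(_SYNDROMES, size=n, p=_SYNDROME_P)
    samples = [
        SampleRecord(
            sample_id=sample_ids[i],
            cohort="case" if is_case[i] else "control",
            sex=str(sexes[i]),
            syndrome=str(syndromes[i]) if is_case[i] else None,
        )
        for i in range(n)
    ]

    calls: list[CnvCall] = []
    truth_rows: list[dict] = []

    def emit(i: int, category: str, interval: GenomicInterval, probes: int,
             state: str, qualifies: bool) -> None:
        calls.append(CnvCall(sample_ids[i], interval, int(probes), state))
        truth_rows.append(
            {
                "sample_id": sample_ids[i],
                "cohort": "case" if is_case[i] else "control",
                "category": category,
                "chrom": interval.chrom,
                "start": interval.start,
                "end": interval.end,
                "probes": int(probes),
                "state": state,
                "qualifies": qualifies,
            }
        )

    def _avoids_artifacts(iv: GenomicInterval) -> bool:
        return union_overlap_bp(iv, artifact_ivs) / iv.length <= 0.05

    def _qualifying_interval(chrom: str, center: int, size: int) -> GenomicInterval:
        L = genome[chrom]
        size = min(size, L - 1)
        start = int(np.clip(center - size // 2, 0, L - size))
        return GenomicInterval(chrom, start, start + size)

    # 1) hotspot deletions: span the full critical region with small flanks
    for h in params.hotspot_defs:
        rates = np.where(is_case, h.case_rate, h.control_rate)
        carriers = np.flatnonzero(rng.random(n) < rates)
        # small critical regions (e.g. 300 kb) still yield >= 400 kb calls:
        # real recurrent deletions extend into the flanking segmental duplications
        extra = max(0, 410_000 - (h.end - h.start))
        for i in carriers:
            pad_l = extra // 2 + int(rng.integers(0, 50_000))
            pad_r = extra - extra // 2 + int(rng.integers(0, 50_000))
            iv = GenomicInterval(h.chrom, max(0, h.start - pad_l), h.end + pad_r)
            probes = _draw_probes(rng, np.array([iv.length]), params, min_probes=200)[0]
            emit(i, f"hotspot:{h.label}", iv, probes, DELETION, True)

    # 2) gene-set-targeted deletions at the planted carrier OR
    for sd in params.set_defs:
        case_rate = case_rate_for_or(sd.control_rate, sd.case_or)
        rates = np.where(is_case, case_rate, sd.control_rate)
        carriers = np.flatnonzero(rng.random(n) < rates)
        set_symbols = sorted(bundle.gene_sets[sd.name].symbols)
        for i in carriers:
            for _ in range(50):
                sym = set_symbols[int(rng.integers(0, len(set_symbols)))]
                g = bundle.annotation[sym].span
                size = int(_draw_sizes(rng, 1, params, min_bp=410_000)[0])
                center = int(rng.integers(g.start, g.end))
                iv = _qualifying_interval(g.chrom, center, size)
                if _avoids_artifacts(iv):
                    break
            probes = _draw_probes(rng, np.array([iv.length]), params, min_probes=200)[0]
            emit(i, f"set:{sd.name}", iv, probes, DELETION, True)

    # 3) background qualifying deletions, equal-rate unless configured otherwise
    case_bg = (
        params.baseline_carrier_rate_case
        if params.baseline_carrier_rate_case is not None
        else params.baseline_carrier_rate_control
    )
    rates = np.where(is_case, case_bg, params.baseline_carrier_rate_control)
    carriers = np.flatnonzero(rng.random(n) < rates)
    for i in carriers:
        for _ in range(50):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            size = int(_draw_sizes(rng, 1, params, min_bp=410_000)[0])
            center = int(rng.integers(0, genome[chrom]))
            iv = _qualifying_interval(chrom, center, size)
            if _avoids_artifacts(iv):
                break
        probes = _draw_probes(rng, np.array([iv.length]), params, min_probes=200)[0]
        emit(i, "background", iv, probes, DELETION, True)

    # 4) benign common polymorphisms: identical locus across carriers -> the
    # frequency filter must remove every one of them
    poly_loci = []
    for j in range(params.n_common_polymorphisms):
        chrom = chroms[(5 * j + 3) % len(chroms)]
        pos = int(genome[chrom] * 0.25) + j * 2_000_000
        poly_loci.append(GenomicInterval(chrom, pos, pos + 500_000))
    for j, locus in enumerate(poly_loci):
        carriers = np.flatnonzero(rng.random(n) < params.common_polymorphism_freq)
        for i in carriers:
            probes = _draw_probes(rng, np.array([locus.length]), params, min_probes=200)[0]
            emit(i, f"common_poly_{j + 1}", locus, probes, DELETION, False)

    # 5) decoys: sub-size, low-probe, artifact-region, duplication
    k_small = rng.poisson(params.noise_small_deletion_rate, size=n)
    for i in np.flatnonzero(k_small):
        for _ in range(int(k_small[i])):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            size = int(rng.integers(40_000, 390_000))
            start = int(rng.integers(0, genome[chrom] - size))
            iv = GenomicInterval(chrom, start, start + size)
            probes = _draw_probes(rng, np.array([iv.length]), params)[0]
            emit(i, "decoy_small", iv, probes, DELETION, False)
    for i in np.flatnonzero(rng.random(n) < params.lowprobe_decoy_rate):
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
        size = int(_draw_sizes(rng, 1, params, min_bp=410_000)[0])
        start = int(rng.integers(0, genome[chrom] - size))
        probes = int(rng.integers(20, 199))
        emit(i, "decoy_lowprobe", GenomicInterval(chrom, start, start + size),
             probes, DELETION, False)
    for i in np.flatnonzero(rng.random(n) < params.artifact_decoy_rate):
        region = artifact_ivs[int(rng.integers(0, len(artifact_ivs)))]
        size = 450_000
        start = int(rng.integers(region.start, region.end - size))
        iv = GenomicInterval(region.chrom, start, start + size)
        probes = _draw_probes(rng, np.array([iv.length]), params, min_probes=200)[0]
        emit(i, "decoy_artifact", iv, probes, DELETION, False)
    for i in np.flatnonzero(rng.random(n) < params.duplication_rate):
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
        size = int(_draw_sizes(rng, 1, params, min_bp=410_000)[0])
        start = int(rng.integers(0, genome[chrom] - size))
        probes = _draw_probes(rng, np.array([size]), params, min_probes=200)[0]
        emit(i, "decoy_duplication", GenomicInterval(chrom, start, start + size),
             probes, DUPLICATION, False)

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "cohort", "category", "chrom", "start", "end",
                 "probes", "state", "qualifies"],
    )
    return CohortData(params, calls, samples, truth)


def simulate_study(params: SimulationParams) -> tuple[AnnotationBundle, CohortData]:
    """Convenience wrapper: annotation bundle plus one cohort, same seed lineage."""
    bundle = simulate_annotation(params)
    return bundle, simulate_cohort(params, bundle)
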