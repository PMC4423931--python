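import pytest

from cnvburden.core import (
    GeneAnnotation,
    GeneModel,
    GenomicInterval,
    Region,
    RegionSet,
    SampleRecord,
)
from cnvburden.simulate import SimulationParams, simulate_study


@pytest.fixture(scope="session")
def toy_annotation() -> GeneAnnotation:
    """A handful of genes, including the PLCB1 span used in worked examples."""
    return GeneAnnotation(
        [
            GeneModel("GENE_A", GenomicInterval("1", 1_000_000, 1_050_000), True),
            GeneModel("GENE_B", GenomicInterval("1", 2_000_000, 2_080_000), False),
            GeneModel("GENE_C", GenomicInterval("2", 500_000, 620_000), True),
            GeneModel("PLCB1", GenomicInterval("20", 8_112_911, 8_865_546), True),
        ]
    )


@pytest.fixture(scope="session")
def hotspot_regions() -> RegionSet:
    """The seven rearrangement-hotspot critical regions (hg19, Mb coordinates)."""
    rows = [
        ("1q21.1", "1", 146_500_000, 147_500_000),
        ("15q11.2", "15", 22_800_000, 23_100_000),
        ("15q13.3", "15", 31_300_000, 32_500_000),
        ("16p13.11", "16", 15_000_000, 16_300_000),
        ("16p12", "16", 21_900_000, 22_500_000),
        ("16p11.2", "16", 29_600_000, 30_200_000),
        ("22q11.2", "22", 18_800_000, 21_600_000),
    ]
    return RegionSet(
        "hotspots", [Region(lab, GenomicInterval(c, s, e)) for lab, c, s, e in rows]
    )


def make_samples(n_case: int, n_control: int) -> list[SampleRecord]:
    return [
        SampleRecord(f"case_{i}", "case") for i in range(n_case)
    ] + [SampleRecord(f"ctrl_{i}", "control") for i in range(n_control)]


@pytest.fixture(scope="session")
def small_study():
    """One small but complete synthetic study shared across tests."""
    params = SimulationParams(
        rng_seed=11, n_case=400, n_control=1600, n_genes=600,
        noise_small_deletion_rate=0.1,
    )
    bundle, cohort = simulate_study(params)
    return params, bundle, cohort
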