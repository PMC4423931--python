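"""Sample QC and the large/rare deletion filter."""

import random

import pytest

from cnvburden.core import CnvCall, GenomicInterval, Region, RegionSet, reciprocal_overlap
from cnvburden.qc import (
    FilterParams,
    apply_deletion_filters,
    cluster_recurrence,
    flag_hypervariable_samples,
)

from conftest import make_samples


def dele(sample, chrom, start, end, probes=300, state="deletion"):
    return CnvCall(sample, GenomicInterval(chrom, start, end), probes, state)


class TestHypervariableSamples:
    @pytest.mark.parametrize("n_dels,excluded", [(51, True), (50, False)])
    def test_strict_count_boundary(self, n_dels, excluded):
        # > 50 qualifying deletions excludes; exactly 50 does not
        samples = make_samples(1, 0)
        calls = [
            dele("case_0", "1", i * 200_000, i * 200_000 + 50_000, probes=30)
            for i in range(n_dels)
        ]
        exc, counts = flag_hypervariable_samples(calls, samples)
        assert (("case_0" in exc) is excluded)
        assert counts["case_0"] == n_dels

    def test_small_deletions_do_not_count(self):
        # 80 deletions of 30 kb: none pass the 40 kb gate, sample retained
        samples = make_samples(1, 0)
        calls = [
            dele("case_0", "1", i * 100_000, i * 100_000 + 30_000, probes=30)
            for i in range(80)
        ]
        exc, counts = flag_hypervariable_samples(calls, samples)
        assert exc == set() and counts == {}

    def test_unknown_sample_is_error(self):
        with pytest.raises(ValueError, match="ghost"):
            flag_hypervariable_samples(
                [dele("ghost", "1", 0, 500_000)], make_samples(1, 1)
            )


class TestRecurrenceClustering:
    def test_identical_calls_one_cluster(self):
        samples = make_samples(100, 200)
        calls = [dele(f"case_{i}", "1", 10_000_000, 10_500_000) for i in range(3)]
        (cluster,) = cluster_recurrence(calls, samples)
        assert cluster.carrier_count == 3
        assert cluster.frequency == pytest.approx(0.01)

    def test_disjoint_calls_are_singletons(self):
        samples = make_samples(2, 0)
        calls = [
            dele("case_0", "1", 0, 500_000),
            dele("case_1", "1", 5_000_000, 5_500_000),
        ]
        clusters = cluster_recurrence(calls, samples)
        assert len(clusters) == 2
        assert all(c.carrier_count == 1 for c in clusters)

    def test_single_linkage_chain(self):
        # A~B and B~C at 60% reciprocal, A~C only 20%: one cluster of three
        samples = make_samples(3, 0)
        A = dele("case_0", "1", 0, 100_000)
        B = dele("case_1", "1", 40_000, 140_000)
        C = dele("case_2", "1", 80_000, 180_000)
        assert reciprocal_overlap(A.interval, B.interval)[0] == pytest.approx(0.6)
        assert reciprocal_overlap(A.interval, C.interval)[0] == pytest.approx(0.2)
        clusters = cluster_recurrence([A, B, C], samples)
        assert len(clusters) == 1 and clusters[0].carrier_count == 3
        # brute-force oracle: connected components of the pairwise >= 50% graph
        calls = [A, B, C]
        adj = {
            (i, j)
            for i in range(3)
            for j in range(3)
            if i != j
            and min(reciprocal_overlap(calls[i].interval, calls[j].interval)) >= 0.5
        }
        assert adj == {(0, 1), (1, 0), (1, 2), (2, 1)}

    def test_frequency_invariant_to_input_order(self):
        samples = make_samples(10, 30)
        rng = random.Random(3)
        calls = [
            dele(f"case_{i % 10}", "2", s, s + 450_000)
            for i, s in enumerate(rng.sample(range(0, 50_000_000, 600_000), 20))
        ] + [dele(f"ctrl_{i}", "2", 7_000_000, 7_450_000) for i in range(4)]
        base = {
            frozenset(id(c) for c in cl.members): cl.frequency
            for cl in cluster_recurrence(calls, samples)
        }
        shuffled = calls[:]
        rng.shuffle(shuffled)
        perm = {
            frozenset(id(c) for c in cl.members): cl.frequency
            for cl in cluster_recurrence(shuffled, samples)
        }
        assert base == perm


ARTIFACTS = RegionSet(
    "artifacts", [Region("art1", GenomicInterval("9", 10_000_000, 11_000_000))]
)


class TestDeletionFilters:
    def run(self, calls, n_samples=1000, artifacts=ARTIFACTS, params=FilterParams()):
        samples = make_samples(n_samples // 2, n_samples - n_samples // 2)
        return apply_deletion_filters(calls, samples, artifacts, params)

    def test_size_boundary(self):
        reject = dele("case_0", "1", 0, 399_900, probes=250)
        keep = dele("case_1", "1", 5_000_000, 5_400_000, probes=250)
        retained, tally = self.run([reject, keep])
        assert retained == [keep]
        assert tally.size == 1

    def test_all_gates_pass(self):
        # 500 kb, exactly 200 probes, rare, 9% artifact overlap: retained
        call = dele("case_0", "9", 10_955_000, 11_455_000, probes=200)
        frac = 45_000 / 500_000
        assert frac == pytest.approx(0.09)
        retained, tally = self.run([call])
        assert retained == [call] and tally.total() == 0

    def test_artifact_fraction_strictly_over_10pct(self):
        at_10 = dele("case_0", "9", 10_950_000, 11_450_000, probes=250)  # 10.0%
        over = dele("case_1", "9", 10_900_000, 11_400_000, probes=250)  # 20%
        retained, tally = self.run([at_10, over])
        assert retained == [at_10] and tally.artifact == 1

    def test_engineered_tally(self):
        # 10 calls: 2 fail size, 1 fails probes, 3 fail frequency, 1 fails
        # artifact; 3 pass everything
        calls = [
            dele("case_0", "1", 0, 300_000, probes=250),
            dele("case_1", "1", 0, 350_000, probes=250),
            dele("case_2", "2", 0, 500_000, probes=120),
            dele("case_3", "3", 1_000_000, 1_500_000, probes=250),
            dele("case_4", "3", 1_000_000, 1_500_000, probes=250),
            dele("ctrl_0", "3", 1_000_000, 1_500_000, probes=250),
            dele("ctrl_1", "9", 10_100_000, 10_600_000, probes=250),
            dele("case_5", "5", 0, 600_000, probes=250),
            dele("ctrl_2", "6", 0, 800_000, probes=250),
            dele("ctrl_3", "7", 0, 1_200_000, probes=250),
        ]
        retained, tally = self.run(calls, n_samples=200)  # 3/200 = 1.5% >= 1%
        assert tally.as_dict() == {
            "state": 0, "size": 2, "probes": 1, "frequency": 3, "artifact": 1,
        }
        assert [c.sample_id for c in retained] == ["case_5", "ctrl_2", "ctrl_3"]
        assert len(calls) == len(retained) + tally.total()

    def test_frequency_boundary_strict(self):
        # exactly 1% frequency fails the "< 1%" rule
        calls = [dele(f"case_{i}", "1", 0, 500_000, probes=250) for i in range(2)]
        retained, tally = self.run(calls, n_samples=200)
        assert retained == [] and tally.frequency == 2

    def test_duplications_never_retained(self):
        dup = dele("case_0", "1", 0, 900_000, probes=500, state="duplication")
        retained, tally = self.run([dup])
        assert retained == [] and tally.state == 1

    def test_idempotence(self):
        calls = [
            dele("case_0", "1", 0, 300_000),
            dele("case_1", "2", 0, 900_000, probes=500),
            dele("ctrl_0", "4", 0, 450_000, probes=220),
        ]
        retained, _ = self.run(calls)
        again, tally = self.run(retained)
        assert again == retained and tally.total() == 0

    def test_empty_artifact_set_skips_gate(self):
        inside = dele("case_0", "9", 10_000_000, 10_500_000, probes=250)
        retained, _ = self.run([inside], artifacts=RegionSet("empty", []))
        assert retained == [inside]

    @pytest.mark.parametrize(
        "loose", [
            FilterParams(min_size_kb=300),
            FilterParams(min_probes=100),
            FilterParams(max_cohort_freq=0.05),
            FilterParams(max_artifact_overlap=0.5),
        ],
    )
    def test_loosening_is_monotone(self, loose):
        rng = random.Random(17)
        calls = [
            dele(
                f"case_{i % 100}", str(rng.randint(1, 9)),
                s := rng.randrange(0, 30_000_000, 10_000),
                s + rng.randrange(200_000, 900_000, 10_000),
                probes=rng.randint(80, 400),
            )
            for i in range(120)
        ]
        strict_kept, _ = self.run(calls, n_samples=500)
        loose_kept, _ = self.run(calls, n_samples=500, params=loose)
        assert set(id(c) for c in strict_kept) <= set(id(c) for c in loose_kept)
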