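import itertools

import numpy as np
import pytest

from equicnv import breed_specific_cnvrs, consolidate_calls
from equicnv.calling import CnvCall
from equicnv.regions import Cnvr

from conftest import brute_force_merge


def make_call(sample, chrom, start, end, direction="loss"):
    mean = -1.0 if direction == "loss" else 1.0
    return CnvCall(sample, chrom, start, end, 5, mean, direction, "heterozygous-or-unknown")


class TestConsolidation:
    def test_single_call_is_identity(self):
        [r] = consolidate_calls([make_call("s1", "chr1", 100, 200)])
        assert (r.chromosome, r.start, r.end) == ("chr1", 100, 200)
        assert r.sharing == "private" and r.state == "loss"

    def test_overlap_merges_into_complex_shared_region(self):
        calls = [make_call("s1", "chr1", 100, 200, "loss"),
                 make_call("s2", "chr1", 150, 250, "gain")]
        [r] = consolidate_calls(calls)
        assert (r.start, r.end) == (100, 250)
        assert r.state == "complex" and r.sharing == "shared"

    def test_boundary_adjacency_merges(self):
        calls = [make_call("s1", "chr1", 100, 200), make_call("s2", "chr1", 200, 300)]
        [r] = consolidate_calls(calls)
        assert (r.start, r.end) == (100, 300)

    def test_contiguous_but_not_touching_does_not_merge(self):
        calls = [make_call("s1", "chr1", 100, 200), make_call("s2", "chr1", 201, 300)]
        assert len(consolidate_calls(calls)) == 2

    def test_transitive_chaining(self):
        calls = [make_call("s1", "chr1", 100, 200),
                 make_call("s2", "chr1", 200, 300),
                 make_call("s3", "chr1", 300, 400)]
        [r] = consolidate_calls(calls)
        assert (r.start, r.end) == (100, 400)
        assert r.samples == {"s1", "s2", "s3"}

    def test_chromosomes_never_merge(self):
        calls = [make_call("s1", "chr1", 100, 200), make_call("s1", "chr2", 100, 200)]
        assert len(consolidate_calls(calls)) == 2

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            CnvCall("s", "chr1", 200, 100, 5, -1.0, "loss", "heterozygous-or-unknown")

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_transitive_closure(self, seed, random_intervals):
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, int(rng.integers(1, 21)))
        calls = [make_call(f"s{i % 3}", c, s, e) for i, (c, s, e) in enumerate(ivs)]
        got = sorted((r.chromosome, r.start, r.end) for r in consolidate_calls(calls))
        expected = [(c, s, e) for c, s, e, _ in brute_force_merge(ivs)]
        assert got == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent(self, seed, random_intervals):
        rng = np.random.default_rng(100 + seed)
        ivs = random_intervals(rng, 15)
        calls = [make_call("s1", c, s, e) for c, s, e in ivs]
        once = consolidate_calls(calls)
        again = consolidate_calls([m for r in once for m in r.member_calls])
        assert [(r.chromosome, r.start, r.end) for r in once] == \
               [(r.chromosome, r.start, r.end) for r in again]

    def test_coverage_conserved(self, random_intervals):
        rng = np.random.default_rng(42)
        ivs = random_intervals(rng, 20)
        calls = [make_call("s1", c, s, e) for c, s, e in ivs]
        def covered(spans):
            bases = set()
            for c, s, e in spans:
                bases.update((c, p) for p in range(s, e + 1))
            return bases
        cnvr_spans = [(r.chromosome, r.start, r.end) for r in consolidate_calls(calls)]
        assert covered(cnvr_spans) == covered(ivs)


class TestClassification:
    @pytest.mark.parametrize("directions,expected", [
        (("loss",), "loss"),
        (("gain",), "gain"),
        (("loss", "loss"), "loss"),
        (("gain", "gain"), "gain"),
        (("gain", "loss"), "complex"),
        (("loss", "gain", "loss"), "complex"),
        (("gain", "gain", "gain", "loss"), "complex"),
    ])
    def test_state_truth_table(self, directions, expected):
        # non-overlapping member calls chained by adjacency
        calls = [
            make_call(f"s{i}", "chr1", 100 + 50 * i, 150 + 50 * i, d)
            for i, d in enumerate(directions)
        ]
        [r] = consolidate_calls(calls)
        assert r.state == expected

    @pytest.mark.parametrize("sample_ids,expected", [
        (("A",), "private"),
        (("A", "A"), "private"),  # distinct samples, not distinct calls
        (("A", "B"), "shared"),
        (("A", "A", "B"), "shared"),
        (("A", "B", "C", "D"), "shared"),
    ])
    def test_sharing_truth_table(self, sample_ids, expected):
        calls = [
            make_call(s, "chr1", 100 + 50 * i, 150 + 50 * i)
            for i, s in enumerate(sample_ids)
        ]
        [r] = consolidate_calls(calls)
        assert r.sharing == expected

    @pytest.mark.parametrize("carriers,expected", [
        (("E1", "E2"), True),       # two of one breed, no others
        (("E1",), False),           # needs >= 2 individuals
        (("E1", "E2", "F1"), False),  # second breed present
        (("E1", "E1"), False),      # same individual twice is not sharing
        (("F1", "F2"), True),
    ])
    def test_breed_specific_truth_table(self, carriers, expected):
        breeds = {"E1": "Exmoor", "E2": "Exmoor", "F1": "Friesian", "F2": "Friesian"}
        calls = [
            make_call(s, "chr1", 100 + 50 * i, 150 + 50 * i)
            for i, s in enumerate(carriers)
        ]
        [r] = consolidate_calls(calls)
        flagged = breed_specific_cnvrs([r], breeds)
        assert r.breed_specific is expected
        assert (r in flagged) is expected

    def test_unmapped_sample_errors(self):
        [r] = consolidate_calls([make_call("mystery", "chr1", 1, 10)])
        with pytest.raises(KeyError, match="mystery"):
            breed_specific_cnvrs([r], {"known": "breed"})

    def test_state_counts_partition_total(self, random_intervals):
        rng = np.random.default_rng(7)
        ivs = random_intervals(rng, 30)
        calls = [
            make_call(f"s{i % 4}", c, s, e, "gain" if rng.random() < 0.3 else "loss")
            for i, (c, s, e) in enumerate(ivs)
        ]
        cnvrs = consolidate_calls(calls)
        states = [r.state for r in cnvrs]
        assert states.count("gain") + states.count("loss") + states.count("complex") == len(cnvrs)
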