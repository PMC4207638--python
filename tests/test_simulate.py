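import math

import numpy as np
import pytest

from equicnv import (
    SampleInfo,
    SimParams,
    TruthCnv,
    plant_truth_cnvs,
    simulate_cohort,
    simulate_hybridization,
)
from equicnv.simulate import COPY_STATE_LOG2, HOM_LOSS_LOG2_FLOOR


class TestCopyStates:
    def test_expected_log2_is_log2_copy_over_two(self):
        assert COPY_STATE_LOG2["het_loss"] == -1.0  # copy 1
        assert COPY_STATE_LOG2["het_gain"] == pytest.approx(math.log2(3 / 2))
        assert COPY_STATE_LOG2["multi_gain"] == 1.0  # copy 4
        assert COPY_STATE_LOG2["hom_loss"] == HOM_LOSS_LOG2_FLOOR == -4.0

    def test_invalid_truth_interval_rejected(self):
        with pytest.raises(ValueError):
            TruthCnv("s", "chr1", 100, 50, "het_loss", -1.0)
        with pytest.raises(ValueError):
            TruthCnv("s", "chr1", 1, 10, "triplication", 1.0)


class TestPlanting:
    def test_zero_mean_gives_empty_truth(self, toy_genome, samples4):
        truth = plant_truth_cnvs(
            toy_genome, samples4, SimParams(mean_cnvs_per_sample=0), seed=1
        )
        assert truth == []

    def test_poisson_total_count(self, toy_genome):
        # 36 samples at mean 26.4: total within 3 SD of 950
        samples = [SampleInfo(f"h{i}", breed=f"b{i % 6}") for i in range(36)]
        params = SimParams(size_range=(1_000, 100_000), shared_fraction=0.0)
        truth = plant_truth_cnvs(toy_genome, samples, params, seed=7)
        expected = 36 * 26.4
        assert abs(len(truth) - expected) <= 3 * math.sqrt(expected)

    def test_shared_fraction_one_puts_regions_in_both_samples(self, toy_genome):
        samples = [SampleInfo("a", breed="x"), SampleInfo("b", breed="x")]
        params = SimParams(
            mean_cnvs_per_sample=5, size_range=(1_000, 10_000),
            shared_fraction=1.0, breed_restricted_fraction=0.0,
        )
        truth = plant_truth_cnvs(toy_genome, samples, params, seed=3)
        regions = {}
        for t in truth:
            regions.setdefault((t.chromosome, t.start, t.end), set()).add(t.sample_id)
        assert regions  # something was planted
        assert all(carriers == {"a", "b"} for carriers in regions.values())

    def test_truth_cnvs_never_overlap_within_sample(self, toy_genome, samples4):
        params = SimParams(mean_cnvs_per_sample=30, size_range=(1_000, 200_000))
        truth = plant_truth_cnvs(toy_genome, samples4, params, seed=11)
        by = {}
        for t in truth:
            by.setdefault((t.sample_id, t.chromosome), []).append((t.start, t.end))
        for ivs in by.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 < s2

    def test_breed_restricted_variants_stay_in_one_breed(self, toy_genome, samples4):
        params = SimParams(
            mean_cnvs_per_sample=20, size_range=(1_000, 50_000),
            shared_fraction=0.0, breed_restricted_fraction=1.0,
        )
        truth = plant_truth_cnvs(toy_genome, samples4, params, seed=5)
        breed = {s.sample_id: s.breed for s in samples4}
        regions = {}
        for t in truth:
            regions.setdefault((t.chromosome, t.start, t.end), set()).add(t.sample_id)
        for carriers in regions.values():
            assert len({breed[s] for s in carriers}) == 1

    def test_intervals_within_chromosome_bounds(self, toy_genome, samples4):
        truth = plant_truth_cnvs(toy_genome, samples4, SimParams(), seed=2)
        for t in truth:
            assert 1 <= t.start <= t.end <= toy_genome.length(t.chromosome)

    def test_size_range_larger_than_smallest_chromosome_rejected(self, toy_genome, samples4):
        with pytest.raises(ValueError):
            plant_truth_cnvs(
                toy_genome, samples4,
                SimParams(size_range=(3_000_000, 3_000_000)), seed=0,
            )


class TestHybridization:
    def test_noiseless_limit_recovers_planted_shift(self, exact_probe_map):
        t = exact_probe_map.table
        body = t[(t.chromosome == "chr1") & (t.start > 1_000_000)].iloc[:6]
        truth = [TruthCnv("s", "chr1", int(body.start.iloc[0]), int(body.end.iloc[-1]),
                          "het_loss", -1.0)]
        hyb = simulate_hybridization(exact_probe_map, truth, noise_sd=1e-9, seed=0)
        covered = hyb.log2[body.index]
        assert np.allclose(covered, -1.0, atol=1e-6)
        rest = np.delete(hyb.log2, body.index)
        assert np.abs(rest).max() < 1e-6

    def test_null_profile_noise_sd_calibrated(self, toy_genome):
        from equicnv import design_probe_map

        g = toy_genome
        pm = design_probe_map(g, spacing={"default": 100, "subtelomere": 100}, seed=0)
        assert len(pm) >= 100_000
        hyb = simulate_hybridization(pm, [], noise_sd=0.14, seed=4,
                                     sample=SampleInfo("n", breed="x"))
        assert 0.135 <= hyb.log2.std(ddof=1) <= 0.145

    def test_sex_effect_shifts_x_probes(self):
        from equicnv import build_genome, design_probe_map

        g = build_genome(spec=[("chr1", 3_000_000), ("chrX", 3_000_000)])
        pm = design_probe_map(g, jitter_fraction=0.0, seed=0)
        hyb = simulate_hybridization(
            pm, [], noise_sd=1e-9, sex_effect="male_vs_female_ref", seed=0,
            sample=SampleInfo("m", breed="x", sex="M"),
        )
        x = pm.table.chromosome == "chrX"
        assert np.allclose(hyb.log2[x.to_numpy()], -1.0, atol=1e-6)
        assert np.allclose(hyb.log2[(~x).to_numpy()], 0.0, atol=1e-6)

    def test_truth_covering_no_probe_warns(self, exact_probe_map):
        # between two probes: probe at 7501..7560, next at 15001; pick a gap
        truth = [TruthCnv("s", "chr1", 7_561, 7_570, "het_loss", -1.0)]
        with pytest.warns(UserWarning, match="zero probes"):
            simulate_hybridization(exact_probe_map, truth, noise_sd=0.1, seed=0,
                                   sample=SampleInfo("s", breed="x"))

    def test_rejects_foreign_truth(self, exact_probe_map):
        truth = [TruthCnv("other", "chr1", 1, 100_000, "het_loss", -1.0)]
        with pytest.raises(ValueError, match="other"):
            simulate_hybridization(exact_probe_map, truth, noise_sd=0.1, seed=0,
                                   sample=SampleInfo("s", breed="x"))


class TestCohort:
    def test_two_null_samples(self, toy_genome, toy_probe_map):
        samples = [SampleInfo("a", breed="x"), SampleInfo("b", breed="x")]
        hybs, truth = simulate_cohort(
            toy_genome, toy_probe_map, samples,
            SimParams(mean_cnvs_per_sample=0), seed=1,
        )
        assert len(hybs) == 2 and truth == []

    def test_deterministic_given_seed(self, toy_genome, toy_probe_map, samples4):
        params = SimParams(mean_cnvs_per_sample=3, size_range=(50_000, 200_000))
        h1, t1 = simulate_cohort(toy_genome, toy_probe_map, samples4, params, seed=9)
        h2, t2 = simulate_cohort(toy_genome, toy_probe_map, samples4, params, seed=9)
        assert t1 == t2
        for a, b in zip(h1, h2):
            assert np.array_equal(a.log2, b.log2)

    def test_tissue_noise_levels_recovered_by_qc(self, toy_genome):
        from equicnv import compute_dlrsd, design_probe_map

        pm = design_probe_map(toy_genome, spacing={"default": 200, "subtelomere": 200}, seed=0)
        samples = [
            SampleInfo("blood1", breed="x", tissue="blood"),
            SampleInfo("hair1", breed="x", tissue="hair"),
        ]
        hybs, _ = simulate_cohort(
            toy_genome, pm, samples, SimParams(mean_cnvs_per_sample=0), seed=21
        )
        for hyb, sd in zip(hybs, (0.14, 0.41)):
            assert abs(compute_dlrsd(hyb, pm) - sd) / sd < 0.05
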