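"""Ambiguity-weighted coverage, sampling distribution, artifact masking."""

import numpy as np
import pytest

import teenrich as te
from teenrich.background import filter_library_by_mask

from conftest import brute_coverage


class TestWeightedCoverage:
    def test_two_read_worked_example(self, two_read_library):
        cov = te.compute_weighted_coverage(two_read_library)
        v = cov.cov["chr1"]
        assert v[17] == pytest.approx(1.5)  # 1 from A + 0.5 from B
        assert v[105] == pytest.approx(0.5)
        assert v[12] == pytest.approx(1.0)
        assert v[30] == 0.0
        assert cov.cov_c["chr1"] == pytest.approx(20.0)  # 10·1 + 20·0.5

    def test_single_unimapper_conserves_length(self):
        lib = te.MappingLibrary(
            [te.ReadGroup("r", 37, [te.Mapping("chr1", 5, 42)])], {"chr1": 100})
        assert te.compute_weighted_coverage(lib).total == pytest.approx(37.0)

    def test_matches_per_base_oracle(self, small_study):
        cov = te.compute_weighted_coverage(small_study["input"])
        oracle = brute_coverage(small_study["input"])
        for chrom in oracle:
            assert np.max(np.abs(cov.cov[chrom] - oracle[chrom])) < 1e-9

    def test_out_of_bounds_mapping_truncated(self):
        lib = te.MappingLibrary(
            [te.ReadGroup("r", 20, [te.Mapping("chr1", 90, 110)])], {"chr1": 100})
        cov = te.compute_weighted_coverage(lib)
        assert cov.total == pytest.approx(10.0)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty input"):
            te.compute_weighted_coverage(te.MappingLibrary([], {"chr1": 100}))


class TestProbabilityModel:
    def test_p_n_from_worked_example(self, two_read_library):
        model = te.build_probability_model(
            te.compute_weighted_coverage(two_read_library))
        pos = model.eff_pos["chr1"]
        assert model.p["chr1"][np.where(pos == 17)[0][0]] == pytest.approx(1.5 / 20)

    def test_uniform_coverage_gives_uniform_p(self):
        reads = [te.ReadGroup(f"r{i}", 10, [te.Mapping("chr1", s, s + 10)])
                 for i, s in enumerate(range(0, 100, 10))]
        model = te.build_probability_model(
            te.compute_weighted_coverage(te.MappingLibrary(reads, {"chr1": 100})))
        assert np.allclose(model.p["chr1"], 0.01)

    def test_normalisation_invariants(self, small_study):
        model = te.build_probability_model(
            te.compute_weighted_coverage(small_study["input"]))
        assert model.w_c.sum() == pytest.approx(1.0, abs=1e-9)
        for chrom in model.chrom_names:
            assert model.p[chrom].sum() == pytest.approx(1.0, abs=1e-9)

    def test_read_probabilities_sum_to_one_at_effective_positions(self, small_study):
        model = te.build_probability_model(
            te.compute_weighted_coverage(small_study["input"]))
        rng = np.random.default_rng(0)
        for chrom in model.chrom_names:
            for pos in rng.choice(model.eff_pos[chrom], size=25):
                _, probs = model.reads_at(chrom, int(pos))
                assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mask_zeroes_and_renormalises(self, two_read_library):
        cov = te.compute_weighted_coverage(two_read_library)
        mask = te.RegionMask.from_intervals([("chr1", 17, 18)])
        model = te.build_probability_model(cov, mask=mask)
        assert 17 not in set(model.eff_pos["chr1"])
        assert model.p["chr1"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_masked_rejected(self, two_read_library):
        cov = te.compute_weighted_coverage(two_read_library)
        with pytest.raises(ValueError, match="effective"):
            te.build_probability_model(
                cov, mask=te.RegionMask.from_intervals([("chr1", 0, 200)]))


class TestRegionMaskApplication:
    def test_masked_coverage_matches_oracle(self, two_read_library):
        cov = te.compute_weighted_coverage(two_read_library)
        masked = te.apply_region_mask(
            cov, te.RegionMask.from_intervals([("chr1", 10, 20)]))
        oracle = brute_coverage(two_read_library)["chr1"]
        oracle[10:20] = 0.0
        assert np.max(np.abs(masked.cov["chr1"] - oracle)) < 1e-9
        assert masked.cov_c["chr1"] == pytest.approx(oracle.sum())

    def test_empty_mask_is_identity(self, two_read_library):
        cov = te.compute_weighted_coverage(two_read_library)
        masked = te.apply_region_mask(cov, te.RegionMask())
        assert np.array_equal(masked.cov["chr1"], cov.cov["chr1"])

    def test_whole_chromosome_masked(self, two_read_library):
        cov = te.compute_weighted_coverage(two_read_library)
        masked = te.apply_region_mask(
            cov, te.RegionMask.from_intervals([("chr1", 0, 200)]))
        assert masked.cov_c["chr1"] == 0.0

    def test_masking_never_increases_coverage(self, small_study):
        cov = te.compute_weighted_coverage(small_study["input"])
        mask = te.RegionMask.from_intervals([("chr1", 100, 5_000),
                                             ("chr2", 0, 1_000)])
        masked = te.apply_region_mask(cov, mask)
        for chrom in cov.cov:
            assert np.all(masked.cov[chrom] <= cov.cov[chrom] + 1e-12)


def _stacked_library(window_counts, span, chrom_len, window):
    """One read per count unit, fully inside each window."""
    reads = []
    i = 0
    for w, n in enumerate(window_counts):
        for _ in range(n):
            s = w * window + 2
            reads.append(te.ReadGroup(f"r{i}", span, [te.Mapping("chr1", s, s + span)]))
            i += 1
    return te.MappingLibrary(reads, {"chr1": chrom_len})


class TestArtifactWindows:
    def test_extreme_window_flagged_by_percentile_rule(self):
        # non-zero window counts [1,1,1,1,1000]: the 99.997th percentile
        # interpolates to ~999.88, so only the 1000-count window exceeds it
        lib = _stacked_library([1, 1, 1, 1, 1000], span=10, chrom_len=250, window=50)
        mask = te.detect_artifact_windows(lib, window=50, step=50)
        assert mask.intervals["chr1"][0].tolist() == [200]
        assert mask.intervals["chr1"][1].tolist() == [250]

    def test_equal_windows_give_empty_mask(self):
        lib = _stacked_library([5, 5, 5, 5, 5], span=10, chrom_len=250, window=50)
        assert te.detect_artifact_windows(lib, window=50, step=50).is_empty()

    def test_flagged_windows_union_into_one_interval(self):
        mask = te.RegionMask.from_intervals([("chr1", 0, 100), ("chr1", 50, 150)])
        assert mask.intervals["chr1"][0].tolist() == [0]
        assert mask.intervals["chr1"][1].tolist() == [150]

    def test_zero_count_windows_excluded_from_percentile(self):
        # sparse genome: most windows empty; threshold computed on non-zero
        # counts [2]*30 + [500] only, so the hot window is still caught
        counts = [0] * 0 + [2] * 30 + [500]
        lib = _stacked_library(counts, span=10, chrom_len=100_000, window=50)
        mask = te.detect_artifact_windows(lib, window=50, step=50)
        assert not mask.is_empty()
        s, e = mask.intervals["chr1"]
        assert s[0] == 30 * 50 and e[0] == 31 * 50

    def test_invalid_window_config_rejected(self, two_read_library):
        with pytest.raises(ValueError):
            te.detect_artifact_windows(two_read_library, window=0)
        with pytest.raises(ValueError):
            te.detect_artifact_windows(two_read_library, step=-5)

    def test_mapping_counts_in_every_overlapped_window(self):
        # one read straddling two windows counts in both
        lib = te.MappingLibrary(
            [te.ReadGroup("r", 20, [te.Mapping("chr1", 45, 65)])], {"chr1": 150})
        from teenrich.background import _window_counts
        arr = lib.arrays()
        counts = _window_counts(arr, 150, 50, 50, np.ones(1, dtype=bool))
        assert counts.tolist() == [1, 1, 0]


class TestLibraryMaskFilter:
    def test_fully_masked_mapping_dropped_and_ambiguity_recomputed(self, two_read_library):
        mask = te.RegionMask.from_intervals([("chr1", 95, 115)])
        out = filter_library_by_mask(two_read_library, mask)
        by_id = {r.read_id: r for r in out.reads}
        assert by_id["B"].n_mappings == 1  # [100,110) removed
        assert by_id["A"].n_mappings == 1

    def test_partially_masked_mapping_dropped_whole(self, two_read_library):
        # exclusion is at mapping granularity: any overlap removes the mapping
        mask = te.RegionMask.from_intervals([("chr1", 0, 13)])
        out = filter_library_by_mask(two_read_library, mask)
        assert [r.read_id for r in out.reads] == ["B"]
        assert out.reads[0].mappings == [te.Mapping("chr1", 15, 25),
                                         te.Mapping("chr1", 100, 110)]

    def test_emptied_read_dropped(self, two_read_library):
        mask = te.RegionMask.from_intervals([("chr1", 0, 30)])
        out = filter_library_by_mask(two_read_library, mask)
        assert [r.read_id for r in out.reads] == ["B"]
        assert out.reads[0].n_mappings == 1


def test_mask_bed_round_trip(tmp_path):
    mask = te.RegionMask.from_intervals(
        [("chr2", 100, 200), ("chr1", 0, 50), ("chr1", 40, 90)])
    p = tmp_path / "mask.bed"
    mask.write_bed(p)
    back = te.RegionMask.read_bed(p)
    for chrom in mask.intervals:
        assert back.intervals[chrom][0].tolist() == mask.intervals[chrom][0].tolist()
        assert back.intervals[chrom][1].tolist() == mask.intervals[chrom][1].tolist()
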