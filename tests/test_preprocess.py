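"""QC filters, site assignment, UMI dedup, normalization, matrix assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mreseq import simulate as sim
from mreseq.preprocess import (
    BACKGROUND,
    DepthMatrix,
    ReadSet,
    assign_reads_to_sites,
    build_depth_matrix,
    classify_on_target,
    deduplicate_umis,
    directional_cluster,
    on_target_ratio,
    preprocess_fastq_sample,
    qc_filter_reads,
    read_fastq_pair,
    trimmed_mean_normalize,
)
from mreseq.sites import GenomeSequence, enumerate_sacii_sites


def _readset(rows):
    cols = ["read_id", "seq1", "qual1", "seq2", "qual2", "chrom", "pos"]
    return ReadSet(pd.DataFrame(rows, columns=cols))


GOOD = ("r0", "GCGG" + "A" * 96, "I" * 100, "ACGTACGTAC" + "T" * 90, "I" * 100, "chrT", 3)


class TestQC:
    @pytest.mark.parametrize(
        "row,reason",
        [
            (("r1", "A" * 19, "I" * 19, "ACGTACGTAC" + "T" * 90, "I" * 100, "c", 0), "short"),
            (("r2", "A" * 100, "I" * 100, None, None, "c", 0), "single_end"),
            (("r3", "A" * 100, "I" * 100, "ACGTNACGTA" + "T" * 90, "I" * 100, "c", 0), "umi_N"),
            (("r4", "A" * 100, "I" * 100, "ACGTACGTAC" + "T" * 90, "!" + "I" * 99, "c", 0), "umi_q0"),
        ],
    )
    def test_drop_reasons(self, row, reason):
        kept, report = qc_filter_reads(_readset([GOOD, row]))
        assert report.total == 2 and report.kept == 1
        assert report.dropped[reason] == 1
        assert kept.df["read_id"].tolist() == ["r0"]

    def test_missing_umi_counted_when_length_filter_relaxed(self):
        row = ("r5", "A" * 100, "I" * 100, "ACGTACGT", "I" * 8, "c", 0)
        kept, report = qc_filter_reads(_readset([GOOD, row]), min_length=5)
        assert report.dropped["no_umi"] == 1 and report.kept == 1

    def test_clean_pair_kept(self):
        kept, report = qc_filter_reads(_readset([GOOD]))
        assert report.kept == 1 and sum(report.dropped.values()) == 0


@pytest.fixture(scope="module")
def sites():
    return enumerate_sacii_sites(GenomeSequence({"chrT": "ACCGCGGT" + "A" * 20}))


class TestAssignment:
    def test_cut_terminus_offset_arithmetic(self, sites):
        rs = _readset([GOOD])  # pos 3 == motif_start 1 + 2
        out = assign_reads_to_sites(rs, sites)
        assert out.df["site_id"].tolist() == ["chrT:1"]

    def test_off_by_one_goes_to_background(self, sites):
        row = list(GOOD)
        row[0], row[6] = "r9", 4
        out = assign_reads_to_sites(_readset([tuple(row)]), sites)
        assert out.df["site_id"].tolist() == [BACKGROUND]

    def test_unknown_contig_warns_background(self, sites):
        row = list(GOOD)
        row[5] = "chrUn"
        with pytest.warns(UserWarning, match="chrUn"):
            out = assign_reads_to_sites(_readset([tuple(row)]), sites)
        assert out.df["site_id"].tolist() == [BACKGROUND]


def exhaustive_directional_oracle(umis, counts):
    """Brute-force reference: build the directional graph explicitly, then
    count weakly connected components reachable from high-count roots in the
    same descending-count order the algorithm uses."""
    k = len(umis)
    ham = lambda a, b: sum(x != y for x, y in zip(a, b))
    order = sorted(range(k), key=lambda i: (-counts[i], umis[i]))
    visited = set()
    n_clusters = 0
    for seed in order:
        if seed in visited:
            continue
        n_clusters += 1
        frontier = [seed]
        visited.add(seed)
        while frontier:
            u = frontier.pop()
            for v in range(k):
                if v not in visited and ham(umis[u], umis[v]) <= 1 and counts[u] >= 2 * counts[v] - 1:
                    visited.add(v)
                    frontier.append(v)
    return n_clusters


class TestUMIDedup:
    def test_exact_duplicates_collapse(self):
        assert len(directional_cluster(["AAAAAAAAAA"], [2])) == 1

    def test_single_error_umi_absorbed(self):
        clusters = directional_cluster(["AAAAAAAAAA", "AAAAAAAAAT"], [10, 1])
        assert len(clusters) == 1
        assert clusters[0][0] == 0  # representative is the high-count UMI

    def test_distant_umis_stay_separate(self):
        assert len(directional_cluster(["AAAAAAAAAA", "TTTTTTTTTT"], [5, 5])) == 2

    def test_near_equal_counts_not_merged(self):
        # directional rule: 5 >= 2*5-1 is false, so two molecules
        assert len(directional_cluster(["AAAAAAAAAA", "AAAAAAAAAT"], [5, 5])) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        base = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(4)]
        umis, counts = [], []
        for b in base:
            for _ in range(rng.integers(1, 4)):
                u = list(b)
                if rng.random() < 0.7:
                    u[rng.integers(10)] = rng.choice(list("ACGT"))
                u = "".join(u)
                if u not in umis:
                    umis.append(u)
                    counts.append(int(rng.integers(1, 20)))
        got = len(directional_cluster(umis, counts))
        assert got == exhaustive_directional_oracle(umis, counts)

    def test_dedup_never_increases_counts(self):
        rows = []
        for i, (umi, n) in enumerate([("AAAAAAAAAA", 4), ("CCCCCCCCCC", 3)]):
            for j in range(n):
                rows.append((f"r{i}_{j}", "GCGG" + "A" * 96, "I" * 100,
                             umi + "T" * 90, "I" * 100, "chrT", 3))
        rs = _readset(rows)
        rs.df["site_id"] = "chrT:1"
        molecules, ratio = deduplicate_umis(rs)
        assert len(molecules) == 2
        assert molecules["n_reads"].sum() == 7
        assert ratio == pytest.approx(2 / 7)


class TestOnTarget:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GCGGATTT", True), ("ACGGATTT", False), ("GCG", False), (None, False)],
    )
    def test_prefix_rule(self, seq, expected):
        assert classify_on_target(seq) is expected

    def test_simulated_ratio_matches_generator_expectation(self, toy_genome, toy_sites, tmp_path):
        atlas = sim.build_methylation_atlas(len(toy_sites), seed=3)
        lib = sim.LibraryConfig(mean_site_depth=15, off_target_rate=0.0, seq_error_rate=0.0)
        meta = sim.SampleMetadata("S1", "control")
        library = sim.simulate_reads(atlas, meta, toy_genome, toy_sites, lib, seed=8, out_dir=tmp_path)
        reads = read_fastq_pair(library.fastq1, library.fastq2, library.truth)
        kept, _ = qc_filter_reads(reads)
        molecules, _ = deduplicate_umis(assign_reads_to_sites(kept, toy_sites))
        assert on_target_ratio(molecules) == 1.0


class TestTrimmedMean:
    def test_constant_row(self):
        tm, norm = trimmed_mean_normalize(np.full(100, 10.0))
        assert tm == 10.0 and np.all(norm == 1.0)

    def test_sort_and_slice_oracle_1_to_20(self):
        tm, _ = trimmed_mean_normalize(np.arange(1, 21, dtype=float))
        assert tm == pytest.approx(np.mean(np.arange(2, 20)))  # 10.5

    def test_extreme_outlier_excluded(self):
        row = np.full(100, 10.0)
        row[0] = 1e6
        tm, _ = trimmed_mean_normalize(row)
        assert tm == 10.0

    def test_scale_invariance_of_normalized_row(self):
        rng = np.random.default_rng(0)
        row = rng.poisson(20, size=200).astype(float) + 1
        _, n1 = trimmed_mean_normalize(row)
        _, n2 = trimmed_mean_normalize(row * 7.5)
        np.testing.assert_allclose(n1, n2)

    def test_trimmed_mean_bounded_by_row_extremes(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            row = rng.poisson(15, size=50).astype(float) + 1
            tm, _ = trimmed_mean_normalize(row)
            assert row.min() <= tm <= row.max()

    def test_short_row_plain_mean_with_warning(self):
        with pytest.warns(UserWarning, match="plain mean"):
            tm, _ = trimmed_mean_normalize(np.array([1.0, 2.0, 3.0]))
        assert tm == 2.0

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            trimmed_mean_normalize(np.zeros(100))


class TestDepthMatrix:
    def test_assembly_and_renormalization(self, toy_sites):
        rng = np.random.default_rng(2)
        depths = {
            f"S{i}": pd.Series(rng.poisson(20, len(toy_sites)) + 1, index=toy_sites.site_ids)
            for i in range(3)
        }
        dm = build_depth_matrix(depths, toy_sites)
        assert dm.raw.shape == (3, len(toy_sites))
        for sid in dm.sample_ids:
            tm, norm = trimmed_mean_normalize(dm.raw.loc[sid].to_numpy())
            assert dm.trimmed_means[sid] == pytest.approx(tm)
            np.testing.assert_allclose(dm.normalized.loc[sid].to_numpy(), norm)

    def test_inconsistent_site_set_names_sample(self, toy_sites):
        depths = {
            "ok": pd.Series(1.0, index=toy_sites.site_ids),
            "bad": pd.Series(1.0, index=toy_sites.site_ids[:-1]),
        }
        with pytest.raises(ValueError, match="bad"):
            build_depth_matrix(depths, toy_sites)

    def test_tsv_round_trip(self, tmp_path, toy_sites):
        rng = np.random.default_rng(3)
        depths = {
            "S0": pd.Series(rng.poisson(9, len(toy_sites)) + 1, index=toy_sites.site_ids)
        }
        dm = build_depth_matrix(depths, toy_sites)
        p = tmp_path / "m.tsv"
        dm.to_tsv(p)
        back = DepthMatrix.read_tsv(p)
        pd.testing.assert_frame_equal(back.raw, dm.raw, check_dtype=False)


class TestCrossPath:
    def test_fastq_path_equals_direct_path(self, toy_genome, toy_sites, tmp_path):
        atlas = sim.build_methylation_atlas(len(toy_sites), seed=3)
        lib = sim.LibraryConfig(mean_site_depth=8, off_target_rate=0.0, seq_error_rate=0.0)
        meta = sim.SampleMetadata("SX", "crc", 0.3, stage="II")
        library = sim.simulate_reads(atlas, meta, toy_genome, toy_sites, lib, seed=33, out_dir=tmp_path)
        counts, qc = preprocess_fastq_sample(library.fastq1, library.fastq2, library.truth, toy_sites)
        direct = sim.simulate_sample_depths(atlas, meta, lib, seed=33)
        assert np.array_equal(counts.to_numpy(), direct)
        assert qc["on_target_ratio"] == 1.0

    def test_pipeline_idempotent(self, toy_genome, toy_sites, tmp_path):
        atlas = sim.build_methylation_atlas(len(toy_sites), seed=3)
        lib = sim.LibraryConfig(mean_site_depth=5)
        meta = sim.SampleMetadata("SY", "control")
        library = sim.simulate_reads(atlas, meta, toy_genome, toy_sites, lib, seed=4, out_dir=tmp_path)
        c1, _ = preprocess_fastq_sample(library.fastq1, library.fastq2, library.truth, toy_sites)
        c2, _ = preprocess_fastq_sample(library.fastq1, library.fastq2, library.truth, toy_sites)
        pd.testing.assert_series_equal(c1, c2)
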