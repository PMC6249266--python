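"""Matrix preparation: CPM filtering, TMM, log normalization, peak/read
interval operations and MAD feature selection, each checked against an
independent per-definition oracle where the operation is non-trivial."""

import numpy as np
import pandas as pd
import pytest

from epitax.matrixprep import (NormalizedMatrix, consensus_peaks,
                               count_reads_in_regions, cpm_filter, frip,
                               mad_select, normalize_log, occupancy_curve,
                               qc_metrics, tmm_factors)
from conftest import jittered_peak_sets


# ---------------------------------------------------------------------- CPM

class TestCpmFilter:
    def test_strict_inequality_at_exactly_one_cpm(self):
        # count 1 in a library of exactly 1e6 reads gives CPM == 1, which is
        # not > 1, so the gene is removed
        counts = pd.DataFrame(np.zeros((2, 12), dtype=int))
        counts.iloc[0] = 1
        counts.iloc[1] = 10 ** 6 - 1  # filler keeping each library at 1e6
        keep = cpm_filter(counts, min_cpm=1.0, min_samples=10)
        assert 0 not in keep

    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame({"a": [0, 5, 100], "b": [0, 5, 100]})
        keep = cpm_filter(counts, min_cpm=1.0, min_samples=2)
        assert 0 not in keep

    def test_matches_exhaustive_definition_scan(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, size=(3, 12)))
        lib = counts.sum(axis=0)
        expected = [
            i for i in range(3)
            if sum(counts.iloc[i, j] / lib[j] * 1e6 > 1.0 for j in range(12)) >= 3
        ]
        assert cpm_filter(counts, min_cpm=1.0, min_samples=3).tolist() == expected

    def test_zero_library_names_sample(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            cpm_filter(counts)


# ---------------------------------------------------------------------- TMM

class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 200, 35, 80, 4, 60])
        counts = pd.DataFrame(np.tile(col[:, None], (1, 4)))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_scaling_cancels(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 500, 50)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_composition_bias_matches_reference_walk(self):
        # fixed 20x4 matrix with two composition-biased genes; expected factors
        # computed independently with the reference TMM implementation
        rng = np.random.default_rng(42)
        base = rng.integers(50, 500, size=20)
        counts = np.stack([rng.poisson(base * d) for d in (1.0, 1.5, 0.7, 2.0)], axis=1)
        counts[0, 1] *= 30
        counts[1, 1] *= 20
        f = tmm_factors(pd.DataFrame(counts))
        expected = [1.2873798976, 0.4707591430, 1.2959203373, 1.2732573963]
        assert np.allclose(f, expected, atol=1e-8)

    def test_scale_invariance_and_geometric_mean(self, rng):
        counts = pd.DataFrame(rng.integers(0, 300, size=(40, 5)))
        f1 = tmm_factors(counts)
        f2 = tmm_factors(counts * 7)
        assert np.allclose(f1, f2)
        assert abs(np.exp(np.mean(np.log(f1))) - 1.0) < 1e-12


# ------------------------------------------------------------ normalize_log

class TestNormalizeLog:
    def test_zero_count_gives_log2_pseudocount(self):
        counts = pd.DataFrame({"a": [0, 100], "b": [0, 100]})
        norm = normalize_log(counts, pseudocount=0.5)
        assert np.allclose(norm.values.iloc[0], np.log2(0.5))

    def test_depth_invariance(self):
        c1 = pd.DataFrame({"a": [10, 90], "b": [30, 70]})
        c2 = c1 * 2
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        assert np.allclose(normalize_log(c1, f).values, normalize_log(c2, f).values)

    def test_spot_check_arithmetic(self):
        counts = pd.DataFrame({"a": [25, 75], "b": [50, 50]})
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        norm = normalize_log(counts, f, pseudocount=0.5)
        assert norm.values.iloc[0, 0] == pytest.approx(np.log2(25 / 100 * 1e6 + 0.5))

    def test_rejects_nonpositive_pseudocount(self):
        with pytest.raises(ValueError):
            normalize_log(pd.DataFrame({"a": [1, 2], "b": [3, 4]}), pseudocount=0.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            NormalizedMatrix(values=pd.DataFrame({"a": [1.0]}),
                             lib_size=pd.Series({"a": 10.0}),
                             tmm_factors=pd.Series({"a": -1.0}))


# ----------------------------------------------------------- consensus peaks

def _base_oracle(peak_sets, min_support, length=100_000):
    depth = np.zeros(length, dtype=int)
    for df in peak_sets.values():
        cov = np.zeros(length, dtype=bool)
        for _, r in df.iterrows():
            cov[r.start:r.end] = True
        depth += cov
    ok = depth >= min_support
    rows, i = [], 0
    while i < length:
        if ok[i]:
            j = i
            while j < length and ok[j]:
                j += 1
            rows.append(("chr1", i, j))
            i = j
        else:
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestConsensusPeaks:
    def test_identical_peaks(self):
        ps = {s: pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
              for s in "abc"}
        got = consensus_peaks(ps, min_support=2)
        assert got.values.tolist() == [["chr1", 100, 200]]

    def test_disjoint_peaks_no_consensus(self):
        ps = {s: pd.DataFrame({"chrom": ["chr1"], "start": [i * 1000], "end": [i * 1000 + 100]})
              for i, s in enumerate("abc")}
        assert consensus_peaks(ps, min_support=2).empty

    @pytest.mark.parametrize("min_support", [1, 2, 3, 4])
    def test_matches_base_resolution_oracle(self, rng, min_support):
        ps = jittered_peak_sets(rng, n_samples=5, n_sites=15, chrom_len=100_000)
        got = consensus_peaks(ps, min_support).reset_index(drop=True)
        assert got.equals(_base_oracle(ps, min_support))

    def test_base_level_monotone_shrinkage(self, rng):
        # raising min_support can only shrink the covered base set
        ps = jittered_peak_sets(rng, n_samples=6, n_sites=25, chrom_len=200_000)
        covered = []
        for n in (1, 2, 3):
            bases = set()
            for _, r in consensus_peaks(ps, n).iterrows():
                bases.update(range(r.start, r.end))
            covered.append(bases)
        assert covered[2] <= covered[1] <= covered[0]

    def test_output_sorted_disjoint(self, rng):
        got = consensus_peaks(jittered_peak_sets(rng), 2)
        starts, ends = got["start"].to_numpy(), got["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()

    def test_empty_input(self):
        assert consensus_peaks({}, 1).empty


class TestOccupancyCurve:
    def test_identical_peak_everywhere(self):
        ps = {s: pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [99]})
              for s in "abcd"}
        assert occupancy_curve(ps).tolist() == [1, 1, 1, 1]

    def test_all_disjoint(self):
        ps = {f"s{i}": pd.DataFrame({"chrom": ["chr1"], "start": [i * 500], "end": [i * 500 + 50]})
              for i in range(4)}
        assert occupancy_curve(ps).tolist() == [4, 0, 0, 0]

    def test_matches_repeated_consensus_calls(self, rng):
        ps = jittered_peak_sets(rng, n_samples=6)
        curve = occupancy_curve(ps)
        for n in range(1, 7):
            assert curve[n] == len(consensus_peaks(ps, n))
        assert (np.diff(curve) <= 0).all()  # site-centered peaks: non-increasing


# --------------------------------------------------------- read/region ops

class TestCountReadsInRegions:
    REGION = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})

    def test_exact_match_counts_once(self):
        reads = {"s": pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})}
        assert count_reads_in_regions(reads, self.REGION).iloc[0, 0] == 1

    def test_half_open_abutment_is_no_overlap(self):
        reads = {"s": pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [100]})}
        assert count_reads_in_regions(reads, self.REGION).iloc[0, 0] == 0

    def test_matches_all_pairs_oracle(self, rng):
        starts = rng.integers(0, 9_900, 1000)
        reads = {"s": pd.DataFrame({"chrom": "chr1", "start": starts,
                                    "end": starts + rng.integers(30, 120, 1000)})}
        gs = rng.integers(0, 9_500, 100)
        regions = pd.DataFrame({"chrom": "chr1", "start": gs,
                                "end": gs + rng.integers(100, 500, 100)})
        got = count_reads_in_regions(reads, regions)
        df = reads["s"]
        for i, (_, r) in enumerate(regions.iterrows()):
            assert got.iloc[i, 0] == ((df.start < r.end) & (df.end > r.start)).sum()

    def test_unknown_chromosome_warned_and_skipped(self):
        reads = {"s": pd.DataFrame({"chrom": ["chrUn"], "start": [0], "end": [10]})}
        with pytest.warns(UserWarning, match="chrUn"):
            got = count_reads_in_regions(reads, self.REGION)
        assert got.iloc[0, 0] == 0


class TestFrip:
    def test_all_reads_in_peaks(self):
        reads = {"s": pd.DataFrame({"chrom": ["chr1"] * 3, "start": [10, 20, 30],
                                    "end": [40, 50, 60]})}
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        assert frip(reads, peaks)["s"] == 1.0

    def test_no_peaks(self):
        reads = {"s": pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [40]})}
        peaks = pd.DataFrame(columns=["chrom", "start", "end"])
        assert frip(reads, peaks)["s"] == 0.0

    def test_matches_brute_force(self, rng):
        starts = rng.integers(0, 9_900, 300)
        reads = {"s": pd.DataFrame({"chrom": "chr1", "start": starts,
                                    "end": starts + 50})}
        ps = rng.integers(0, 9_500, 20)
        peaks = pd.DataFrame({"chrom": "chr1", "start": ps, "end": ps + 300})
        got = frip(reads, peaks)["s"]
        df = reads["s"]
        brute = np.mean([((peaks.start < e) & (peaks.end > s)).any()
                         for s, e in zip(df.start, df.end)])
        assert got == pytest.approx(brute)

    def test_zero_reads_is_missing(self):
        reads = {"s": pd.DataFrame(columns=["chrom", "start", "end"])}
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        with pytest.warns(UserWarning, match="zero reads"):
            assert np.isnan(frip(reads, peaks)["s"])

    def test_qc_metrics_bundle(self, rng):
        ps = jittered_peak_sets(rng, n_samples=2)
        starts = rng.integers(0, 900_000, 100)
        reads = {s: pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 65})
                 for s in ps}
        qc = qc_metrics(reads, ps)
        assert ((qc.frip >= 0) & (qc.frip <= 1)).all()
        assert (qc.n_reads == 100).all()


# ----------------------------------------------------------------- mad_select

class TestMadSelect:
    def test_hand_computed_mad(self):
        df = pd.DataFrame([[1, 2, 3, 4, 100]], index=["g"], dtype=float)
        sel = mad_select(df, top_n=1)
        assert sel.mad["g"] == 1.0  # median 3; |x-3| = {2,1,0,1,97}; median 1

    def test_constant_feature_ranked_last(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 9.0]], index=["flat", "varying"])
        sel = mad_select(df, top_n=2)
        assert sel.selected.tolist() == [1, 0]

    def test_permuting_samples_leaves_selection_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 8)))
        sel1 = mad_select(df, top_n=10)
        perm = rng.permutation(8)
        sel2 = mad_select(df.iloc[:, perm], top_n=10)
        assert sel1.selected.tolist() == sel2.selected.tolist()

    def test_matches_exhaustive_definition(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 7)))
        sel = mad_select(df, top_n=5)
        x = df.to_numpy()
        mads = [np.median(np.abs(row - np.median(row))) for row in x]
        expected = sorted(range(25), key=lambda i: (-mads[i], i))[:5]
        assert sel.selected.tolist() == expected

    def test_top_n_exceeding_features_warns_and_returns_all(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 6)))
        with pytest.warns(UserWarning, match="exceeds"):
            sel = mad_select(df, top_n=10)
        assert len(sel.selected) == 4
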