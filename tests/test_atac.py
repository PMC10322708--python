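"""Clone ATAC analysis: merging, normalization, background matching,
permutation test, flagging, per-copy expression."""

import numpy as np
import pandas as pd
import pytest

import hapdose as h
from hapdose.atac import local_copy_number


def peaks_df(rows, gc=None):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if gc is not None:
        df["gc"] = gc
    return df


class TestMergePeaks:
    def test_within_400bp_merged(self):
        out = h.merge_peaks(peaks_df([("chr1", 0, 100), ("chr1", 400, 500)]))
        assert len(out) == 1
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == 500

    def test_401bp_apart_stay_separate(self):
        out = h.merge_peaks(peaks_df([("chr1", 0, 100), ("chr1", 501, 600)]))
        assert len(out) == 2

    def test_transitive_chain_collapses(self):
        # oracle: brute-force union-find over the pairwise gap relation
        rows = [("chr1", 0, 100), ("chr1", 400, 500), ("chr1", 800, 900),
                ("chr1", 5000, 5100)]
        out = h.merge_peaks(peaks_df(rows))

        parent = list(range(len(rows)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                gap = rows[j][1] - rows[i][2]
                if gap <= 400:
                    parent[find(j)] = find(i)
        n_components = len({find(i) for i in range(len(rows))})
        assert len(out) == n_components == 2

    def test_gc_length_weighted(self):
        out = h.merge_peaks(
            peaks_df([("chr1", 0, 300), ("chr1", 400, 500)], gc=[0.4, 0.8])
        )
        assert out.iloc[0]["gc"] == pytest.approx((0.4 * 300 + 0.8 * 100) / 400)

    def test_unsorted_input_warned_and_sorted(self):
        with pytest.warns(UserWarning, match="sort"):
            out = h.merge_peaks(peaks_df([("chr1", 5000, 5100), ("chr1", 0, 100)]))
        assert out["start"].tolist() == [0, 5000]

    def test_post_merge_gaps_exceed_400(self):
        rng = np.random.default_rng(8)
        starts = np.sort(rng.integers(0, 1_000_000, 300))
        out = h.merge_peaks(peaks_df([("chr1", s, s + 150) for s in starts]))
        gaps = out["start"].to_numpy()[1:] - out["end"].to_numpy()[:-1]
        assert (gaps > 400).all()


class TestNormalizeCounts:
    def test_identical_columns_unchanged(self):
        vals = np.arange(1.0, 21.0)
        counts = pd.DataFrame({"a": vals, "b": vals})
        out = h.quantile_normalize(counts)
        pd.testing.assert_frame_equal(out, counts)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, size=(200, 4)), columns=list("abcd"))
        out = h.quantile_normalize(counts)
        for c in counts:
            assert (
                counts[c].rank(method="average") == out[c].rank(method="average")
            ).all()

    def test_cn1_region_doubled(self):
        peaks = peaks_df([("chr1", 0, 300), ("chr1", 500_000, 500_300)])
        peaks["peak_id"] = ["p0", "p1"]
        counts = pd.DataFrame({"s1": [10.0, 10.0]}, index=["p0", "p1"])
        cn = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 250_000],
                "end": [250_000, 1_000_000],
                "sample": ["s1", "s1"],
                "copy_number": [1, 2],
            }
        )
        out = h.normalize_counts(counts, peaks, cn)
        assert out.loc["p0", "s1"] == pytest.approx(2 * out.loc["p1", "s1"])

    def test_cn0_region_masked(self):
        peaks = peaks_df([("chr1", 0, 300)])
        peaks["peak_id"] = ["p0"]
        counts = pd.DataFrame({"s1": [10.0]}, index=["p0"])
        cn = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [250_000],
             "sample": ["s1"], "copy_number": [0]}
        )
        out = h.normalize_counts(counts, peaks, cn)
        assert np.isnan(out.loc["p0", "s1"])


SMALL_GENOME = {f"chr{i + 1}": 20_000_000 for i in range(5)}
SMALL_INTERVAL = ("chr4", 5_000_000, 15_000_000)


@pytest.fixture(scope="module")
def atac_data():
    return h.simulate_atac_clones(
        n_peaks=4000, n_control_clones=5, n_case_clones=3,
        suppression_factor=0.5, seed=17, chrom_lengths=SMALL_GENOME,
        suppressed_interval=SMALL_INTERVAL,
    )


@pytest.fixture(scope="module")
def atac_norm(atac_data):
    return h.normalize_counts(atac_data["counts"], atac_data["peaks"], atac_data["cn"])


@pytest.fixture(scope="module")
def bg_sets(atac_data, atac_norm):
    ctrl = atac_norm[atac_data["truth"]["control_samples"]].mean(axis=1).to_numpy()
    return h.select_background_peaks(atac_data["peaks"], ctrl, k=50, seed=2)


class TestBackgroundPeaks:
    def test_exactly_k_distinct_entries(self, bg_sets):
        assert bg_sets.shape[1] == 50
        assert all(len(set(row)) == 50 for row in bg_sets[:200])

    def test_self_exclusion(self, bg_sets):
        n = bg_sets.shape[0]
        assert not (bg_sets == np.arange(n)[:, None]).any()

    def test_gc_matching_quality(self, atac_data, bg_sets):
        gc = atac_data["peaks"]["gc"].to_numpy()
        diffs = np.abs(gc[bg_sets].mean(axis=1) - gc)
        assert diffs.mean() < 0.05

    def test_too_few_peaks_rejected(self):
        peaks = peaks_df([("chr1", i * 1000, i * 1000 + 300) for i in range(100)])
        peaks["gc"] = 0.5
        with pytest.raises(ValueError, match="500"):
            h.select_background_peaks(peaks, np.ones(100), k=50)

    def test_seeded_determinism(self, atac_data, atac_norm):
        ctrl = atac_norm[atac_data["truth"]["control_samples"]].mean(axis=1).to_numpy()
        a = h.select_background_peaks(atac_data["peaks"], ctrl, k=20, seed=5)
        b = h.select_background_peaks(atac_data["peaks"], ctrl, k=20, seed=5)
        np.testing.assert_array_equal(a, b)


INTERVAL = ("chr4", 5_000_000, 15_000_000)


class TestPermutationTest:
    def test_permutation_space_of_minimal_interval(self):
        # 10 peaks, 50 replicates each -> 50^10 ~ 9.8e16 possible profiles
        assert float(50) ** 10 == pytest.approx(9.8e16, rel=0.005)

    def test_reported_space_matches_peak_count(self, atac_data, atac_norm, bg_sets):
        s = atac_data["truth"]["case_samples"][0]
        res = h.interval_permutation_test(
            atac_norm[s].to_numpy(), atac_data["peaks"],
            ("chr1", 5_000_000, 6_000_000), bg_sets, n_perm=2000, seed=1,
            sample=s,
        )
        assert np.log(res.perm_space) == pytest.approx(res.n_peaks * np.log(50.0))

    def test_suppressed_interval_detected(self, atac_data, atac_norm, bg_sets):
        s = atac_data["truth"]["case_samples"][0]
        res = h.interval_permutation_test(
            atac_norm[s].to_numpy(), atac_data["peaks"], INTERVAL, bg_sets,
            n_perm=10_000, seed=1, sample=s,
        )
        assert res.fold_change == pytest.approx(0.5, abs=0.08)
        assert res.p == pytest.approx(1 / 10_001, rel=1e-6)  # attainable floor

    def test_null_interval_fold_change_near_one(self, atac_data, atac_norm, bg_sets):
        s = atac_data["truth"]["control_samples"][0]
        res = h.interval_permutation_test(
            atac_norm[s].to_numpy(), atac_data["peaks"], ("chr2", 5_000_000, 15_000_000),
            bg_sets, n_perm=5000, seed=2, sample=s,
        )
        assert res.fold_change == pytest.approx(1.0, abs=0.1)
        assert res.p > 0.01

    def test_scale_invariance_of_p(self, atac_data, atac_norm, bg_sets):
        s = atac_data["truth"]["case_samples"][0]
        vals = atac_norm[s].to_numpy()
        r1 = h.interval_permutation_test(
            vals, atac_data["peaks"], ("chr1", 5_000_000, 15_000_000), bg_sets,
            n_perm=3000, seed=3, sample=s,
        )
        r2 = h.interval_permutation_test(
            vals * 37.5, atac_data["peaks"], ("chr1", 5_000_000, 15_000_000), bg_sets,
            n_perm=3000, seed=3, sample=s,
        )
        assert r1.p == r2.p
        assert r1.fold_change == pytest.approx(r2.fold_change, rel=1e-12)

    def test_ineligible_interval_skipped(self, atac_data, atac_norm, bg_sets):
        s = atac_data["truth"]["control_samples"][0]
        sparse = peaks_df([("chr9", 0, 300)])
        sparse["gc"] = 0.5
        res = h.interval_permutation_test(
            np.ones(1), sparse, ("chr9", 0, 10_000_000), bg_sets[:1],
            n_perm=100, seed=0,
        )
        assert res is None

    def test_fold_change_independent_of_n_perm(self, atac_data, atac_norm, bg_sets):
        s = atac_data["truth"]["case_samples"][0]
        vals = atac_norm[s].to_numpy()
        r1 = h.interval_permutation_test(
            vals, atac_data["peaks"], INTERVAL, bg_sets, n_perm=2000, seed=4,
        )
        r2 = h.interval_permutation_test(
            vals, atac_data["peaks"], INTERVAL, bg_sets, n_perm=8000, seed=4,
        )
        assert r1.observed == r2.observed
        assert r1.fold_change == r2.fold_change  # exact: analytic null mean


class TestFlagging:
    def test_strict_070_boundary(self):
        res = pd.DataFrame(
            {
                "chrom": ["chr1"] * 2, "start": [0, 10], "end": [10, 20],
                "sample": ["s1", "s1"], "n_peaks": [20, 20],
                "observed": [1, 1], "null_mean": [1, 1],
                "fold_change": [0.70, 0.699], "p": [1e-5, 1e-5],
                "n_perm": [1000, 1000], "perm_space": [1e16, 1e16],
            }
        )
        out = h.flag_suppressed_intervals(res)
        assert out["flagged"].tolist() == [False, True]

    def test_requires_significance_too(self):
        res = pd.DataFrame(
            {
                "chrom": ["chr1"], "start": [0], "end": [10],
                "sample": ["s1"], "n_peaks": [20],
                "observed": [1], "null_mean": [1],
                "fold_change": [0.5], "p": [0.5],
                "n_perm": [1000], "perm_space": [1e16],
            }
        )
        assert not h.flag_suppressed_intervals(res)["flagged"].any()

    def test_recovery_in_suppressed_clones_only(self):
        data = h.simulate_atac_clones(
            n_peaks=4000, n_control_clones=5, n_case_clones=4,
            suppression_factor=0.5, seed=23, chrom_lengths=SMALL_GENOME,
            suppressed_interval=SMALL_INTERVAL,
            suppressed_samples=["case_clone_01", "case_clone_03"],
        )
        norm = h.normalize_counts(data["counts"], data["peaks"], data["cn"])
        ctrl = norm[data["truth"]["control_samples"]].mean(axis=1).to_numpy()
        sets = h.select_background_peaks(data["peaks"], ctrl, k=50, seed=3)
        rows = []
        for s in data["truth"]["case_samples"]:
            res = h.interval_permutation_test(
                norm[s].to_numpy(), data["peaks"], INTERVAL, sets,
                n_perm=10_000, seed=5, sample=s,
            )
            rows.append(res.as_dict())
        out = h.flag_suppressed_intervals(pd.DataFrame(rows))
        flagged = set(out.loc[out["flagged"], "sample"])
        assert flagged == {"case_clone_01", "case_clone_03"}


class TestPerCopyExpression:
    def _setup(self, clone_gb_cn=1):
        # five genes; only gB sits in a 250-kb bin whose copy number differs
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2", "chr2", "chr2"],
                "start": [0, 500_000, 0, 300_000, 600_000],
                "end": [1000, 501_000, 1000, 301_000, 601_000],
            },
            index=["gA", "gB", "gC", "gD", "gE"],
        )
        cn_rows = []
        for sample in ("parent", "clone"):
            for chrom, start in [("chr1", 0), ("chr1", 500_000), ("chr2", 0),
                                 ("chr2", 250_000), ("chr2", 500_000)]:
                value = (
                    clone_gb_cn
                    if sample == "clone" and (chrom, start) == ("chr1", 500_000)
                    else 2
                )
                cn_rows.append((chrom, start, start + 250_000, sample, value))
        cn = pd.DataFrame(
            cn_rows, columns=["chrom", "start", "end", "sample", "copy_number"]
        )
        parent_tpm = [10.0, 20.0, 30.0, 40.0, 50.0]
        return genes, cn, parent_tpm

    def test_identical_sample_ratios_one(self):
        genes, cn, base = self._setup(clone_gb_cn=2)
        tpm = pd.DataFrame({"parent": base, "clone": base}, index=genes.index)
        out = h.per_copy_expression(tpm, genes, cn, parent="parent")
        assert np.allclose(out["clone"], 1.0)

    def test_cn_loss_with_halved_tpm_is_dosage_explained(self):
        genes, cn, base = self._setup(clone_gb_cn=1)
        clone = list(base)
        clone[1] = base[1] / 2  # gB halved, matching its CN 1
        tpm = pd.DataFrame({"parent": base, "clone": clone}, index=genes.index)
        out = h.per_copy_expression(tpm, genes, cn, parent="parent")
        assert out.loc["gB", "clone"] == pytest.approx(1.0, abs=1e-9)

    def test_halved_tpm_at_normal_cn_is_suppression(self):
        genes, cn, base = self._setup(clone_gb_cn=2)
        clone = list(base)
        clone[1] = base[1] / 2  # gB halved with CN still 2: epigenetic signature
        tpm = pd.DataFrame({"parent": base, "clone": clone}, index=genes.index)
        out = h.per_copy_expression(tpm, genes, cn, parent="parent")
        assert out.loc["gB", "clone"] == pytest.approx(0.5, abs=1e-9)

    def test_cn_zero_masked(self):
        genes, cn, base = self._setup(clone_gb_cn=0)
        tpm = pd.DataFrame({"parent": base, "clone": base}, index=genes.index)
        out = h.per_copy_expression(tpm, genes, cn, parent="parent")
        assert np.isnan(out.loc["gB", "clone"])

    def test_unknown_parent_rejected(self):
        genes, cn, base = self._setup()
        tpm = pd.DataFrame({"s": base}, index=genes.index)
        with pytest.raises(ValueError, match="parent"):
            h.per_copy_expression(tpm, genes, cn, parent="nope")
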