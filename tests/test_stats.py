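import itertools

import numpy as np
import pandas as pd
import pytest

from semiconn.core import ConnectomeError, RegionTable
from semiconn.stats import bh_fdr, compare_groups, rejection_counts, wilcoxon_rank_sum

from oracles import exact_wilcoxon_two_sided, stepup_bh


class TestWilcoxonRankSum:
    def test_separated_samples_exact_p(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert stat == 6.0  # ranks 1+2+3

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 5.0], [5.0, 1.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_symmetric_under_swap(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(0.5, 1, size=9)
        _, p_xy = wilcoxon_rank_sum(x, y)
        _, p_yx = wilcoxon_rank_sum(y, x)
        assert p_xy == pytest.approx(p_yx, rel=1e-12)

    def test_all_values_identical_convention(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ConnectomeError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_enumeration_all_small_sizes(self, rng):
        # full-assignment oracle over every n, m <= 6
        for n, m in itertools.product(range(1, 7), repeat=2):
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            x, y = vals[:n], vals[n:]
            stat, p = wilcoxon_rank_sum(x, y, mode="exact")
            stat_o, p_o = exact_wilcoxon_two_sided(x, y)
            assert stat == stat_o
            assert p == pytest.approx(p_o, rel=1e-12), (n, m)

    def test_auto_switches_to_tie_corrected_approximation(self):
        x = [1.0, 1.0, 2.0, 3.0] * 4
        y = [2.0, 3.0, 3.0, 4.0] * 4
        stat, p = wilcoxon_rank_sum(x, y, mode="auto")
        import scipy.stats as sps

        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0], mode="bogus")


class TestBHFDR:
    def test_all_rejected_when_uniformly_small(self):
        q, reject = bh_fdr([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert reject.all()

    def test_single_p_passes_through(self):
        q, reject = bh_fdr([0.04], alpha=0.05)
        assert q[0] == pytest.approx(0.04)
        assert reject[0]

    def test_large_ps_not_rejected(self):
        _, reject = bh_fdr([0.5, 0.9], alpha=0.05)
        assert not reject.any()

    def test_matches_stepup_definition(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1, size=m)
            q, _ = bh_fdr(p)
            np.testing.assert_allclose(q, stepup_bh(p), rtol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = np.sort(rng.uniform(0, 1, size=25))
        q, _ = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-15)

    def test_no_more_conservative_than_bonferroni(self, rng):
        for _ in range(10):
            p = rng.uniform(1e-6, 1, size=15)
            q, reject = bh_fdr(p, alpha=0.05)
            bonf = p <= 0.05 / len(p)
            assert np.all(reject[bonf])

    def test_invalid_input_rejected(self):
        with pytest.raises(ConnectomeError):
            bh_fdr([])
        with pytest.raises(ConnectomeError):
            bh_fdr([0.0, 0.5])


def _toy_cohort(rng, n_per=8, n_nodes=6, shift=0.0):
    """Hand-assembled cohort frames with an optional smr_left group shift."""
    regions = RegionTable.generic(n_nodes)
    ids = [f"s{i:02d}" for i in range(2 * n_per)]
    groups = pd.Series(["low"] * n_per + ["high"] * n_per, index=ids)
    cols = ["smr_global", "smr_left", "smr_right", "smr_inter", "bai",
            "smp_global", "smp_left", "smp_right"]
    summaries = pd.DataFrame(
        rng.uniform(0.2, 0.6, size=(2 * n_per, len(cols))), index=ids, columns=cols
    )
    summaries.loc[groups == "high", "smr_left"] += shift
    smp_nodes = pd.DataFrame(
        rng.uniform(0, 1, size=(2 * n_per, n_nodes)), index=ids, columns=regions.names
    )
    stack = np.full((2 * n_per, n_nodes, n_nodes), np.nan)
    iu, ju = np.triu_indices(n_nodes, k=1)
    for s in range(2 * n_per):
        present = rng.random(len(iu)) < 0.8
        vals = 1 + rng.exponential(0.5, size=present.sum())
        stack[s, iu[present], ju[present]] = vals
        stack[s, ju[present], iu[present]] = vals
    descriptors = pd.DataFrame(
        rng.uniform(0, 1, size=(2 * n_per, 5)),
        index=ids,
        columns=["sparsity", "global_strength", "left_strength", "right_strength",
                 "inter_strength"],
    )
    bai_vol = pd.DataFrame(
        rng.normal(1, 0.05, size=(2 * n_per, 3)),
        index=ids,
        columns=["whole_brain", "language", "subcortical"],
    )
    return groups, summaries, smp_nodes, stack, regions, descriptors, bai_vol


class TestCompareGroups:
    def test_family_layout(self, rng):
        groups, summaries, smp, stack, regions, desc, bv = _toy_cohort(rng)
        fams = compare_groups(groups, summaries, smp, stack, regions,
                              descriptors=desc, bai_vol=bv)
        assert set(fams) == {"smr_edges", "smr_scales", "smp_scales",
                             "smp_nodes", "descriptors", "bai_vol"}
        assert list(fams["smr_scales"]["label"]) == [
            "smr_global", "smr_left", "smr_right", "smr_inter", "bai"]
        assert list(fams["smp_scales"]["label"]) == [
            "smp_global", "smp_left", "smp_right"]
        assert len(fams["smp_nodes"]) == regions.n
        assert len(fams["descriptors"]) == 5
        assert len(fams["bai_vol"]) == 3
        counts = rejection_counts(fams)
        assert counts["smr_scales"]["n_comparisons"] == 5

    def test_injected_shift_detected_with_direction(self, rng):
        groups, summaries, smp, stack, regions, desc, bv = _toy_cohort(
            rng, n_per=20, shift=0.6
        )
        fams = compare_groups(groups, summaries, smp, stack, regions)
        row = fams["smr_scales"].set_index("label").loc["smr_left"]
        assert row["significant"]
        assert row["direction"] == "high>low"

    def test_uncorrected_families_use_raw_p(self, rng):
        groups, summaries, smp, stack, regions, desc, bv = _toy_cohort(rng)
        fams = compare_groups(groups, summaries, smp, stack, regions,
                              descriptors=desc, bai_vol=bv)
        for fid in ("descriptors", "bai_vol"):
            df = fams[fid]
            np.testing.assert_array_equal(df["q_bh"], df["p_raw"])

    def test_rare_edges_excluded_by_presence_rule(self, rng):
        groups, summaries, smp, stack, regions, desc, bv = _toy_cohort(rng, n_per=10)
        # make edge (0, 1) present in only one subject per group
        stack[:, 0, 1] = np.nan
        stack[:, 1, 0] = np.nan
        stack[0, 0, 1] = stack[0, 1, 0] = 1.5
        stack[10, 0, 1] = stack[10, 1, 0] = 1.5
        fams = compare_groups(groups, summaries, smp, stack, regions)
        label = f"{regions.names[0]}--{regions.names[1]}"
        assert label not in set(fams["smr_edges"]["label"])

    def test_missing_values_dropped_per_comparison(self, rng):
        groups, summaries, smp, stack, regions, desc, bv = _toy_cohort(rng, n_per=10)
        # BAI missing for all but one subject per group: comparison dropped
        summaries.loc[summaries.index[1:10], "bai"] = np.nan
        summaries.loc[summaries.index[11:], "bai"] = np.nan
        fams = compare_groups(groups, summaries, smp, stack, regions)
        assert "bai" not in set(fams["smr_scales"]["label"])
        assert len(fams["smr_scales"]) == 4

    def test_requires_two_groups_and_two_subjects(self, rng):
        groups, summaries, smp, stack, regions, *_ = _toy_cohort(rng, n_per=4)
        with pytest.raises(ConnectomeError, match="low"):
            compare_groups(groups.replace("high", "low"), summaries, smp, stack, regions)
        small = groups.copy()
        small.iloc[:7] = "low"  # leaves one high subject
        with pytest.raises(ConnectomeError, match="two subjects"):
            compare_groups(small, summaries, smp, stack, regions)
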