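"""Sliding windows, enrichment, resampling nulls and regimen comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from lekscan.data import DesignSpec
from lekscan.windows import (
    arm_distribution_test,
    build_windows,
    ld_decay_profile,
    locus_he,
    p_s_less_f,
    regimen_ttest,
    starting_freq_test,
    window_enrichment,
    window_mean_he,
)


def test_locus_he_values():
    assert locus_he(0.5) == 0.5
    assert locus_he(0.0) == 0.0
    assert locus_he(0.077) == pytest.approx(0.142142, abs=1e-6)
    p = np.linspace(0, 1, 11)
    np.testing.assert_allclose(locus_he(p), locus_he(1 - p))


class TestBuildWindows:
    def test_window_counts_by_extent(self):
        assert len(build_windows({"2L": (1, 100_000)})) == 6
        assert len(build_windows({"2L": (1, 50_000)})) == 1
        short = build_windows({"2L": (1, 49_999)})
        assert len(short) == 1
        assert (short["end"] - short["start"]).iloc[0] == 49_999

    def test_anchored_at_first_locus(self):
        win = build_windows({"3R": (200_001, 300_000)})
        assert win["start"].iloc[0] == 200_000
        assert win["end"].iloc[-1] == 300_000

    def test_overlap_and_locus_membership(self):
        win = build_windows({"2L": (1, 200_000)})
        starts = win["start"].to_numpy()
        assert (np.diff(starts) == 10_000).all()
        # any interior position falls in exactly 5 windows of 50kb/10kb
        x = 123_456
        n_containing = ((win["start"] <= x) & (x < win["end"])).sum()
        assert n_containing == 5


class TestWindowMeanHe:
    def _loci(self, positions, chrom="2L"):
        return pd.DataFrame({"chrom": chrom, "pos": positions})

    def test_simple_mean(self):
        win = build_windows({"2L": (1, 50_000)})
        loci = self._loci([10, 20, 30])
        he = np.array([[0.1], [0.2], [0.3]])
        out = window_mean_he(win, loci, he, ["L1"])
        assert out["n"].iloc[0] == 3
        assert out["he_L1"].iloc[0] == pytest.approx(0.2)

    def test_empty_window_is_missing(self):
        win = build_windows({"2L": (1, 120_000)})
        loci = self._loci([1, 2, 3])
        he = np.full((3, 1), 0.4)
        out = window_mean_he(win, loci, he, ["L1"])
        assert np.isnan(out["he_L1"].iloc[-1])
        assert out["n"].iloc[-1] == 0

    def test_matches_brute_force_on_random_layouts(self, rng):
        for _ in range(50):
            pos = np.sort(rng.choice(np.arange(1, 150_000), size=80,
                                     replace=False))
            he = rng.uniform(0, 0.5, size=(80, 3))
            loci = self._loci(pos)
            win = build_windows({"2L": (int(pos.min()), int(pos.max()))})
            out = window_mean_he(win, loci, he, ["a", "b", "c"])
            for _, row in out.iterrows():
                inside = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
                assert row["n"] == inside.sum()
                if inside.any():
                    np.testing.assert_allclose(
                        [row["he_a"], row["he_b"], row["he_c"]],
                        he[inside].mean(axis=0),
                    )


class TestEnrichment:
    def brute_force_upper_tail(self, s, N, K, n):
        """Exhaustive hypergeometric enumeration."""
        total = 0.0
        for x in range(max(0, n + K - N), min(n, K) + 1):
            if x >= s:
                total += (
                    math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
                )
        return total

    def test_example_window(self):
        assert self.brute_force_upper_tail(2, 100, 5, 3) == pytest.approx(
            0.00593, abs=5e-5
        )
        win = pd.DataFrame({"chrom": ["2L"], "start": [0], "end": [3000]})
        pos = [100, 200, 300] + list(range(5000, 5000 + 97 * 29, 29))
        loci = pd.DataFrame({"chrom": "2L", "pos": sorted(pos)})
        sdv = np.zeros(100, dtype=bool)
        sdv[[0, 1]] = True  # both inside the window; arm: N=100, K=...
        sdv[50] = True      # plus 3 more elsewhere to make K=5
        sdv[60] = True
        sdv[70] = True
        out = window_enrichment(win, loci, sdv)
        assert out["n"].iloc[0] == 3 and out["s"].iloc[0] == 2
        assert out["enrich_p"].iloc[0] == pytest.approx(
            self.brute_force_upper_tail(2, 100, 5, 3), rel=1e-10
        )

    def test_zero_sdvs_give_p_one(self):
        win = pd.DataFrame({"chrom": ["2L"], "start": [0], "end": [1000]})
        loci = pd.DataFrame({"chrom": "2L", "pos": [10, 20]})
        out = window_enrichment(win, loci, np.zeros(2, dtype=bool))
        assert out["enrich_p"].iloc[0] == 1.0

    def test_forced_outcome_p_one(self):
        win = pd.DataFrame({"chrom": ["2L"], "start": [0], "end": [1000]})
        loci = pd.DataFrame({"chrom": "2L", "pos": [10, 20]})
        out = window_enrichment(win, loci, np.ones(2, dtype=bool))
        assert out["enrich_p"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_for_small_arms(self, rng):
        from scipy.stats import hypergeom

        for N in range(1, 26):
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            for s in range(0, min(n, K) + 1):
                np.testing.assert_allclose(
                    hypergeom.sf(s - 1, N, K, n),
                    self.brute_force_upper_tail(s, N, K, n),
                    atol=1e-12,
                )


class TestArmDistribution:
    def test_concentrated_windows_flagged(self, rng):
        all_arms = ["2L"] * 2400 + ["2R"] * 2400 + ["3L"] * 2400 + \
            ["3R"] * 2400 + ["X"] * 2400
        sig = ["2R"] * 57
        res = arm_distribution_test(sig, all_arms, rng=rng)
        res = res.set_index("arm")
        assert res.loc["2R", "status"] == "over"
        assert (res.drop("2R")["status"] == "under").all()

    def test_uniform_sampling_rarely_flags(self, rng):
        all_arms = np.repeat(["2L", "2R", "3L", "3R", "X"], 400)
        n_flagged = 0
        n_sets = 200
        for _ in range(n_sets):
            sig = rng.choice(all_arms, size=40, replace=False)
            res = arm_distribution_test(sig, all_arms, n_resamples=400,
                                        rng=rng)
            n_flagged += (res["status"] != "ok").any()
        # each arm is inside its own 95% interval ~95% of the time; with 5
        # arms per set, a no-flag set is still the common outcome
        assert n_flagged / n_sets < 0.45

    def test_single_significant_window(self, rng):
        res = arm_distribution_test(["2L"], ["2L"] * 5 + ["2R"] * 5, rng=rng)
        assert set(res["status"]) <= {"ok", "under", "over"}
        assert res["observed"].sum() == 1

    def test_oversized_set_errors(self, rng):
        with pytest.raises(ValueError, match="more significant"):
            arm_distribution_test(["2L"] * 3, ["2L"] * 2, rng=rng)


class TestRegimenTTest:
    def test_identical_medians(self):
        res = regimen_ttest([0.2] * 4, [0.2] * 4)
        assert res.t == 0.0 and res.p_value == 1.0

    def test_hand_computed_example(self):
        res = regimen_ttest([2, 3, 4, 5], [1, 2, 3, 4])
        assert res.t == pytest.approx(-1.0954, abs=1e-4)
        assert res.df == 6

    def test_df_is_six_for_4_plus_4(self, rng):
        res = regimen_ttest(rng.uniform(size=4), rng.uniform(size=4))
        assert res.df == 6

    def test_zero_variance_unequal_means_degenerate(self):
        res = regimen_ttest([0.1] * 4, [0.3] * 4)
        assert res.degenerate and res.p_value == 0.0
        assert res.t == np.inf  # failure minus success is positive


class TestPSLessF:
    def _design(self):
        return DesignSpec(
            {**{f"S{i}": "success" for i in range(1, 5)},
             **{f"F{i}": "failure" for i in range(1, 5)}}
        )

    def test_all_success_lower(self):
        line_ids = [f"S{i}" for i in range(1, 5)] + [f"F{i}" for i in
                                                     range(1, 5)]
        he = np.c_[np.full((10, 4), 0.1), np.full((10, 4), 0.3)]
        mask = np.ones(10, dtype=bool)
        assert p_s_less_f(he, mask, line_ids, self._design()) == 1.0

    def test_label_swap_symmetry_with_ties(self, rng):
        line_ids = [f"S{i}" for i in range(1, 5)] + [f"F{i}" for i in
                                                     range(1, 5)]
        he = rng.uniform(0, 0.5, size=(200, 8))
        he[:20, 4:] = he[:20, :4]  # 10% exact ties
        mask = np.ones(200, dtype=bool)
        design = self._design()
        swapped = DesignSpec(
            {**{f"S{i}": "failure" for i in range(1, 5)},
             **{f"F{i}": "success" for i in range(1, 5)}}
        )
        p = p_s_less_f(he, mask, line_ids, design)
        p_swap = p_s_less_f(he, mask, line_ids, swapped)
        ties = np.mean(
            he[:, :4].mean(axis=1) == he[:, 4:].mean(axis=1)
        )
        assert p + p_swap + ties == pytest.approx(1.0)

    def test_no_diffstat_loci_errors(self):
        with pytest.raises(ValueError, match="no DiffStat"):
            p_s_less_f(np.zeros((5, 8)), np.zeros(5, dtype=bool),
                       [f"L{i}" for i in range(8)], self._design())


class TestStartingFreqTest:
    def test_self_sampling_inside_interval(self, rng):
        sf = rng.uniform(0.05, 0.5, size=400)
        res = starting_freq_test(sf, np.ones(400, dtype=bool),
                                 n_resamples=2000, rng=rng)
        assert res.ci_low <= res.observed_median <= res.ci_high
        assert not res.is_low

    def test_planted_low_decile_flagged(self, rng):
        sf = rng.uniform(0.05, 0.5, size=5000)
        cutoff = np.quantile(sf, 0.1)
        mask = np.zeros(5000, dtype=bool)
        mask[np.flatnonzero(sf <= cutoff)[:68]] = True
        res = starting_freq_test(sf, mask, n_resamples=5000, rng=rng)
        assert res.is_low
        assert res.observed_median < res.null_median

    def test_interval_stable_across_seeds(self, rng):
        sf = rng.uniform(0.05, 0.5, size=5000)
        mask = np.zeros(5000, dtype=bool)
        mask[:68] = True
        r1 = starting_freq_test(sf, mask, n_resamples=10_000,
                                rng=np.random.default_rng(1))
        r2 = starting_freq_test(sf, mask, n_resamples=10_000,
                                rng=np.random.default_rng(2))
        assert abs(r1.ci_low - r2.ci_low) < 0.005
        assert abs(r1.ci_high - r2.ci_high) < 0.005

    def test_empty_sdv_set_errors(self, rng):
        with pytest.raises(ValueError, match="empty SDV"):
            starting_freq_test(np.ones(10) / 2, np.zeros(10, dtype=bool),
                               rng=rng)


class TestLdDecay:
    def test_flat_profile_flagged_no_decay(self, rng):
        pos = np.arange(0, 20_000, 20)
        p = np.full(pos.size, 0.5)
        prof = ld_decay_profile(p, pos, np.array([0]))
        assert prof.no_decay
        assert np.isnan(prof.independence_distance)

    def test_linear_rise_then_flat_recovers_scale(self):
        pos = np.arange(0, 20_000, 10)
        p = np.minimum(pos, 8000) / 8000 * 0.5
        prof = ld_decay_profile(p, pos, np.array([0]))
        assert not prof.no_decay
        assert abs(prof.independence_distance - 8000) < 1000

    def test_requires_sdvs(self):
        with pytest.raises(ValueError, match="no SDV"):
            ld_decay_profile(np.ones(5), np.arange(5), np.array([]))

    def test_sdv_loci_measure_distance_to_nearest_other_sdv(self):
        from lekscan.windows import _distance_to_nearest_sdv

        d = _distance_to_nearest_sdv(
            np.array([100, 200, 350]), np.array([100, 200])
        )
        np.testing.assert_array_equal(d, [100.0, 100.0, 150.0])
        assert _distance_to_nearest_sdv(
            np.array([100]), np.array([100])
        )[0] == np.inf

    def test_linked_causal_blocks_break_down_within_10kb(self):
        """Significance decays around SDVs on the scale of the planted
        linkage blocks, far below 10 kb."""
        from lekscan.data import DesignSpec, filter_loci, orient_global_minor
        from lekscan.experiment import ExperimentConfig, simulate_experiment
        from lekscan.scan import scan_loci
        from lekscan.windows import ld_decay_by_arm

        rng = np.random.default_rng(6)
        cfg = ExperimentConfig(
            n_loci=8000, fraction_causal=0.003, sel_coeff=0.7,
            locus_spacing_bp=100, linkage_block_bp=2000,
        )
        table, _ = simulate_experiment(cfg, rng)
        table = filter_loci(orient_global_minor(table))
        design = DesignSpec(
            {l: ("success" if l[0] == "S"
                 else "failure" if l[0] == "F" else "control")
             for l in table.line_ids}
        )
        st = scan_loci(table, design).stats
        prof = ld_decay_by_arm(
            st["glm_p"].to_numpy(), st["chrom"].to_numpy(),
            st["pos"].to_numpy(), st["is_sdv"].to_numpy(),
        )["overall"]
        assert not prof.no_decay
        assert prof.independence_distance < 10_000
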