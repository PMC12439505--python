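"""Feature table construction and the group-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pergdwt import features, synthetic
from pergdwt.benchmark import roc_auc
from pergdwt.dwt import decompose
from pergdwt.features import FeatureTable


def brute_force_u(x, y):
    """Independent pair-counting oracle for the Mann-Whitney U."""
    u = 0.0
    for xi in x:
        for yi in y:
            u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
    return u


def make_table(data: dict[str, list[float]], groups: list[str]) -> FeatureTable:
    ids = [f"p{i}" for i in range(len(groups))]
    values = pd.DataFrame(data, index=ids)
    return FeatureTable(values=values, groups=pd.Series(groups, index=ids))


class TestBuildFeatureTable:
    def test_structural_counts_per_wavelet(self):
        # haar: D4..D7 + A7 = 16+8+4+2+2; six-level: 16+8+4+4; five-level: 16+8+8
        assert len(features.feature_addresses("haar")) == 32
        assert len(features.feature_addresses("sym2")) == 32
        assert len(features.feature_addresses("sym4")) == 32
        total = sum(
            len(features.feature_addresses(w))
            for w in features.RETAINED_WAVELETS_DEFAULT
        )
        assert total == 192

    def test_participant_row_is_mean_of_recordings(self, small_cohort):
        table = features.build_feature_table(small_cohort, ["sym2"])
        pid = small_cohort[0].participant_id
        recs = [r for r in small_cohort if r.participant_id == pid]
        manual = np.mean(
            [
                [decompose(r.samples, "sym2").energy(a)
                 for a in features.feature_addresses("sym2")]
                for r in recs
            ],
            axis=0,
        )
        np.testing.assert_allclose(table.values.loc[pid].to_numpy(), manual)

    def test_one_row_per_participant_with_group(self, small_cohort):
        table = features.build_feature_table(small_cohort, ["haar"])
        assert table.values.shape == (12, 32)
        assert table.n_normal == 6 and table.n_mpird == 6

    def test_deterministic_column_order(self, small_cohort):
        t1 = features.build_feature_table(small_cohort, ["haar", "sym2"])
        t2 = features.build_feature_table(small_cohort, ["haar", "sym2"])
        assert list(t1.values.columns) == list(t2.values.columns)
        assert t1.values.columns[0] == "haar-D4-1"
        assert t1.values.columns[31] == "haar-A7-2"


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x,y,expected_u",
        [([3, 4], [1, 2], 4.0), ([1], [1], 0.5), ([1, 3, 5], [2, 4], 3.0)],
    )
    def test_u_examples(self, x, y, expected_u):
        u, _, _ = features.mann_whitney(x, y)
        assert u == expected_u
        assert brute_force_u(x, y) == expected_u

    def test_u_and_p_match_pair_counting_and_scipy(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 12, size=2)
            if rng.random() < 0.5:
                x, y = rng.normal(size=n1), rng.normal(size=n2)
            else:  # discrete values force ties
                x, y = rng.integers(0, 4, n1).astype(float), rng.integers(0, 4, n2).astype(float)
            u, z, p = features.mann_whitney(x, y)
            assert u == pytest.approx(brute_force_u(x, y))
            if len(np.unique(np.concatenate([x, y]))) == n1 + n2:
                ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic", use_continuity=False)
                assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_tied_gives_z_zero(self):
        u, z, p = features.mann_whitney([1, 1], [1, 1])
        assert (u, z, p) == (2.0, 0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            features.mann_whitney([], [1.0])


class TestEffectSizes:
    def test_perfect_separation_cles_one(self):
        r_es, cles = features.effect_sizes(u=12, z=3.0, n_normal=3, n_mpird=4)
        assert cles == 1.0

    def test_r_es_arithmetic(self):
        r_es, _ = features.effect_sizes(u=5, z=2.5, n_normal=8, n_mpird=8)
        assert r_es == pytest.approx(0.625)

    def test_cles_reads_as_pair_probability(self, rng):
        x, y = rng.normal(1, 1, 10), rng.normal(0, 1, 12)
        u, z, _ = features.mann_whitney(x, y)
        _, cles = features.effect_sizes(u, z, 10, 12)
        assert cles == pytest.approx(brute_force_u(x, y) / 120)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=7)
        u1, z1, _ = features.mann_whitney(x, y)
        u2, z2, _ = features.mann_whitney(np.exp(x), np.exp(y))
        assert (u1, z1) == pytest.approx((u2, z2))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        p_adj, reject = features.bh_adjust([0.5])
        assert p_adj[0] == 0.5 and not reject[0]

    def test_step_up_thresholds(self):
        p_adj, reject = features.bh_adjust([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert reject.all()

    def test_equal_ps_share_adjusted_value(self):
        p_adj, _ = features.bh_adjust([0.04, 0.04, 0.04])
        np.testing.assert_allclose(p_adj, 0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            features.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_step_up_definition_and_monotone(self, p_values):
        p = np.asarray(p_values)
        p_adj, _ = features.bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            expected[i] = running
        np.testing.assert_allclose(p_adj, expected, atol=1e-12)
        assert np.all(p_adj >= p - 1e-12)


class TestPruneCorrelated:
    def test_weaker_of_correlated_pair_removed(self, rng):
        base = rng.normal(size=20)
        groups = ["normal"] * 10 + ["mpird"] * 10
        shift = np.array([1.0] * 10 + [0.0] * 10)
        table = make_table(
            {"F1": base + 2 * shift, "F2": base + 2 * shift + rng.normal(0, 0.05, 20),
             "F3": rng.normal(size=20)},
            groups,
        )
        stats_table = features.compute_feature_stats(table)
        kept = features.prune_correlated(table, stats_table, threshold=0.9)
        assert len(kept) == 2 and "F3" in kept
        dropped = ({"F1", "F2"} - set(kept)).pop()
        assert stats_table.loc[dropped, "r_es"] <= max(
            stats_table.loc[f, "r_es"] for f in ("F1", "F2")
        )

    def test_chain_pruning_keeps_first_and_third(self):
        # rho(F1,F2) > 0.9 and rho(F2,F3) > 0.9 but rho(F1,F3) < 0.9, with
        # r_es F1 > F2 > F3: the greedy walk keeps {F1, F3} — F3 is only
        # compared against already-kept features, never the dropped F2
        n = 24
        rng = np.random.default_rng(9)
        groups = ["normal"] * 12 + ["mpird"] * 12
        shift = np.array([1.0] * 12 + [0.0] * 12)
        a = np.linspace(0.0, 1.0, n)
        b = a + rng.normal(0, 0.12, n)
        c = b + rng.normal(0, 0.12, n)
        table = make_table(
            {"F1": a + 6.0 * shift, "F2": b + 4.0 * shift, "F3": c + 2.0 * shift},
            groups,
        )
        stats_table = features.compute_feature_stats(table)
        data = table.values
        rho = lambda u, v: abs(sps.spearmanr(data[u], data[v]).statistic)
        # fixture sanity: the intended chain structure really holds
        assert rho("F1", "F2") > 0.9 and rho("F2", "F3") > 0.9 and rho("F1", "F3") < 0.9
        r = stats_table["r_es"]
        assert r["F1"] >= r["F2"] >= r["F3"]
        kept = features.prune_correlated(table, stats_table, threshold=0.9)
        assert kept == ["F1", "F3"]

    def test_just_below_threshold_keeps_both(self):
        # |rho| just below the 0.9 cutoff: both features survive
        n = 40
        rng = np.random.default_rng(3)
        x = np.arange(n, dtype=float)
        y = x + rng.normal(0, 6.0, n)
        rho = abs(sps.spearmanr(x, y).statistic)
        assert 0.8 < rho < 0.9
        table = make_table({"F1": x, "F2": y}, ["normal"] * 20 + ["mpird"] * 20)
        stats_table = features.compute_feature_stats(table)
        kept = features.prune_correlated(table, stats_table, threshold=0.9)
        assert kept == ["F1", "F2"]

    def test_constant_feature_treated_as_uncorrelated(self):
        table = make_table(
            {"F1": list(range(10)), "F2": [1.0] * 10},
            ["normal"] * 5 + ["mpird"] * 5,
        )
        stats_table = features.compute_feature_stats(table)
        kept = features.prune_correlated(table, stats_table, threshold=0.9)
        assert set(kept) == {"F1", "F2"}

    def test_pruned_set_pairwise_below_threshold(self, small_cohort):
        table = features.build_feature_table(small_cohort, ["sym2", "haar"])
        stats_table = features.compute_feature_stats(table)
        kept = features.prune_correlated(table, stats_table, threshold=0.9)
        rho = sps.spearmanr(table.values[kept].to_numpy()).statistic
        rho = np.atleast_2d(np.nan_to_num(rho, nan=0.0))
        off_diag = rho[~np.eye(len(kept), dtype=bool)]
        assert np.all(np.abs(off_diag) <= 0.9 + 1e-12)


class TestRankFeatures:
    def test_descending_and_stable(self):
        table = pd.DataFrame(
            {"r_es": [0.2, 0.9, 0.5, 0.9]}, index=["a", "b", "c", "d"]
        )
        ranked = features.rank_features(table)
        assert list(ranked.index) == ["b", "d", "c", "a"]


class TestPipelineIdentities:
    def test_cles_equals_roc_auc_exactly(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(3, 12, size=2)
            x = rng.integers(0, 5, n1).astype(float)
            y = rng.integers(0, 5, n2).astype(float)
            u, z, _ = features.mann_whitney(x, y)
            _, cles = features.effect_sizes(u, z, n1, n2)
            auc = roc_auc(
                np.concatenate([x, y]),
                np.array(["normal"] * n1 + ["mpird"] * n2),
            )
            assert abs(cles - auc) < 1e-12

    def test_top_feature_is_central_d6_on_separated_cohort(self):
        cfg = synthetic.CohortConfig(
            n_normal=12, n_mpird=12, recordings_per_participant=2,
            attenuation_p50=0.3, seed=21,
        )
        cohort = synthetic.generate_cohort(cfg)
        table = features.build_feature_table(cohort, ["sym2"])
        stats_table = features.compute_feature_stats(table)
        ranked = features.rank_features(stats_table)
        top_window = features.feature_window(ranked.index[0])
        assert top_window.overlaps_time(40.0, 70.0)
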