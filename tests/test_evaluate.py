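import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ardi import evaluate


def meta_with_names(names):
    return pd.DataFrame(
        {
            "vocalization_id": [f"v{i}" for i in range(len(names))],
            "call_name": names,
        }
    )


class TestClassifyCallNames:
    def test_keyword_hits(self):
        cls = evaluate.classify_call_names(
            meta_with_names(["Duet.Song", "alarm bark", "Musical.Sequence"])
        )
        assert list(cls["musical_flag"]) == [True, False, True]
        assert cls["matched_keyword"].iloc[0] == "song"  # first in keyword order
        assert cls["matched_keyword"].iloc[2] == "music"

    def test_case_and_punctuation_invariance(self):
        variants = ["SONG", " song ", "..song!!", "Great-Call", "great call"]
        cls = evaluate.classify_call_names(meta_with_names(variants))
        assert cls["musical_flag"].all()

    def test_missing_names_are_not_musical(self):
        meta = meta_with_names(["song", None])
        cls = evaluate.classify_call_names(meta)
        assert list(cls["musical_flag"]) == [True, False]


class TestIndexLabelCorrelation:
    def test_separated_groups_positive(self):
        idx = np.array([3.0, 4.0, 5.0, 0.5, 0.6, 0.7])
        flag = np.array([1, 1, 1, 0, 0, 0])
        res = evaluate.index_label_correlation(idx, flag)
        assert res.statistic > 0.8

    def test_independent_labels_near_zero(self, rng):
        idx = rng.normal(size=4000)
        flag = rng.integers(0, 2, size=4000)
        res = evaluate.index_label_correlation(idx, flag)
        assert abs(res.statistic) < 0.05

    def test_matches_brute_force_rank_arithmetic(self):
        idx = np.array([2.1, 0.3, 4.5, 1.1, 0.9, 3.3])
        flag = np.array([1, 0, 1, 0, 0, 1])
        res = evaluate.index_label_correlation(idx, flag, method="pearson_on_ranks")
        rx = stats.rankdata(idx)
        ry = stats.rankdata(flag)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            evaluate.index_label_correlation([1.0, 2.0, 3.0], [1, 1, 1])


def brute_force_ranksum(a, b):
    """Full enumeration of group assignments over the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)]
    sums = np.asarray(sums)
    p_less = np.mean(sums <= obs + 1e-9)
    p_greater = np.mean(sums >= obs - 1e-9)
    return p_less, p_greater


class TestRanksum:
    def test_extreme_small_case(self):
        res = evaluate.ranksum_test([1, 2], [3, 4])
        assert res.extra["U"] == 0
        assert res.extra["p_less"] == pytest.approx(1 / 6)

    def test_identical_groups_central_u(self):
        res = evaluate.ranksum_test([1, 2, 3], [1, 2, 3])
        assert res.extra["U"] == pytest.approx(4.5)  # n1*n2/2

    def test_single_observation_group(self):
        res = evaluate.ranksum_test([5], [1, 2, 3])
        assert res.extra["U"] == 3
        assert res.extra["p_greater"] == pytest.approx(1 / 4)

    @pytest.mark.parametrize("trial", range(8))
    def test_exact_p_matches_full_enumeration(self, trial):
        rng = np.random.default_rng(200 + trial)
        n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        a = rng.integers(0, 6, n1).astype(float)  # small range forces ties
        b = rng.integers(0, 6, n2).astype(float)
        res = evaluate.ranksum_test(a, b)
        p_less, p_greater = brute_force_ranksum(a, b)
        assert res.extra["p_less"] == pytest.approx(p_less, abs=1e-12)
        assert res.extra["p_greater"] == pytest.approx(p_greater, abs=1e-12)

    def test_agrees_with_scipy_without_ties(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=9) + 0.5
        res = evaluate.ranksum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.extra["U"] == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_u_complement_identity(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        res = evaluate.ranksum_test(a, b)
        assert res.extra["U"] + res.extra["U_prime"] == pytest.approx(5 * 7)


class TestWelch:
    def test_identical_groups(self):
        res = evaluate.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_equal_variances(self):
        res = evaluate.welch_t_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.6742346, abs=1e-6)
        assert res.df == pytest.approx(4.0)
        assert res.effect == pytest.approx(-3.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=9) + 1
        r1 = evaluate.welch_t_test(a, b)
        r2 = evaluate.welch_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.effect == pytest.approx(-r2.effect)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_agrees_with_scipy(self, rng):
        a, b = rng.normal(size=10), rng.normal(scale=3, size=14) + 0.7
        res = evaluate.welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_reduces_to_pooled_t_in_balanced_equal_variance_limit(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.5, 3.5, 4.5, 5.5])  # same spread, same size
        res = evaluate.welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.df == pytest.approx(len(a) + len(b) - 2)

    def test_degenerate_variance_cases(self):
        res = evaluate.welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)
        with pytest.raises(ValueError):
            evaluate.welch_t_test([2.0, 2.0], [3.0, 3.0])


class TestGroupSize:
    @pytest.mark.parametrize(
        "size,solitary,expected",
        [
            (4, False, "small"),
            (2, False, "small"),
            (6, False, "small"),
            (20, False, "large"),
            (1, True, "solitary"),
            (10, True, "solitary"),  # flag dominates
            (float("nan"), False, "unknown"),
        ],
    )
    def test_categories(self, size, solitary, expected):
        assert evaluate.categorize_group_size(size, solitary) == expected


def synthetic_species_table(rng, n_per_arm=30, effect=1.2):
    monog = np.repeat([True, False], n_per_arm)
    base = rng.normal(2.0, 0.8, size=2 * n_per_arm)
    ardi = base + effect * monog
    return pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(2 * n_per_arm)],
            "max_ardi": ardi,
            "monogamous": monog,
            "wooded": rng.integers(0, 2, 2 * n_per_arm).astype(bool),
            "arboreal": rng.integers(0, 2, 2 * n_per_arm).astype(bool),
            "territorial": rng.integers(0, 2, 2 * n_per_arm).astype(bool),
            "group_size": rng.uniform(2, 30, 2 * n_per_arm),
            "solitary": np.zeros(2 * n_per_arm, dtype=bool),
        }
    )


class TestHypothesisBattery:
    def test_recovers_built_in_monogamy_effect(self, rng):
        table = synthetic_species_table(rng, n_per_arm=30, effect=1.2)
        results = evaluate.run_hypothesis_battery(table)
        mono = next(r for r in results if "monogamous" in r.name)
        assert mono.effect == pytest.approx(1.2, abs=0.3)
        assert mono.p_value < 0.05

    def test_null_covariate_small_statistic(self):
        tstats = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            table = synthetic_species_table(rng, n_per_arm=20, effect=0.0)
            mono = next(
                r for r in evaluate.run_hypothesis_battery(table)
                if "monogamous" in r.name
            )
            tstats.append(mono.statistic)
        # null t-statistics: centred near zero, rarely extreme
        assert abs(np.mean(tstats)) < 0.5
        assert np.mean(np.abs(np.array(tstats)) > 2.1) < 0.3

    def test_single_class_covariate_skipped_with_notice(self, rng):
        table = synthetic_species_table(rng, n_per_arm=5)
        table["monogamous"] = True
        results = evaluate.run_hypothesis_battery(table)
        skipped = [r for r in results if "monogamous" in r.name]
        assert skipped and "skipped" in skipped[0].extra.get("notice", "")

    def test_tests_table_carries_unadjusted_flag_and_holm(self, rng):
        table = synthetic_species_table(rng)
        out = evaluate.tests_table(evaluate.run_hypothesis_battery(table))
        assert (out["p_adjusted"] == "unadjusted").all()
        valid = out["p_value"].notna()
        assert (out.loc[valid, "p_holm"] >= out.loc[valid, "p_value"] - 1e-12).all()


class TestRankingTable:
    def make_tables(self):
        idx = pd.DataFrame(
            {
                "ardi": [3.0, 1.0, 2.0, 2.0, 0.5],
                "syllables": [4.0, 1.0, 3.0, 2.0, 1.0],
                "pc1_score": [-2.0, 1.0, -1.0, 0.0, 2.0],
                "log_sci": [1.5, 0.2, 1.0, 0.8, 0.1],
            },
            index=pd.Index([f"v{i}" for i in range(5)], name="vocalization_id"),
        )
        meta = pd.DataFrame(
            {
                "vocalization_id": idx.index,
                "species": ["s"] * 5,
                "genus": ["g"] * 5,
                "call_name": ["great song", "bark", "duet", "song", "grunt"],
            }
        )
        return idx, meta

    def test_distinct_values_rank_one_to_n(self):
        idx, meta = self.make_tables()
        out = evaluate.ranking_table(idx.iloc[:3], meta.iloc[:3])
        assert sorted(out["rank_ardi"]) == [1, 2, 3]

    def test_ties_share_minimum_rank(self):
        idx, meta = self.make_tables()
        out = evaluate.ranking_table(idx, meta)
        tied = out.loc[out["ardi"] == 2.0, "rank_ardi"]
        assert set(tied) == {2}
        assert out.loc[out["ardi"] == 1.0, "rank_ardi"].iloc[0] == 4  # rank skipped

    def test_name_filter_and_brute_force_order(self):
        idx, meta = self.make_tables()
        out = evaluate.ranking_table(idx, meta, name_contains=("song", "duet"))
        assert set(out["call_name"]) == {"great song", "duet", "song"}
        expected = idx.loc[out.index, "ardi"].sort_values(ascending=False)
        assert list(out.sort_values("rank_ardi").index) == list(expected.index)

    def test_empty_subset(self):
        idx, meta = self.make_tables()
        out = evaluate.ranking_table(idx, meta, name_contains=("chorus",))
        assert out.empty


class TestContextSummaries:
    def test_single_category_matches_global_stats(self):
        idx = pd.DataFrame(
            {"ardi": [1.0, 2.0, 3.0]},
            index=pd.Index(["v0", "v1", "v2"], name="vocalization_id"),
        )
        cats = pd.Series(["display"] * 3, index=idx.index, name="context_category")
        out = evaluate.context_summaries(idx, cats, metrics=("ardi",))
        assert len(out) == 1
        assert out.iloc[0]["mean"] == pytest.approx(2.0)
        assert out.iloc[0]["median"] == pytest.approx(2.0)

    def test_two_categories_hand_means(self):
        idx = pd.DataFrame(
            {"ardi": [1.0, 3.0, 10.0, 20.0]},
            index=pd.Index([f"v{i}" for i in range(4)], name="vocalization_id"),
        )
        cats = pd.Series(
            ["alarm", "alarm", "display", "display"], index=idx.index,
            name="context_category",
        )
        out = evaluate.context_summaries(idx, cats, metrics=("ardi",))
        by_cat = out.set_index("context_category")["mean"]
        assert by_cat["alarm"] == pytest.approx(2.0)
        assert by_cat["display"] == pytest.approx(15.0)
        assert out.set_index("context_category")["small_sample"].all()

    def test_empty_context_bucketed_as_unlabeled(self):
        meta = pd.DataFrame(
            {"vocalization_id": ["v0", "v1"], "context": ["", "alarm call"]}
        )
        cats = evaluate.assign_context_categories(meta)
        assert cats.loc["v0"] == "unlabeled"
        assert cats.loc["v1"] == "alarm"
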