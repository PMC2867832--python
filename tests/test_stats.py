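import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from acetclust.io import PromoterTable
from acetclust.stats import (
    ExpressionTiers,
    bonferroni,
    chi_square_test,
    expression_tiers,
    feature_by_cluster_table,
    fisher_exact,
    kruskal_wallis,
    repeat_fraction_by_tier,
    wilcoxon_rank_sum,
)

from conftest import make_promoter
from oracles import chi_square_textbook, fisher_two_sided_p, rank_sum_exact_p

TABLE1 = np.array([[513, 417, 552], [387, 711, 635], [246, 366, 654]])


class TestChiSquare:
    def test_independent_table_statistic_zero(self):
        table = np.outer([10, 20], [3, 7]) / 1.0
        res = chi_square_test(table)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_diagonal_2x2(self):
        res = chi_square_test([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_printed_table_vs_textbook_formula(self):
        res = chi_square_test(TABLE1)
        assert res.statistic == pytest.approx(chi_square_textbook(TABLE1))

    def test_scipy_oracle(self, rng):
        for _ in range(10):
            table = rng.integers(1, 60, size=(3, 2))
            res = chi_square_test(table)
            stat, p, df, _ = sps.chi2_contingency(table, correction=False)
            assert res.statistic == pytest.approx(stat)
            assert res.p == pytest.approx(p)
            assert res.df == df

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_test([[0, 0], [5, 5]])

    def test_permutation_invariance(self, rng):
        table = rng.integers(1, 50, size=(3, 4))
        base = chi_square_test(table).statistic
        perm = table[np.argsort(rng.random(3))][:, np.argsort(rng.random(4))]
        assert chi_square_test(perm).statistic == pytest.approx(base)


class TestFisher:
    def test_extreme_table(self):
        res = fisher_exact([[0, 5], [5, 0]])
        assert res.p == pytest.approx(fisher_two_sided_p([[0, 5], [5, 0]]))
        assert res.p == pytest.approx(2 / 252)

    def test_identical_rows_p_one(self):
        assert fisher_exact([[4, 6], [4, 6]]).p == pytest.approx(1.0)

    def test_enumeration_oracle_small_margins(self, rng):
        for _ in range(40):
            table = rng.integers(0, 7, size=(2, 2))
            if table.sum() == 0:
                continue
            res = fisher_exact(table)
            assert res.p == pytest.approx(fisher_two_sided_p(table.tolist()))

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError, match="2×2"):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestBonferroni:
    def test_simple(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)

    def test_capped(self):
        assert bonferroni(0.5, 4) == 1.0

    def test_identity_m1(self):
        assert bonferroni(0.123, 1) == pytest.approx(0.123)

    def test_attached_to_result(self):
        res = chi_square_test([[10, 2], [3, 9]]).corrected(5)
        assert res.p_bonferroni == pytest.approx(min(1.0, 5 * res.p))
        assert res.m == 5


class TestRankTests:
    def test_kw_identical_groups_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)

    def test_ranksum_exact_small(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.p == pytest.approx(1 / 20)
        res2 = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res2.p == pytest.approx(2 / 20)
        assert res2.p == pytest.approx(rank_sum_exact_p([1, 2, 3], [4, 5, 6], "two-sided"))

    def test_kw_independent_recomputation(self, rng):
        groups = [
            list(rng.integers(0, 15, size=10)),
            list(rng.integers(3, 18, size=10)),
            list(rng.integers(6, 21, size=10)),
        ]
        res = kruskal_wallis(groups)
        # independent rank-based recomputation with tie correction
        pooled = np.concatenate(groups).astype(float)
        ranks = sps.rankdata(pooled)
        n = pooled.size
        h = 0.0
        start = 0
        for g in groups:
            r = ranks[start : start + len(g)]
            h += r.sum() ** 2 / len(g)
            start += len(g)
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        h /= 1 - ((counts**3 - counts).sum() / (n**3 - n))
        assert res.statistic == pytest.approx(h)
        assert res.df == 2

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


def promoters_with_tpm(tpms):
    records = []
    for i, tpm in enumerate(tpms):
        rep = 10_000 + 6_000 * i
        records.append(
            make_promoter(f"p{i:03d}", rep=rep, level1=((rep, 5),), tpm={"0h": float(tpm)})
        )
    return PromoterTable(tuple(records))


class TestExpressionTiers:
    def test_exact_sizes_distinct(self):
        table = promoters_with_tpm(range(100))
        tiers = expression_tiers(table)
        counts = pd.Series(tiers.tier_by_id).value_counts()
        assert counts["low"] == 10 and counts["high"] == 10 and counts["medium"] == 80

    def test_massive_ties_sizes_still_exact(self):
        table = promoters_with_tpm([5.0] * 50)
        tiers = expression_tiers(table)
        counts = pd.Series(tiers.tier_by_id).value_counts()
        assert counts["low"] == 5 and counts["high"] == 5
        # ties resolved by id order
        assert set(tiers.ids_in("low")) == {f"p{i:03d}" for i in range(5)}
        assert set(tiers.ids_in("high")) == {f"p{i:03d}" for i in range(45, 50)}

    def test_small_n_strict_errors_lenient_min_one(self):
        table = promoters_with_tpm(range(6))
        with pytest.raises(ValueError):
            expression_tiers(table, strict=True)
        tiers = expression_tiers(table, strict=False)
        assert len(tiers.ids_in("low")) == 1 and len(tiers.ids_in("high")) == 1

    def test_high_tier_profile_dominates_low_noiseless(self):
        from acetclust.profiles import average_replicates, binned_profiles
        from acetclust.synth import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(
            n_promoters=24,
            genome_length=200_000,
            seed=9,
            noise_sd=0.0,
            gap_rate=0.0,
            shape_mix={"upstream": 1.0, "centered": 0.0, "downstream": 0.0},
        )
        d = generate_dataset(cfg, with_annotations=False)
        tier = {r.promoter_id: r.tier for r in d.truth}
        profs = binned_profiles(d.promoters, average_replicates(d.track))
        means = {}
        for name in ("low", "high"):
            ids = [pid for pid, t in tier.items() if t == name]
            means[name] = np.mean([profs[pid].scores for pid in ids], axis=0)
        assert np.all(means["high"] >= means["low"] - 1e-9)


class TestFeatureTable:
    @staticmethod
    def fixture_annotations():
        ids = [f"p{i}" for i in range(20)]
        frame = pd.DataFrame(
            {
                "architecture": ["SP" if i % 3 == 0 else "BR" for i in range(20)],
                "cpg": [i % 2 == 0 for i in range(20)],
                "gene": [i % 4 == 0 for i in range(20)],
                "lincrna": [False] * 20,
                "repeat": [i % 5 == 0 for i in range(20)],
                "repeat_class": ["SINE" if i % 5 == 0 else None for i in range(20)],
                "tata": [i % 2 == 1 for i in range(20)],
                "tata_score": [0.5] * 20,
            },
            index=pd.Index(ids, name="id"),
        )
        labels = {
            pid: ["upstream", "centered", "downstream"][i % 3]
            for i, pid in enumerate(ids)
        }
        return labels, frame

    def test_counts_sum_to_n(self):
        labels, ann = self.fixture_annotations()
        table = feature_by_cluster_table(labels, ann, "cpg")
        assert int(table.values.sum()) == 20

    def test_matches_brute_force_recount(self):
        labels, ann = self.fixture_annotations()
        table = feature_by_cluster_table(labels, ann, "architecture")
        for cluster in table.index:
            for arch in table.columns:
                expected = sum(
                    1
                    for pid in labels
                    if labels[pid] == cluster and ann.loc[pid, "architecture"] == arch
                )
                assert table.loc[cluster, arch] == expected

    def test_all_sp_gives_zero_br_column(self):
        labels, ann = self.fixture_annotations()
        ann = ann.assign(architecture="SP")
        table = feature_by_cluster_table(labels, ann, "architecture")
        assert (table["BR"] == 0).all()

    def test_unknown_feature_errors(self):
        labels, ann = self.fixture_annotations()
        with pytest.raises(ValueError, match="unknown feature"):
            feature_by_cluster_table(labels, ann, "banana")


class TestRepeatFraction:
    def make_tiers(self, mapping):
        return ExpressionTiers(mapping, "0h", 1, 1, 0.0, 0.0)

    def test_all_flagged(self):
        tiers = self.make_tiers({"a": "low", "b": "high"})
        ann = pd.DataFrame({"repeat": [True, True]}, index=["a", "b"])
        frac = repeat_fraction_by_tier(tiers, ann)
        assert frac["low"] == 1.0 and frac["high"] == 1.0 and frac["medium"] is None

    def test_none_flagged(self):
        tiers = self.make_tiers({"a": "low"})
        ann = pd.DataFrame({"repeat": [False]}, index=["a"])
        assert repeat_fraction_by_tier(tiers, ann)["low"] == 0.0

    def test_twenty_promoter_hand_count(self):
        ids = [f"p{i}" for i in range(20)]
        tiers = self.make_tiers(
            {pid: ("low" if i < 5 else "high" if i >= 15 else "medium") for i, pid in enumerate(ids)}
        )
        ann = pd.DataFrame({"repeat": [i % 2 == 0 for i in range(20)]}, index=ids)
        frac = repeat_fraction_by_tier(tiers, ann)
        assert frac["low"] == pytest.approx(3 / 5)  # p0, p2, p4
        assert frac["medium"] == pytest.approx(5 / 10)
        assert frac["high"] == pytest.approx(2 / 5)  # p16, p18
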