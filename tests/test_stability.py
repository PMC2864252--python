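"""Rank-sum statistics, cluster comparisons and the shut-off flagger."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from decaykinetics import stability
from decaykinetics.stability import HalfLifeAtlas, rank_sum_test


def brute_force_rank_sum_p(a, b, alternative):
    """Permutation-null oracle: relabel the pooled values in every way."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n_a].sum()
    ws = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n_a)
    ]
    ws = np.asarray(ws)
    p_less = np.mean(ws <= w_obs + 1e-9)
    p_greater = np.mean(ws >= w_obs - 1e-9)
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


def atlas_of(mapping: dict) -> HalfLifeAtlas:
    return HalfLifeAtlas(half_life_h=pd.Series(mapping))


class TestRankSumExact:
    def test_textbook_case(self):
        # a={1,2} vs b={3,4}: only one of C(4,2)=6 labelings is as extreme
        res = rank_sum_test([1, 2], [3, 4], alternative="less")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 6, abs=1e-12)

    def test_identical_samples_two_sided(self):
        res = rank_sum_test([5, 5, 5], [5, 5, 5], alternative="two-sided")
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
    def test_matches_permutation_oracle(self, alternative):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n_a = int(rng.integers(1, 8))
            n_b = int(rng.integers(1, 8))
            if n_a + n_b > 12:
                continue
            a = rng.integers(0, 6, n_a).astype(float)  # ties likely
            b = rng.integers(0, 6, n_b).astype(float)
            res = rank_sum_test(a, b, alternative=alternative)
            assert res.p_value == pytest.approx(
                brute_force_rank_sum_p(a, b, alternative), abs=1e-12
            )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            ours = rank_sum_test(a, b, alternative="greater").p_value
            ref = sps.mannwhitneyu(a, b, alternative="greater", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_one_sided_tails_overlap(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=5), rng.normal(size=5)
        p_l = rank_sum_test(a, b, "less").p_value
        p_g = rank_sum_test(a, b, "greater").p_value
        assert p_l + p_g >= 1.0  # both tails include the observed statistic

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 60)
        b = rng.normal(1, 1, 60)
        res = rank_sum_test(a, b, alternative="less")
        assert res.method == "normal-approximation"
        assert res.p_value < 1e-4

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestClusterComparisons:
    def test_early_late_exact_example(self):
        # early half-lives {0.5, 0.7} vs late {5, 6, 7}: p = 1/C(5,2) = 1/10
        atlas = atlas_of({"e1": 0.5, "e2": 0.7, "l1": 5.0, "l2": 6.0, "l3": 7.0})
        res = stability.early_late_stability_test(
            ["e1", "e2"], ["l1", "l2", "l3"], atlas, alternative="less"
        )
        assert res.p_value == pytest.approx(1 / 10, abs=1e-12)

    def test_identical_groups_show_no_signal(self):
        atlas = atlas_of({f"g{i}": float(i + 1) for i in range(8)})
        genes = [f"g{i}" for i in range(8)]
        res = stability.early_late_stability_test(genes, genes, atlas, "less")
        assert res.p_value > 0.4

    def test_core_removal_shrinks_groups(self):
        atlas = atlas_of({f"g{i}": float(i + 1) for i in range(10)})
        early = [f"g{i}" for i in range(5)]
        late = [f"g{i}" for i in range(5, 10)]
        res = stability.early_late_stability_test(
            early, late, atlas, exclude=["g0", "g9"]
        )
        assert (res.n_a, res.n_b) == (4, 4)

    def test_pairwise_matrix_has_all_pairs(self):
        atlas = atlas_of({f"g{i}": float(i + 1) for i in range(12)})
        clusters = {
            0.5: [f"g{i}" for i in range(4)],
            1.0: [f"g{i}" for i in range(4, 8)],
            2.0: [f"g{i}" for i in range(8, 12)],
        }
        pw = stability.pairwise_cluster_tests(clusters, atlas)
        assert len(pw) == 3  # C(3,2)
        assert (pw["earlier_h"] < pw["later_h"]).all()
        # the 0.5 h cluster holds the smallest half-lives: strong signal
        assert pw.loc[(pw.earlier_h == 0.5) & (pw.later_h == 2.0), "p_value"].iloc[0] < 0.05

    def test_unmatched_genes_dropped_case_insensitively(self):
        atlas = atlas_of({"GENEA": 1.0, "GENEB": 2.0, "GENEC": 3.0})
        res = stability.early_late_stability_test(
            ["genea", "missing1"], ["geneb", "genec", "missing2"], atlas
        )
        assert (res.n_a, res.n_b) == (1, 2)


class TestLengthAssociation:
    def _table(self, times: dict) -> pd.DataFrame:
        return pd.DataFrame(
            {"response_time_h": pd.Series(times, dtype=float), "direction": "up"}
        )

    def test_earliest_cluster_shorter_exact_p(self):
        table = self._table({"a": 0.5, "b": 0.5, "c": 2, "d": 4, "e": 4})
        ann = pd.DataFrame(
            {
                "gene_id": list("abcde"),
                "genomic_length_bp": [1000, 2000, 30000, 40000, 50000],
            }
        )
        res = stability.length_association(table, ann)
        assert res["earliest_vs_rest"].p_value == pytest.approx(1 / 10, abs=1e-12)

    def test_equal_lengths_no_signal(self):
        table = self._table({"a": 0.5, "b": 0.5, "c": 2, "d": 4})
        ann = pd.DataFrame({"gene_id": list("abcd"), "genomic_length_bp": [5] * 4})
        res = stability.length_association(table, ann)
        assert res["earliest_vs_rest"].p_value > 0.4

    def test_null_lengths_give_uniform_p(self):
        # with timing-independent lengths the earliest-vs-rest p must not
        # show systematic signal across replicates
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(50):
            times = {f"g{i}": float(rng.choice([0.5, 1, 2, 4])) for i in range(40)}
            ann = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(40)],
                    "genomic_length_bp": rng.lognormal(10, 1, 40),
                }
            )
            ps.append(
                stability.length_association(self._table(times), ann)[
                    "earliest_vs_rest"
                ].p_value
            )
        ps = np.asarray(ps)
        # roughly uniform: mean near 0.5 and no pile-up below 0.05
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.05).mean() <= 0.15


class TestFlagDestabilized:
    def _down(self, rows: dict) -> pd.DataFrame:
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")

    def test_stable_transcript_flagged(self):
        table = self._down(
            {"g1": {"response_time_h": 1.0, "fold_at_crossing": 2.0, "direction": "down"}}
        )
        out = stability.flag_destabilized(table, atlas_of({"g1": 5.0}), margin=1.0)
        assert out.loc["g1", "implied_max_half_life_h"] == pytest.approx(1.0)
        assert bool(out.loc["g1", "flagged"])

    def test_unstable_transcript_not_flagged(self):
        table = self._down(
            {"g1": {"response_time_h": 1.0, "fold_at_crossing": 2.0, "direction": "down"}}
        )
        out = stability.flag_destabilized(table, atlas_of({"g1": 0.5}), margin=1.0)
        assert not bool(out.loc["g1", "flagged"])

    def test_margin_monotone_never_adds_flags(self):
        rng = np.random.default_rng(8)
        rows = {
            f"g{i}": {
                "response_time_h": float(rng.choice([0.5, 1, 2, 4])),
                "fold_at_crossing": float(rng.uniform(2, 6)),
                "direction": "down",
            }
            for i in range(30)
        }
        atlas = atlas_of({f"g{i}": float(rng.lognormal(1.2, 1)) for i in range(30)})
        table = self._down(rows)
        flags_by_margin = [
            set(
                stability.flag_destabilized(table, atlas, margin=m)
                .query("flagged")
                .index
            )
            for m in (1.0, 1.5, 2.0, 3.0)
        ]
        for small, large in zip(flags_by_margin, flags_by_margin[1:]):
            assert large <= small
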