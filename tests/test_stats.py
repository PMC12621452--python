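from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from aquanrf.stats import (
    compact_letters,
    compare_wild_farmed,
    one_way_anova,
    summary_strings,
    tukey_hsd,
)

from conftest import make_item


class TestAnova:
    def test_hand_computed_f(self):
        # SSB = 6, SSW = 6 -> F = (6/2)/(6/6) = 3 with df (2, 6)
        res = one_way_anova({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert res.f_statistic == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.ss_between == pytest.approx(6.0)
        assert res.ss_within == pytest.approx(6.0)

    def test_identical_groups(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.f_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_reference_oracle_equivalence(self):
        # agreement with scipy's independent implementation on 100 fixtures
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = rng.integers(2, 6)
            samples = {
                f"g{i}": rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3),
                                    size=rng.integers(3, 12))
                for i in range(k)
            }
            res = one_way_anova(samples)
            ref = sps.f_oneway(*samples.values())
            assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0], "b": [1, 2]})
        with pytest.raises(ValueError):
            one_way_anova({"a": [1, 2]})

    def test_shift_invariance_and_scale_invariance(self):
        rng = np.random.default_rng(7)
        samples = {f"g{i}": rng.normal(i, 1, 8) for i in range(3)}
        base = one_way_anova(samples)
        shifted = one_way_anova({g: np.asarray(v) + 17.3 for g, v in samples.items()})
        scaled = one_way_anova({g: np.asarray(v) * 4.2 for g, v in samples.items()})
        assert shifted.f_statistic == pytest.approx(base.f_statistic, rel=1e-9)
        assert scaled.f_statistic == pytest.approx(base.f_statistic, rel=1e-9)


class TestTukey:
    def test_identical_groups_share_letter(self):
        res = tukey_hsd({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert all(not p.significant for p in res.pairs)
        assert set(res.letters.values()) == {"a"}

    def test_far_separated_groups(self):
        rng = np.random.default_rng(0)
        res = tukey_hsd(
            {"low": rng.normal(0, 1, 10), "high": rng.normal(100, 1, 10)}
        )
        (pair,) = res.pairs
        assert pair.significant
        assert sorted(res.letters.values()) == ["a", "b"]

    def test_adjusted_p_against_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        for _ in range(20):
            sizes = rng.integers(4, 10, size=3)
            samples = {
                f"g{i}": rng.normal(rng.uniform(0, 3), 1.0, size=n)
                for i, n in enumerate(sizes)
            }
            values = np.concatenate(list(samples.values()))
            labels = np.concatenate(
                [[g] * len(v) for g, v in samples.items()]
            )
            ref = pairwise_tukeyhsd(values, labels)
            ours = tukey_hsd(samples)
            ref_p = {
                frozenset((a, b)): p
                for (a, b), p in zip(
                    [(r[0], r[1]) for r in ref.summary().data[1:]], ref.pvalues
                )
            }
            for pair in ours.pairs:
                key = frozenset((pair.group_a, pair.group_b))
                assert pair.p_adjusted == pytest.approx(ref_p[key], abs=1e-6)

    def test_significance_matches_alpha(self):
        rng = np.random.default_rng(11)
        samples = {f"g{i}": rng.normal(i * 0.8, 1, 12) for i in range(4)}
        res = tukey_hsd(samples, alpha=0.05)
        for p in res.pairs:
            assert p.significant == (p.p_adjusted < 0.05)

    def test_letters_never_contradict_pairwise_table(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            k = int(rng.integers(3, 6))
            samples = {
                f"g{i}": rng.normal(rng.uniform(0, 4), 1.0, size=int(rng.integers(4, 9)))
                for i in range(k)
            }
            res = tukey_hsd(samples)
            for pair in res.pairs:
                shared = set(res.letters[pair.group_a]) & set(res.letters[pair.group_b])
                if pair.significant:
                    assert not shared, (pair, res.letters)
                else:
                    assert shared, (pair, res.letters)


class TestCompactLetters:
    def test_chain_structure(self):
        # a > b > c with only (a, c) different: a/ab/b pattern
        letters = compact_letters(["a", "b", "c"], [("a", "c")])
        assert letters["a"] != letters["c"]
        assert set(letters["b"]) >= set(letters["a"]) or set(letters["b"]) >= set(
            letters["c"]
        )

    def test_all_different(self):
        letters = compact_letters(
            ["x", "y", "z"], [("x", "y"), ("x", "z"), ("y", "z")]
        )
        assert len({letters["x"], letters["y"], letters["z"]}) == 3


class TestWildFarmed:
    def _items(self, farmed_vals, wild_vals, nutrient="iron"):
        items = []
        for i, v in enumerate(farmed_vals):
            it = make_item(f"f{i}", "salmon", **{nutrient: v})
            it.habitat = "farmed"
            items.append(it)
        for i, v in enumerate(wild_vals):
            it = make_item(f"w{i}", "salmon", **{nutrient: v})
            it.habitat = "wild"
            items.append(it)
        return items

    def test_identical_groups(self):
        items = self._items([1, 2, 3, 4], [1, 2, 3, 4])
        res = compare_wild_farmed(items, "iron")
        assert res.mean_difference == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_omega3_total_fat_ratio_of_means(self):
        # farmed means omega-3 0.88 g, total fat 6.90 g -> ratio 0.1275...
        items = []
        for i, (o3, fat) in enumerate([(0.8, 6.8), (0.96, 7.0)]):
            it = make_item(f"f{i}", "salmon", omega3=o3, total_fat=fat)
            it.habitat = "farmed"
            items.append(it)
        for i, (o3, fat) in enumerate([(0.7, 3.2), (0.74, 3.28)]):
            it = make_item(f"w{i}", "salmon", omega3=o3, total_fat=fat)
            it.habitat = "wild"
            items.append(it)
        res = compare_wild_farmed(items, "omega3")
        assert res.ratio_metrics["omega3_total_fat_ratio_farmed"] == pytest.approx(
            0.88 / 6.90, abs=1e-6
        )

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            farmed = rng.normal(1.0, 0.4, int(rng.integers(4, 12)))
            wild = rng.normal(1.5, 0.4, int(rng.integers(4, 12)))
            items = self._items(farmed, wild)
            res = compare_wild_farmed(items, "iron")
            anova = one_way_anova({"farmed": farmed, "wild": wild})
            assert res.t_statistic**2 == pytest.approx(anova.f_statistic, rel=1e-9)
            assert res.p_value == pytest.approx(anova.p_value, rel=1e-9)

    def test_missing_habitat_group_rejected(self):
        items = [make_item("f0", "salmon", iron=1.0)]  # habitat unknown
        with pytest.raises(ValueError, match="habitat"):
            compare_wild_farmed(items, "iron")

    def test_per_item_ratio_metric(self):
        items = self._items([1, 2, 3], [4, 5, 6])
        for it in items:
            it.nutrients.omega3 = 0.5
            it.nutrients.total_fat = 4.0
        res = compare_wild_farmed(items, "omega3_total_fat_ratio")
        assert res.mean_farmed == pytest.approx(0.125)


class TestSyntheticIronContrast:
    def test_mollusk_vs_finfish_iron_significant(self):
        # published-moment synthetic data: the mollusk-finfish iron gap is
        # declared significant in every seeded replicate
        from aquanrf.scoring import score_dataset  # noqa: F401  (import guard)
        from aquanrf.stats import one_way_anova
        from aquanrf.synthetic import generate_dataset, load_generator_config

        config = load_generator_config()
        hits = 0
        n_reps = 10
        for seed in range(n_reps):
            items = generate_dataset(config, seed=seed)
            groups: dict[str, list[float]] = {"mollusk": [], "finfish": []}
            for it in items:
                if it.broad_group in groups and it.nutrients.iron is not None:
                    groups[it.broad_group].append(it.nutrients.iron)
            res = one_way_anova(groups)
            if res.p_value < 0.05:
                hits += 1
        assert hits == n_reps  # >= 99% required; expect 10/10 at this effect size


def test_summary_strings_format():
    samples = {"a": [1.0, 2.0, 3.0], "b": [10.0, 11.0, 12.0]}
    tk = tukey_hsd(samples)
    strings = summary_strings(samples, tk)
    assert strings["a"].startswith("2.00^")
    assert "(1.00)" in strings["a"]
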