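import numpy as np
import pytest
from scipy import stats as sps

from rhizosense.group_stats import (
    StatsError,
    assign_categories,
    category_summary,
    compact_letters,
    one_way_anova,
    tukey_kramer,
)


def anova_oracle(groups):
    """Textbook sums-of-squares computation, independent of the implementation."""
    allv = np.concatenate([np.asarray(g, float) for g in groups])
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0, abs=1e-15)
        assert not res.undefined

    def test_matches_textbook_oracle(self):
        groups = [[3.1, 2.7, 3.3], [4.0, 4.4, 3.9, 4.1], [1.2, 1.5, 0.9, 1.1, 1.4]]
        res = one_way_anova(groups)
        assert res.F == pytest.approx(anova_oracle(groups), abs=1e-10)
        assert (res.df_between, res.df_within) == (2, 9)
        # independent route: scipy
        F, p = sps.f_oneway(*groups)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_two_groups_f_is_squared_t(self):
        a, b = [1.0, 2.0, 3.0, 2.5], [4.0, 5.0, 4.5]
        res = one_way_anova([a, b])
        t, _ = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2, rel=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=n) for n in (4, 6, 5)]
        f0 = one_way_anova(groups).F
        shifted = [3.0 * np.asarray(g) - 7.0 for g in groups]
        assert one_way_anova(shifted).F == pytest.approx(f0, rel=1e-10)

    def test_all_constant_is_undefined(self):
        res = one_way_anova([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.undefined

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(StatsError):
            one_way_anova([[1.0], [2.0]])


class TestTukeyKramer:
    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 5)
        b = rng.normal(10.0, 1.0, 5)  # 10 pooled SDs apart
        res = tukey_kramer([a, b], names=["low", "high"])
        assert res.pairwise["significant"].all()
        assert res.letters["low"] != res.letters["high"]

    def test_identical_groups_share_a_letter(self):
        g = [1.0, 2.0, 3.0]
        res = tukey_kramer([g, g, g], names=["a", "b", "c"])
        assert not res.pairwise["significant"].any()
        assert len({v for v in res.letters.values()}) == 1

    def test_equal_n_reduces_to_classical_tukey_se(self):
        """With equal n the Kramer SE equals sqrt(MSW/n)."""
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1.0, 6) for m in (0, 1, 2)]
        res = tukey_kramer(groups)
        expected_se = np.sqrt(res.ms_within / 6)
        assert np.allclose(res.pairwise["se"], expected_se, rtol=1e-12)

    def test_pvalues_match_scipy_tukey_hsd(self):
        """Independent cross-check against scipy's Tukey-Kramer implementation."""
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1.0, n) for m, n in ((0, 4), (0.5, 7), (2.5, 5))]
        res = tukey_kramer(groups, names=["a", "b", "c"])
        sp = sps.tukey_hsd(*groups)
        pairs = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        for _, row in res.pairwise.iterrows():
            i, j = pairs[(row["group_1"], row["group_2"])]
            assert row["p"] == pytest.approx(sp.pvalue[i, j], abs=1e-8)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.0, 5) for m in (0, 1, 4)]
        r1 = tukey_kramer(groups, names=["x", "y", "z"])
        r2 = tukey_kramer(groups[::-1], names=["z", "y", "x"])
        assert r1.letters == r2.letters

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            tukey_kramer([[1.0], [2.0, 3.0]])


class TestCompactLetters:
    def test_valid_clique_cover_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            k = int(rng.integers(2, 7))
            means = rng.normal(size=k)
            sig = np.zeros((k, k), bool)
            for i in range(k):
                for j in range(i + 1, k):
                    sig[i, j] = sig[j, i] = rng.random() < 0.4
            names = [f"g{i}" for i in range(k)]
            letters = compact_letters(names, means, sig)
            for i in range(k):
                assert letters[names[i]], "every group needs at least one letter"
                for j in range(i + 1, k):
                    shared = set(letters[names[i]]) & set(letters[names[j]])
                    if sig[i, j]:
                        assert not shared, "significant pair must not share a letter"
                    else:
                        assert shared, "non-significant pair must share a letter"


class TestCategories:
    def test_known_assignments(self):
        a = assign_categories("KNO3")
        assert a.cation_category == "macronutrient"
        assert a.anion_category == "macronutrient"
        b = assign_categories("CuSO4")
        assert b.cation_category == "heavy_metal"
        assert b.anion_category == "secondary_nutrient"
        c = assign_categories("NaCl")
        assert c.cation_category == "sodium"
        assert c.anion_category == "micronutrient"

    def test_category_summary_structure(self):
        import pandas as pd

        rng = np.random.default_rng(4)
        rows = []
        for salt, mu in [("KNO3", 6), ("NH4Cl", 5.5), ("CaCl2", 5), ("MgCl2", 4.5),
                         ("NaCl", 5.2), ("CuSO4", 1.2), ("CdCl2", 1.0), ("LaCl3", 1.1)]:
            for _ in range(4):
                rows.append({"salt_name": salt, "role": "plant",
                             "ratio": mu + rng.normal(0, 0.4)})
        df = pd.DataFrame(rows)
        summary, anova, tukey = category_summary(df, by="cation")
        assert set(summary["category"]) == {
            "macronutrient", "secondary_nutrient", "sodium", "heavy_metal"
        }
        assert anova.p < 0.01
        assert tukey is not None
        hm = summary.set_index("category")
        # nutrients clearly separated from heavy metals in this construction
        assert hm.loc["heavy_metal", "letter"] != hm.loc["macronutrient", "letter"]
        assert (summary["ci_low"] <= summary["mean"]).all()
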