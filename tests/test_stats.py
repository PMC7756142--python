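"""Statistical battery: oracles, identities, and reference cross-checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from sharedreach import (
    DegenerateSampleError,
    IncompleteDesignError,
    InvalidArgumentError,
    art_rm_anova,
    art_transform,
    holm_adjust,
    holm_posthoc,
    mauchly_sphericity,
    paired_t,
    partial_eta_sq_from_f,
    rm_anova_oneway,
    rm_anova_twoway,
    shapiro_wilk,
    spearman,
    tukey_posthoc,
    wilcoxon_signed_rank,
)


class TestShapiroWilk:
    def test_three_point_symmetric_sample_is_perfectly_normal(self):
        assert shapiro_wilk([-1.0, 0.0, 1.0]).statistic == pytest.approx(1.0, abs=1e-6)

    def test_matches_reference_implementation(self):
        # frozen from R: shapiro.test(c(1,1,1,2,10)) -> W = 0.62463129
        assert shapiro_wilk([1, 1, 1, 2, 10]).statistic == pytest.approx(
            0.62463129, abs=1e-6
        )

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])


def _brute_force_wilcoxon_p(diffs):
    """Exact two-sided p by enumerating all 2^m sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = len(d)
    ws = [np.sum(ranks[list(signs)]) for signs in
          (np.array(bits, bool) for bits in itertools.product([0, 1], repeat=m))]
    ws = np.array(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))


class TestWilcoxonSignedRank:
    def test_all_positive_with_one_zero(self):
        # 20 pairs, one zero difference, 19 positive
        x = np.arange(1.0, 21.0)
        y = x - 1.0
        y[0] = x[0]  # one zero difference
        res = wilcoxon_signed_rank(x, y)
        assert res.statistic == 190.0
        assert res.effect_size == pytest.approx(1.0)
        assert res.p < 0.001
        assert res.extras["n_zero_dropped"] == 1

    def test_all_negative_mirror(self):
        x = np.arange(1.0, 21.0)
        y = x + 1.0
        y[0] = x[0]
        res = wilcoxon_signed_rank(x, y)
        assert res.statistic == 0.0
        assert res.effect_size == pytest.approx(-1.0)
        assert res.p < 0.001

    def test_small_example_by_hand(self):
        # differences {+1, -2, +3}: ranks {1,2,3}, W+ = 4, rb = 1/3
        res = wilcoxon_signed_rank([1.0, -2.0, 3.0])
        assert res.statistic == 4.0
        assert res.effect_size == pytest.approx(1 / 3)
        assert res.p == pytest.approx(0.75)  # matches scipy exact mode

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.2, 1.0, size=rng.integers(4, 11)), 1)
        d = d[d != 0]
        if len(d) == 0:
            return
        res = wilcoxon_signed_rank(d)
        assert res.p == pytest.approx(_brute_force_wilcoxon_p(d), abs=1e-12)

    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=20))
    def test_rank_sum_identity_and_effect_size_bounds(self, diffs):
        d = np.array([v for v in diffs if v != 0], float)
        if len(d) == 0:
            return
        res = wilcoxon_signed_rank(d)
        m = len(d)
        w_minus = m * (m + 1) / 2 - res.statistic
        assert res.effect_size == pytest.approx(
            (res.statistic - w_minus) / (m * (m + 1) / 2)
        )
        assert -1.0 <= res.effect_size <= 1.0
        assert 0.0 <= res.p <= 1.0

    def test_one_sample_form(self):
        res = wilcoxon_signed_rank([52.0, 61, 55, 70, 58], mu=50.0)
        assert res.statistic == 15.0
        assert res.effect_size == pytest.approx(1.0)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateSampleError):
            wilcoxon_signed_rank([3.0, 3.0], [3.0, 3.0])


class TestPairedT:
    def test_hand_computed_example(self):
        # differences {1,2,3}: t = 2*sqrt(3), df 2, dz = 2
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.df == (2.0,)
        assert res.effect_size == pytest.approx(2.0)

    def test_antisymmetric_differences_give_zero_t(self):
        res = paired_t([1.0, -1.0, 2.0, -2.0], [0.0, 0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(0.0)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        res = paired_t(x, y)
        t, p = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_constant_offset_rejected(self):
        with pytest.raises(DegenerateSampleError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestRmAnova:
    def test_df_bookkeeping_three_conditions_ten_units(self, rng):
        res = rm_anova_oneway(rng.normal(size=(10, 3)))
        assert res.df == (2.0, 18.0)

    def test_identical_columns_give_zero_f(self):
        col = np.arange(8.0)
        res = rm_anova_oneway(np.column_stack([col, col, col]))
        assert res.statistic == pytest.approx(0.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_partial_eta_identity_matches_printed_triples(self):
        assert partial_eta_sq_from_f(19.278, 2, 18) == pytest.approx(0.682, abs=0.001)
        assert partial_eta_sq_from_f(37.238, 2, 18) == pytest.approx(0.805, abs=0.001)
        assert partial_eta_sq_from_f(117.839, 2, 18) == pytest.approx(0.929, abs=0.001)

    def test_oneway_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        values = rng.normal(size=(9, 4)) + rng.normal(size=(9, 1))
        res = rm_anova_oneway(values)
        long = pd.DataFrame(
            {
                "y": values.ravel(),
                "cond": np.tile(np.arange(4), 9),
                "subj": np.repeat(np.arange(9), 4),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_twoway_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        values = rng.normal(size=(8, 2, 4)) + rng.normal(size=(8, 1, 1))
        out = rm_anova_twoway(values)
        rows = []
        for s in range(8):
            for a in range(2):
                for b in range(4):
                    rows.append({"y": values[s, a, b], "A": a, "B": b, "subj": s})
        ref = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["A", "B"], subject="subj"
        ).set_index("Source")
        assert out["A"].statistic == pytest.approx(float(ref.loc["A", "F"]), rel=1e-6)
        assert out["B"].statistic == pytest.approx(float(ref.loc["B", "F"]), rel=1e-6)
        assert out["A:B"].statistic == pytest.approx(float(ref.loc["A * B", "F"]), rel=1e-6)
        assert out["B"].df == (3.0, 21.0)

    def test_missing_cells_rejected(self):
        bad = np.full((5, 3), np.nan)
        with pytest.raises(IncompleteDesignError):
            rm_anova_oneway(bad)


class TestMauchly:
    def test_matches_pingouin_on_fixed_table(self, rng):
        import pandas as pd
        import pingouin as pg

        values = rng.normal(size=(10, 3)) + 0.5 * rng.normal(size=(10, 1))
        res = mauchly_sphericity(values)
        long = pd.DataFrame(
            {
                "y": values.ravel(),
                "cond": np.tile(np.arange(3), 10),
                "subj": np.repeat(np.arange(10), 3),
            }
        )
        ref = pg.sphericity(long, dv="y", within="cond", subject="subj")
        assert res.statistic == pytest.approx(float(ref.W), rel=1e-6)
        assert res.p == pytest.approx(float(ref.pval), rel=1e-6)

    def test_two_levels_not_applicable(self, rng):
        with pytest.raises(InvalidArgumentError):
            mauchly_sphericity(rng.normal(size=(10, 2)))


class TestHolm:
    def test_hand_step_down(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal(self):
        assert np.allclose(holm_adjust([0.02, 0.02, 0.02]), [0.06, 0.06, 0.06])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_monotone_and_never_below_raw(self, ps):
        adj = holm_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)


def _reference_art_twoway(values, effect):
    """Independent ART implementation via pandas groupby (test oracle)."""
    import pandas as pd

    n, a, b = values.shape
    rows = [
        {"y": values[s, i, j], "A": i, "B": j}
        for s in range(n) for i in range(a) for j in range(b)
    ]
    df = pd.DataFrame(rows)
    mu = df["y"].mean()
    cell = df.groupby(["A", "B"])["y"].transform("mean")
    ma = df.groupby("A")["y"].transform("mean")
    mb = df.groupby("B")["y"].transform("mean")
    resid = df["y"] - cell
    est = {"A": ma - mu, "B": mb - mu, "A:B": cell - ma - mb + mu}[effect]
    return sps.rankdata((resid + est).to_numpy()).reshape(values.shape)


class TestART:
    def test_rank_completeness(self, rng):
        values = rng.normal(size=(6, 2, 2))
        for effect in ("A", "B", "A:B"):
            ranks = art_transform(values, effect)
            total = values.size
            assert ranks.sum() == pytest.approx(total * (total + 1) / 2)

    def test_alignment_removes_other_effects(self):
        # pure main effect of A, zero residuals
        n, a, b = 6, 2, 3
        values = np.zeros((n, a, b)) + np.array([1.0, 5.0])[None, :, None]
        for effect in ("B", "A:B"):
            ranks = art_transform(values, effect)
            cell_means = ranks.mean(axis=0)
            assert np.allclose(cell_means, cell_means.mean())

    def test_oneway_art_equals_anova_on_ranks_of_raw_data(self, rng):
        values = rng.normal(size=(10, 3))
        art = art_rm_anova(values)["A"]
        plain = rm_anova_oneway(
            sps.rankdata(values.ravel()).reshape(values.shape)
        )
        assert art.statistic == pytest.approx(plain.statistic)

    def test_matches_reference_implementation_2x2(self, rng):
        values = rng.normal(size=(6, 2, 2)) + rng.normal(size=(6, 1, 1))
        for effect in ("A", "B", "A:B"):
            assert np.allclose(
                art_transform(values, effect), _reference_art_twoway(values, effect)
            )

    def test_session_effect_df(self, rng):
        values = rng.normal(size=(10, 2, 4))
        out = art_rm_anova(values, factor_names=("condition", "session", "interaction"))
        assert out["session"].df == (3.0, 27.0)
        assert out["condition"].df == (1.0, 9.0)


class TestPostHoc:
    def test_identical_levels_give_p_near_one(self, rng):
        base = rng.normal(size=10)
        values = np.column_stack([base, base.copy(), base + 3.0])
        table = tukey_posthoc(values)
        first = next(c for c in table.contrasts if c.label == "level0 - level1")
        assert first.p_adjusted > 0.99

    def test_three_levels_give_three_contrasts(self, rng):
        table = tukey_posthoc(rng.normal(size=(8, 3)))
        assert len(table.contrasts) == 3

    def test_tukey_effect_size_convention(self, rng):
        # d = t * sqrt(2/n) for the model-standardized difference
        values = rng.normal(size=(10, 3)) + np.array([0.0, 1.0, 2.0])
        for c in tukey_posthoc(values).contrasts:
            assert c.effect_size == pytest.approx(c.statistic * np.sqrt(2 / 10))

    def test_holm_posthoc_adjusted_never_below_raw(self, rng):
        table = holm_posthoc(rng.normal(size=(10, 3)) + np.array([0.0, 0.5, 1.0]))
        for c in table.contrasts:
            assert c.p_adjusted >= c.p_raw - 1e-12

    def test_tukey_familywise_error_under_null(self):
        rng = np.random.default_rng(99)
        hits = 0
        reps = 500
        for _ in range(reps):
            values = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
            table = tukey_posthoc(values)
            hits += any(c.p_adjusted < 0.05 for c in table.contrasts)
        # familywise error <= alpha + 3 binomial sd
        assert hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestSpearman:
    def test_strict_monotone_gives_one(self):
        assert spearman([1, 2, 5, 9], [2, 3, 10, 40]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 5, 9], [40, 10, 3, 2]).statistic == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        res = spearman([1, 2, 3, 4], [10, 30, 20, 40])
        assert res.statistic == pytest.approx(0.8)

    def test_exact_p_matches_permutation_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        res = spearman(x, y)
        # brute force: distribution of rho over all orderings of y
        rhos = []
        for perm in itertools.permutations(range(5)):
            rhos.append(np.corrcoef(np.arange(5), np.array(perm))[0, 1])
        rhos = np.array(rhos)
        lower = np.mean(rhos <= -abs(res.statistic) + 1e-9)
        upper = np.mean(rhos >= abs(res.statistic) - 1e-9)
        assert res.p == pytest.approx(min(1.0, lower + upper), abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateSampleError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
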