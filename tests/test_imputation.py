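"""The seven handling methods: worked examples, invariants, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hadsim import (
    METHODS,
    MissingnessSpec,
    apply_half_rule,
    complete_case_scores,
    impute_item_mean,
    impute_subject_mean,
    impute_subscale_mean,
    induce_missingness,
    mice_impute,
    score_with_method,
)
from hadsim.scales import scale_columns


def masked_matrix(n=12, seed=0, frac=0.25):
    """A small item matrix with random missingness."""
    rng = np.random.default_rng(seed)
    items = rng.integers(0, 4, size=(n, 14)).astype(float)
    mask = rng.uniform(size=items.shape) < frac
    items[mask] = np.nan
    return items


class TestSubjectMean:
    def test_single_missing_filled_with_row_mean(self):
        items = np.full((1, 14), 2.0)
        items[0, 3] = np.nan
        out = impute_subject_mean(items)
        assert out[0, 3] == pytest.approx(2.0)
        # depression score unchanged: 7 items x 2 = 14
        assert out[0, scale_columns("depression")].sum() == pytest.approx(14.0)

    def test_cross_subscale_leakage_by_construction(self):
        # anxiety all 3, depression observed all 0, one depression item
        # missing: the fill is the mean of the 13 observed items = 21/13
        items = np.zeros((1, 14))
        items[0, scale_columns("anxiety")] = 3.0
        items[0, 1] = np.nan  # item 2, depression
        out = impute_subject_mean(items)
        assert out[0, 1] == pytest.approx(21 / 13)
        assert out[0, scale_columns("depression")].sum() == pytest.approx(21 / 13)

    def test_identity_without_missing(self):
        items = masked_matrix(frac=0.0)
        assert np.array_equal(impute_subject_mean(items), items)

    def test_fully_missing_subject_left_unscored(self):
        items = np.full((2, 14), 1.0)
        items[1, :] = np.nan
        out = impute_subject_mean(items)
        assert np.isnan(out[1]).all() and not np.isnan(out[0]).any()


class TestSubscaleMean:
    def test_fills_with_subscale_mean(self):
        items = np.full((1, 14), np.nan)
        dep = scale_columns("depression")
        items[0, dep[:6]] = 1.0
        items[0, scale_columns("anxiety")] = 3.0
        out = impute_subscale_mean(items)
        assert out[0, dep[6]] == pytest.approx(1.0)
        assert out[0, dep].sum() == pytest.approx(7.0)

    def test_two_observed_five_missing(self):
        items = np.full((1, 14), 2.0)
        dep = scale_columns("depression")
        items[0, dep] = np.nan
        items[0, dep[0]] = 0.0
        items[0, dep[1]] = 3.0
        out = impute_subscale_mean(items)
        assert out[0, dep].sum() == pytest.approx(10.5)  # 7 x mean {0, 3}

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_equals_seven_times_observed_mean(self, seed):
        """Oracle: the subscale-mean score is 7 x the mean of the observed
        subscale items, checked cell-by-cell against brute force."""
        items = masked_matrix(n=8, seed=seed, frac=0.3)
        out = impute_subscale_mean(items)
        for scale in ("anxiety", "depression"):
            cols = scale_columns(scale)
            for i in range(items.shape[0]):
                row = items[i, cols]
                obs = row[~np.isnan(row)]
                if obs.size == 0:
                    assert np.isnan(out[i, cols]).all()
                else:
                    assert out[i, cols].sum() == pytest.approx(7 * obs.mean())


class TestItemMean:
    def test_fills_with_column_mean(self):
        items = np.full((3, 14), 1.0)
        items[0, 2] = 0.0
        items[1, 2] = 2.0
        items[2, 2] = np.nan
        out = impute_item_mean(items)
        assert out[2, 2] == pytest.approx(1.0)

    def test_all_missing_item_rejected(self):
        items = np.full((3, 14), 1.0)
        items[:, 5] = np.nan
        with pytest.raises(ValueError, match=r"\[6\]"):
            impute_item_mean(items)


class TestHalfRule:
    def test_boundary_four_observed_scored(self):
        items = np.full((1, 14), 1.0)
        dep = scale_columns("depression")
        items[0, dep[:3]] = np.nan  # 4 observed, 3 missing
        s = apply_half_rule(items)
        assert s.depression[0] == pytest.approx(7.0)

    def test_boundary_three_observed_missing(self):
        items = np.full((1, 14), 1.0)
        dep = scale_columns("depression")
        items[0, dep[:4]] = np.nan  # 3 observed, 4 missing
        s = apply_half_rule(items)
        assert np.isnan(s.depression[0])
        assert s.anxiety[0] == pytest.approx(7.0)
        assert np.isnan(s.distress[0])  # distress needs both subscales

    def test_invalid_inner_method(self):
        with pytest.raises(ValueError):
            apply_half_rule(masked_matrix(), inner_method="item_mean")


class TestMice:
    def test_identity_without_missing(self):
        items = masked_matrix(frac=0.0)
        out = mice_impute(items, m=3, rng=0)
        assert np.array_equal(out, items)

    def test_imputed_values_truncated(self):
        items = masked_matrix(n=30, seed=3, frac=0.3)
        out = mice_impute(items, m=5, rng=1)
        assert np.nanmin(out) >= 0.0 and np.nanmax(out) <= 3.0
        assert not np.isnan(out).any()

    def test_deterministic_given_seed(self):
        items = masked_matrix(n=30, seed=4, frac=0.3)
        a = mice_impute(items, m=10, rng=123)
        b = mice_impute(items, m=10, rng=123)
        assert np.array_equal(a, b)

    def test_observed_cells_untouched(self):
        items = masked_matrix(n=30, seed=5, frac=0.3)
        out = mice_impute(items, m=4, rng=2)
        obs = ~np.isnan(items)
        assert np.array_equal(out[obs], items[obs])

    def test_close_to_sklearn_chained_equations(self, source_cohort):
        """Independent cross-check: on a correlated-item dataset our
        chained-equations imputer and scikit-learn's IterativeImputer with
        posterior sampling agree on the mean of the imputed cells."""
        sklearn_exp = pytest.importorskip("sklearn.experimental.enable_iterative_imputer")
        from sklearn.impute import IterativeImputer

        rng = np.random.default_rng(9)
        items = source_cohort.items[:200].astype(float)
        mask = rng.uniform(size=items.shape) < 0.2
        masked = items.copy()
        masked[mask] = np.nan

        ours = mice_impute(masked, m=10, rng=11)
        theirs = np.zeros_like(items)
        for k in range(10):
            imp = IterativeImputer(
                sample_posterior=True, max_iter=10, min_value=0, max_value=3,
                random_state=k,
            )
            theirs += imp.fit_transform(masked)
        theirs /= 10
        assert ours[mask].mean() == pytest.approx(theirs[mask].mean(), abs=0.1)
        # both should sit reasonably near the deleted truth on average
        assert ours[mask].mean() == pytest.approx(items[mask].mean(), abs=0.25)


class TestCompleteCase:
    def test_no_missing_equals_standard_scoring(self, source_cohort):
        sub = source_cohort.take(np.arange(20))
        s = complete_case_scores(sub.items.astype(float))
        t = sub.true_scores()
        assert np.array_equal(s.depression, t.depression)
        assert s.n_scored("depression") == 20

    def test_candidates_excluded_when_everything_deleted(self, source_cohort, rng):
        sub = source_cohort.take(np.arange(52))
        spec = MissingnessSpec(
            mechanism="random", p_sub=0.5, p_item=1.0, target_scale="depression"
        )
        masked = induce_missingness(sub, spec, rng)
        n_candidates = int(masked.candidate_flags.sum())
        s = complete_case_scores(masked)
        assert s.n_scored("depression") == 52 - n_candidates
        # exclusion is per scale: anxiety is untouched by depression-scope deletion
        assert s.n_scored("anxiety") == 52


class TestDispatchInvariants:
    @pytest.mark.parametrize("method", METHODS)
    def test_observed_cells_and_score_ranges(self, source_cohort, method):
        rng = np.random.default_rng(31)
        sub = source_cohort.take(np.arange(40))
        spec = MissingnessSpec(mechanism="subscale", p_sub=0.5, p_item=0.5)
        masked = induce_missingness(sub, spec, rng)
        scores = score_with_method(masked, method, rng=rng)
        for scale, hi in (("anxiety", 21), ("depression", 21), ("distress", 42)):
            s = scores.scores(scale)
            finite = s[~np.isnan(s)]
            assert (finite >= 0).all() and (finite <= hi).all()
        # scores of untouched subjects equal the truth for every method
        truth = sub.true_scores()
        clean = ~masked.candidate_flags
        np.testing.assert_allclose(scores.depression[clean], truth.depression[clean])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            score_with_method(masked_matrix(), "oracle")
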