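"""Candidate selection and item deletion under the three mechanisms."""

import numpy as np
import pytest
from scipy import stats

from hadsim import (
    MissingnessSpec,
    delete_items,
    induce_missingness,
    overall_missing_rate,
    select_candidates,
)
from hadsim.scales import scale_columns


class TestOverallRate:
    @pytest.mark.parametrize(
        "p_sub, p_item, expected",
        [
            (0.1, 0.2, 2.0),
            (0.2, 0.2, 4.0),
            (0.1, 0.5, 5.0),
            (0.2, 0.5, 10.0),
            (0.5, 0.2, 10.0),
            (0.5, 0.5, 25.0),
        ],
    )
    def test_design_grid_rates(self, p_sub, p_item, expected):
        assert overall_missing_rate(p_sub, p_item) == pytest.approx(expected)

    def test_zero(self):
        assert overall_missing_rate(0.0, 0.7) == 0.0

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            overall_missing_rate(1.2, 0.5)


class TestCandidateSelection:
    @pytest.mark.parametrize("mechanism", ["random", "demographic", "subscale"])
    def test_p_sub_zero_selects_nobody(self, source_cohort, rng, mechanism):
        spec = MissingnessSpec(mechanism=mechanism, p_sub=0.0, p_item=0.5)
        assert select_candidates(source_cohort, spec, rng).size == 0

    def test_subscale_mechanism_picks_highest_scorers(self, rng):
        from hadsim import Cohort

        # 10 subjects with distinct depression scores 0, 2, ..., 18
        items = np.zeros((10, 14), dtype=int)
        dep_cols = scale_columns("depression")
        for i in range(10):
            items[i, dep_cols] = np.minimum(
                np.repeat(i * 2 // 7, 7) + (np.arange(7) < (i * 2) % 7), 3
            )
        cohort = Cohort(
            items=items,
            age=np.full(10, 60.0),
            male=np.zeros(10, dtype=bool),
            on_treatment=np.zeros(10, dtype=bool),
            immigrant=np.zeros(10, dtype=bool),
            qol=np.zeros(10),
        )
        truth = cohort.true_scores().depression
        assert len(np.unique(truth)) == 10
        spec = MissingnessSpec(mechanism="subscale", p_sub=0.2, p_item=0.5)
        chosen = select_candidates(cohort, spec, rng)
        assert sorted(chosen) == sorted(np.argsort(truth)[-2:])

    def test_ranking_mechanisms_exact_count(self, source_cohort, rng):
        for mechanism in ("subscale", "demographic"):
            for p_sub in (0.1, 0.2, 0.5):
                spec = MissingnessSpec(mechanism=mechanism, p_sub=p_sub, p_item=0.5)
                chosen = select_candidates(source_cohort, spec, rng)
                assert chosen.size == int(np.floor(p_sub * source_cohort.n + 0.5))

    def test_random_mechanism_candidate_count_binomial(self, source_cohort):
        """Candidate counts over replicates behave as Binomial(n, p_sub):
        a binomial test of the aggregate at the 1% level does not reject."""
        n, p_sub, reps = 52, 0.5, 10_000
        sub = source_cohort.take(np.arange(n))
        spec = MissingnessSpec(mechanism="random", p_sub=p_sub, p_item=0.5)
        rng = np.random.default_rng(2024)
        counts = np.array(
            [select_candidates(sub, spec, rng).size for _ in range(reps)]
        )
        assert counts.mean() == pytest.approx(n * p_sub, abs=0.2)
        res = stats.binomtest(int(counts.sum()), n * reps, p_sub)
        assert res.pvalue > 0.01

    def test_subscale_candidates_score_higher(self, source_cohort):
        spec = MissingnessSpec(mechanism="subscale", p_sub=0.3, p_item=0.5)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sample = source_cohort.take(rng.integers(0, source_cohort.n, 52))
            chosen = select_candidates(sample, spec, rng)
            truth = sample.true_scores().depression
            rest = np.setdiff1d(np.arange(sample.n), chosen)
            assert truth[chosen].mean() > truth[rest].mean()

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError):
            MissingnessSpec(mechanism="astrological", p_sub=0.1, p_item=0.2)


class TestDeletion:
    def test_p_item_zero_is_identity(self, source_cohort, rng):
        spec = MissingnessSpec(mechanism="random", p_sub=0.5, p_item=0.0)
        masked = induce_missingness(source_cohort, spec, rng)
        assert not masked.missing_mask.any()
        assert np.array_equal(masked.items, source_cohort.items.astype(float))

    def test_p_item_one_deletes_whole_scope(self, source_cohort, rng):
        spec = MissingnessSpec(
            mechanism="random", p_sub=0.5, p_item=1.0, target_scale="depression"
        )
        candidates = select_candidates(source_cohort, spec, rng)
        masked = delete_items(source_cohort, candidates, spec, rng)
        dep_cols = scale_columns("depression")
        assert np.isnan(masked.items[np.ix_(candidates, dep_cols)]).all()
        # anxiety columns untouched even for candidates
        anx_cols = scale_columns("anxiety")
        assert not np.isnan(masked.items[:, anx_cols]).any()

    def test_observed_cells_preserved(self, source_cohort, rng):
        spec = MissingnessSpec(mechanism="subscale", p_sub=0.5, p_item=0.5)
        masked = induce_missingness(source_cohort, spec, rng)
        obs = ~masked.missing_mask
        assert np.array_equal(masked.items[obs], source_cohort.items.astype(float)[obs])

    def test_missing_only_in_candidates_and_scope(self, source_cohort, rng):
        spec = MissingnessSpec(
            mechanism="demographic", p_sub=0.2, p_item=0.5, target_scale="anxiety"
        )
        masked = induce_missingness(source_cohort, spec, rng)
        miss = masked.missing_mask
        assert not miss[~masked.candidate_flags].any()
        dep_cols = scale_columns("depression")
        assert not miss[:, dep_cols].any()

    def test_in_scope_cell_rate_approaches_product(self, source_cohort):
        """Over replicates the fraction of deleted in-scope cells is
        p_sub * p_item (25% at 0.5 x 0.5) for the random mechanism."""
        spec = MissingnessSpec(mechanism="random", p_sub=0.5, p_item=0.5)
        rng = np.random.default_rng(77)
        sub = source_cohort.take(np.arange(52))
        rates = []
        for _ in range(400):
            masked = induce_missingness(sub, spec, rng)
            rates.append(
                np.isnan(masked.items[:, scale_columns("depression")]).mean()
            )
        assert 100 * np.mean(rates) == pytest.approx(25.0, abs=1.0)

    def test_distress_scope_covers_all_items(self, source_cohort, rng):
        spec = MissingnessSpec(
            mechanism="random", p_sub=1.0, p_item=1.0, target_scale="distress"
        )
        masked = induce_missingness(source_cohort, spec, rng)
        assert masked.missing_mask.all()

    def test_mask_round_trips_through_csv(self, source_cohort, rng, tmp_path):
        import pandas as pd

        spec = MissingnessSpec(mechanism="random", p_sub=0.5, p_item=0.5)
        masked = induce_missingness(source_cohort.take(np.arange(30)), spec, rng)
        df = pd.DataFrame(masked.items, columns=[f"hads{i}" for i in range(1, 15)])
        path = tmp_path / "masked.csv"
        df.to_csv(path, index=False)  # NaN -> empty field
        back = pd.read_csv(path).to_numpy()
        assert np.array_equal(np.isnan(back), masked.missing_mask)
        obs = ~masked.missing_mask
        assert np.array_equal(back[obs], masked.items[obs])
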