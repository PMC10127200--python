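import numpy as np
import pandas as pd
import pytest

from phenoselect.optimize import (
    aggregate_set,
    greedy_rank,
    improvement,
    rank_sets,
    ranking_frame,
    subsample_distribution,
    summarize,
)
from phenoselect.profiling import profile_screen
from phenoselect.simulate import SyntheticScreenConfig, generate_screen


def _tables(score_dict):
    """line -> {moa: score} dict into line -> Series."""
    return {line: pd.Series(scores) for line, scores in score_dict.items()}


class TestAggregation:
    def test_pairwise_max(self):
        tables = _tables({"A": {"m": 0.2}, "B": {"m": 0.7}})
        assert aggregate_set(tables, ["A", "B"])["m"] == 0.7

    def test_singleton_identity(self):
        tables = _tables({"A": {"m1": 0.3, "m2": 0.9}})
        pd.testing.assert_series_equal(
            aggregate_set(tables, ["A"]), tables["A"].sort_index()
        )

    def test_random_table_matches_brute_force(self):
        rng = np.random.default_rng(8)
        lines, moas = ["A", "B", "C"], ["m1", "m2", "m3", "m4"]
        tables = _tables(
            {l: {m: rng.uniform() for m in moas} for l in lines}
        )
        agg = aggregate_set(tables, lines)
        for m in moas:
            assert agg[m] == max(tables[l][m] for l in lines)

    def test_eligibility_requires_all_lines(self):
        tables = _tables({"A": {"m1": 0.1, "m2": 0.2}, "B": {"m1": 0.5}})
        agg = aggregate_set(tables, ["A", "B"])
        assert list(agg.index) == ["m1"]

    def test_missing_line_errors(self):
        with pytest.raises(ValueError, match="no score table"):
            aggregate_set(_tables({"A": {"m": 1.0}}), ["A", "Z"])


class TestSummaryAndImprovement:
    @pytest.mark.parametrize("scores, expected", [([0.2, 0.8], 0.5), ([0.4, 0.4], 0.4)])
    def test_mean_summary(self, scores, expected):
        assert summarize(pd.Series(scores)) == pytest.approx(expected)

    def test_random_scores_match_direct_summation(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(size=10)
        assert summarize(pd.Series(s)) == pytest.approx(sum(s) / 10)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no eligible"):
            summarize(pd.Series(dtype=float))

    def test_no_change_is_zero_percent(self):
        assert improvement(0.4, 0.4) == 0.0

    def test_zero_base_undefined(self):
        with pytest.raises(ValueError, match="base"):
            improvement(0.0, 0.5)


class TestRankSets:
    def test_single_line_gives_single_result(self, small_screen, small_profiles):
        only = small_profiles[small_profiles.cell_line == "L1"]
        ranked = rank_sets(only, small_screen.annotation, "phenoactivity", max_set_size=1)
        assert len(ranked) == 1 and ranked[0].lines == ("L1",)

    def test_sets_containing_best_line_never_worse(self, small_screen, small_profiles):
        ranked = rank_sets(small_profiles, small_screen.annotation, "phenoactivity",
                           max_set_size=2)
        by_lines = {r.lines: r.summary for r in ranked}
        best_single = max((l for l in by_lines if len(l) == 1), key=by_lines.get)
        for lines, summary in by_lines.items():
            if best_single[0] in lines:
                assert summary >= by_lines[best_single] - 1e-12

    def test_complementary_lines_form_top_pair(self):
        # MOAs 1-3 strong only in L1, MOAs 4-6 strong only in L2, L3 weak everywhere
        a = np.zeros((6, 3))
        a[:3, 0] = 2.5
        a[3:, 1] = 2.5
        a[:, 2] = 0.3
        cfg = SyntheticScreenConfig(
            n_cell_lines=3, n_features=10, n_active_features=4, n_moas=6,
            compounds_per_moa=4, cells_per_well=60, n_dmso_wells_per_plate=6,
            compound_wells_per_plate=12, effect_magnitude=a, heterogeneity=0.2,
            seed=12,
        )
        screen = generate_screen(cfg)
        profiles = profile_screen(screen.cells)
        ranked = rank_sets(profiles, screen.annotation, "phenoactivity", max_set_size=2)
        top_pair = next(r for r in ranked if len(r.lines) == 2)
        assert top_pair.lines == ("L1", "L2")

    def test_ordering_is_total_and_deterministic(self, small_screen, small_profiles):
        r1 = rank_sets(small_profiles, small_screen.annotation, "phenosimilarity",
                       max_set_size=2)
        r2 = rank_sets(small_profiles, small_screen.annotation, "phenosimilarity",
                       max_set_size=2)
        assert [r.lines for r in r1] == [r.lines for r in r2]
        keys = [(-r.summary, len(r.lines), r.lines) for r in r1]
        assert keys == sorted(keys)

    def test_greedy_matches_exhaustive_on_first_pick(self, small_screen, small_profiles):
        exhaustive = rank_sets(small_profiles, small_screen.annotation,
                               "phenoactivity", max_set_size=1)
        greedy = greedy_rank(small_profiles, small_screen.annotation,
                             "phenoactivity", max_set_size=1)
        assert greedy[0].lines == exhaustive[0].lines


class TestSubsampling:
    def test_fraction_one_reproduces_full_library(self, small_screen, small_profiles):
        results = subsample_distribution(
            small_profiles, small_screen.annotation, "phenoactivity",
            n_draws=3, fraction=1.0, seed=0, max_set_size=1,
        )
        for r in results:
            assert r.subsample_summaries == pytest.approx([r.summary] * 3)

    def test_fixed_seed_reproducible(self, small_screen, small_profiles):
        kwargs = dict(n_draws=5, fraction=2 / 3, seed=17, max_set_size=1)
        r1 = subsample_distribution(small_profiles, small_screen.annotation,
                                    "phenoactivity", **kwargs)
        r2 = subsample_distribution(small_profiles, small_screen.annotation,
                                    "phenoactivity", **kwargs)
        for a, b in zip(r1, r2):
            assert a.subsample_summaries.tolist() == b.subsample_summaries.tolist()

    def test_dispersion_shrinks_with_library_size(self):
        sds = []
        for n_moas in (4, 16):
            cfg = SyntheticScreenConfig(
                n_cell_lines=1, n_features=10, n_active_features=4, n_moas=n_moas,
                compounds_per_moa=4, cells_per_well=50, n_dmso_wells_per_plate=6,
                compound_wells_per_plate=16, effect_magnitude=1.0, heterogeneity=0.5,
                seed=23,
            )
            screen = generate_screen(cfg)
            profiles = profile_screen(screen.cells)
            results = subsample_distribution(
                profiles, screen.annotation, "phenoactivity",
                n_draws=30, fraction=2 / 3, seed=5, max_set_size=1,
            )
            sds.append(results[0].subsample_sd)
        assert sds[1] < sds[0]

    def test_ranking_frame_layout(self, small_screen, small_profiles):
        results = subsample_distribution(
            small_profiles, small_screen.annotation, "phenosimilarity",
            n_draws=4, fraction=0.8, seed=3, max_set_size=2,
        )
        frame = ranking_frame(results)
        assert list(frame.columns) == [
            "lines", "task", "summary", "subsample_mean", "subsample_sd", "n_moas"
        ]
        assert len(frame) == 3  # {L1}, {L2}, {L1;L2}
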