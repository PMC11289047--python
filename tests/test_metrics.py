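import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cjrank.corpus import Judgment, JudgmentSet, Problem, Rationale
from cjrank.metrics import (
    choice_accuracy,
    compare_accuracy,
    effect_size_from_prob,
    normalize_scores,
    percent_agreement,
    reference_ranking,
    spearman_rho,
    team_size_matrix,
    transitivity_fraction,
    winning_percentages,
)
from conftest import make_judgments


class TestWinningPercentages:
    def test_seven_of_ten_matchups_is_seventy_percent(self):
        # the worked example: 7 wins in 10 pairwise matchups -> 70%
        rows = []
        for k in range(10):
            opponent = f"o{k}"
            choice = "star" if k < 7 else opponent
            rows.append(("star", opponent, f"r{k % 3}", choice))
        recs = {r.item_id: r for r in winning_percentages(make_judgments(rows))}
        assert recs["star"].wins == 7 and recs["star"].matchups == 10
        assert recs["star"].win_pct == pytest.approx(0.70)

    def test_never_chosen_item_and_conservation(self, toy_judgments):
        recs = winning_percentages(toy_judgments)
        assert sum(r.wins for r in recs) == len(toy_judgments)
        loser = {r.item_id: r for r in recs}["a3"]
        assert loser.wins == 2  # only r3's perverse picks, in its two pairs

    def test_unjudged_item_flagged(self, toy_corpus, toy_judgments):
        recs = winning_percentages(toy_judgments, toy_corpus[1])
        by_id = {r.item_id: r for r in recs}
        assert by_id["b1"].matchups == 0 and by_id["b1"].win_pct is None


class TestNormalizeScores:
    def test_hand_example_with_orientation_flip(self):
        problems = [Problem("P", "graded", 1)]
        rats = [
            Rationale(f"i{k}", "P", 5, "", np.array([s]))
            for k, s in enumerate([0.2, 0.5, 0.8])
        ]
        z = [s.z for s in normalize_scores(rats, problems)]
        assert z == pytest.approx([1.0, 0.0, -1.0])

    def test_mean_zero_sd_one_within_problem(self):
        rng = np.random.default_rng(0)
        problems = [Problem("P", "graded", 2)]
        rats = [
            Rationale(f"i{k}", "P", 5, "", rng.random(2)) for k in range(20)
        ]
        z = np.array([s.z for s in normalize_scores(rats, problems)])
        assert abs(z.mean()) < 1e-9 and abs(z.std(ddof=1) - 1) < 1e-9

    def test_zero_variance_flagged(self):
        problems = [Problem("P", "binary", 1)]
        rats = [Rationale(f"i{k}", "P", 5, "", np.array([1.0])) for k in range(3)]
        out = normalize_scores(rats, problems)
        assert all(not s.defined and np.isnan(s.z) for s in out)


class TestCompareAccuracy:
    @pytest.mark.parametrize(
        "sa, sb, expected",
        [
            ([1, 1, 0], [1, 0, 0], "a_more"),
            ([1, 0, 1], [1, 0, 1], "tie"),
            ([1, 0], [0, 1], "tie"),
            ([0.2, 0.9], [0.4, 0.3], "tie"),  # one question each
        ],
    )
    def test_majority_of_question_wins(self, sa, sb, expected):
        a = Rationale("a", "P", 5, "", np.array(sa, dtype=float))
        b = Rationale("b", "P", 5, "", np.array(sb, dtype=float))
        assert compare_accuracy(a, b) == expected
        flipped = {"a_more": "b_more", "b_more": "a_more", "tie": "tie"}
        assert compare_accuracy(b, a) == flipped[expected]

    def test_cross_problem_rejected(self):
        a = Rationale("a", "P", 5, "", np.array([1.0]))
        b = Rationale("b", "Q", 5, "", np.array([1.0]))
        with pytest.raises(ValueError):
            compare_accuracy(a, b)


class TestChoiceAccuracy:
    def test_perfectly_aligned_choices(self, toy_corpus, toy_judgments):
        accurate_only = JudgmentSet(
            j for j in toy_judgments if j.rater_id in ("r1", "r2")
        )
        p, se = choice_accuracy(accurate_only, toy_corpus)
        assert p == 1.0 and se == 0.0

    def test_all_tied_pairs_undefined(self):
        rats = [
            Rationale("x", "P", 5, "", np.array([1.0, 0.0])),
            Rationale("y", "P", 5, "", np.array([0.0, 1.0])),
        ]
        js = make_judgments([("x", "y", "r1", "x")])
        with pytest.raises(ValueError):
            choice_accuracy(js, rats)


class TestPercentAgreement:
    def test_two_of_three_raters_agreeing(self):
        js = make_judgments(
            [("A", "B", "r1", "A"), ("A", "B", "r2", "A"), ("A", "B", "r3", "B")]
        )
        pct, half = percent_agreement(js)
        assert pct == pytest.approx(100 / 3)

    def test_unanimous_is_hundred(self, toy_judgments):
        js = JudgmentSet(j for j in toy_judgments if j.rater_id in ("r1", "r2"))
        assert percent_agreement(js)[0] == 100.0

    def test_invariant_to_relabeling_and_presentation_order(self):
        rows = [
            ("A", "B", "r1", "A"), ("B", "A", "r2", "A"), ("A", "B", "r3", "B"),
            ("C", "D", "r1", "D"), ("C", "D", "r2", "D"),
        ]
        base = percent_agreement(make_judgments(rows))
        relabeled = percent_agreement(
            make_judgments([(a, b, "x" + r, c) for a, b, r, c in rows])
        )
        swapped = percent_agreement(
            make_judgments([(b, a, r, c) for a, b, r, c in rows])
        )
        assert base == relabeled == swapped

    def test_requires_cojudged_pair(self):
        with pytest.raises(ValueError):
            percent_agreement(make_judgments([("A", "B", "r1", "A")]))


class TestTransitivity:
    def test_acyclic_majorities(self):
        js = make_judgments(
            [("A", "B", "r1", "A"), ("B", "C", "r1", "B"), ("A", "C", "r1", "A")]
        )
        assert transitivity_fraction(js) == (1.0, 1)

    def test_cyclic_majorities(self):
        js = make_judgments(
            [("A", "B", "r1", "A"), ("B", "C", "r1", "B"), ("A", "C", "r1", "C")]
        )
        assert transitivity_fraction(js) == (0.0, 1)

    def test_tied_majority_excludes_triple(self):
        js = make_judgments(
            [
                ("A", "B", "r1", "A"), ("A", "B", "r2", "B"),  # tied pair
                ("B", "C", "r1", "B"), ("A", "C", "r1", "A"),
            ]
        )
        with pytest.raises(ValueError):
            transitivity_fraction(js)

    def test_utility_consistent_judgments_fully_transitive(self):
        # deterministic utility comparator => no cycles, by construction
        rng = np.random.default_rng(4)
        util = {f"i{k}": float(u) for k, u in enumerate(rng.normal(size=12))}
        rows = []
        items = list(util)
        for i, a in enumerate(items):
            for b in items[i + 1:]:
                rows.append((a, b, "r1", a if util[a] > util[b] else b))
        frac, n = transitivity_fraction(make_judgments(rows))
        assert frac == 1.0 and n == 220


class TestSpearman:
    def test_identical_reversed_and_hand_example(self):
        ranking = ["a", "b", "c", "d"]
        assert spearman_rho(ranking, ranking) == pytest.approx(1.0)
        assert spearman_rho(ranking, ranking[::-1]) == pytest.approx(-1.0)
        # ranks (1,2,3,4) vs (2,1,4,3): 1 - 6*4/(4*15) = 0.6
        assert spearman_rho(ranking, ["b", "a", "d", "c"]) == pytest.approx(0.6)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(["a", "b", "c"], ["a", "b", "x"])


class TestReferenceRanking:
    def test_unanimous_transitive_order(self):
        rows = []
        for rater in ("r1", "r2"):
            rows += [
                ("A", "B", rater, "A"), ("B", "C", rater, "B"), ("A", "C", rater, "A"),
            ]
        assert reference_ranking(make_judgments(rows)) == ["A", "B", "C"]

    def test_incomplete_coverage_warns(self):
        js = make_judgments([("A", "B", "r1", "A"), ("B", "C", "r1", "B")])
        with pytest.warns(UserWarning, match="incomplete"):
            reference_ranking(js)

    def test_noiseless_simulation_matches_quality_order(self):
        from cjrank.schedulers import roundrobin_schedule
        from cjrank.simulate import (
            RaterModel,
            SimConfig,
            simulate_corpus,
            simulate_judgments,
        )

        sim = simulate_corpus(SimConfig(n_problems=1, items_per_problem=15, seed=2))
        items = [r.item_id for r in sim.rationales]
        schedule = roundrobin_schedule(items, 1, seed=0, problem_id="P001")
        js = simulate_judgments(
            sim, [RaterModel("oracle", beta=float("inf"))], schedule, seed=0
        )
        truth = sorted(items, key=lambda i: -sim.theta[i])
        assert reference_ranking(js) == truth


class TestEffectSize:
    @pytest.mark.parametrize(
        "p, d",
        [
            (0.50, 0.00),
            # the two prose-cited posterior means and their printed effect sizes
            (0.82, 1.29),
            (0.71, 0.78),
            # additional printed probability/effect cells, same conversion
            (0.61, 0.40),
            (0.65, 0.54),
            (0.73, 0.87),
            (0.70, 0.74),
            (0.85, 1.47),
            (0.62, 0.43),
            (0.52, 0.07),
        ],
    )
    def test_probability_of_superiority_conversion(self, p, d):
        assert round(effect_size_from_prob(p), 2) == d

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_odd_and_increasing(self, p):
        d = effect_size_from_prob(p)
        assert d == pytest.approx(-effect_size_from_prob(1 - p), abs=1e-9)
        assert effect_size_from_prob(min(p + 0.005, 0.995)) > d

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.7])
    def test_endpoints_rejected(self, p):
        with pytest.raises(ValueError):
            effect_size_from_prob(p)


class TestTeamSizeMatrix:
    @staticmethod
    def _corpus_two_sizes(n_items=4):
        rats = [
            Rationale(f"s{k}", "P", 5, "", np.array([1.0])) for k in range(n_items)
        ] + [
            Rationale(f"l{k}", "P", 21, "", np.array([1.0])) for k in range(n_items)
        ]
        return [Problem("P", "binary", 1)], rats

    def test_extreme_cells(self):
        corpus = self._corpus_two_sizes()
        rows = [(f"s{k % 4}", f"l{k % 4}", "r1", f"l{k % 4}") for k in range(200)]
        mat = team_size_matrix(make_judgments(rows), corpus, seed=0)
        assert mat.p.loc[5, 21] == pytest.approx(201 / 202)
        assert mat.n.loc[5, 21] == 200

    def test_prose_cited_cell_reproduced(self):
        # 82% preference for the larger team at large n: p ~= .82, d ~= 1.29
        corpus = self._corpus_two_sizes()
        rows = [
            (f"s{k % 4}", f"l{k % 4}", "r1", f"l{k % 4}" if k < 820 else f"s{k % 4}")
            for k in range(1000)
        ]
        mat = team_size_matrix(make_judgments(rows), corpus, seed=1)
        assert mat.p.loc[5, 21] == pytest.approx(0.82, abs=0.005)
        assert mat.d.loc[5, 21] == pytest.approx(1.29, abs=0.03)
        assert 0.0 < mat.d_sd.loc[5, 21] < 0.2

    def test_equal_sizes_rejected(self):
        rats = [
            Rationale("x", "P", 5, "", np.array([1.0])),
            Rationale("y", "P", 5, "", np.array([1.0])),
        ]
        with pytest.raises(ValueError):
            team_size_matrix(
                make_judgments([("x", "y", "r1", "x")]),
                ([Problem("P", "binary", 1)], rats),
            )
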