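import numpy as np
import pytest

from cjrank.corpus import Judgment, JudgmentSet, Problem, Rationale


@pytest.fixture
def toy_corpus():
    """Two problems, five rationales with known accuracy and team sizes."""
    problems = [
        Problem("PA", "binary", 2),
        Problem("PB", "graded", 1),
    ]
    rationales = [
        Rationale("a1", "PA", 5, "we answered more than average last time", np.array([1.0, 1.0])),
        Rationale("a2", "PA", 10, "however the answer follows in addition", np.array([1.0, 0.0])),
        Rationale("a3", "PA", 21, "the team guessed", np.array([0.0, 0.0])),
        Rationale("b1", "PB", 5, "roughly right", np.array([0.8])),
        Rationale("b2", "PB", 15, "way off", np.array([0.2])),
    ]
    return problems, rationales


@pytest.fixture
def toy_judgments():
    """Three raters on the three PA pairs; r1/r2 always prefer the more
    accurate item, r3 always the less accurate one."""
    rows = []
    k = 0
    for rater, pick_accurate in (("r1", True), ("r2", True), ("r3", False)):
        for a, b in (("a1", "a2"), ("a1", "a3"), ("a2", "a3")):
            k += 1
            choice = a if pick_accurate else b  # fixture orders a as more accurate
            rows.append(Judgment(f"j{k}", "PA", a, b, rater, choice))
    return JudgmentSet(rows)


def make_judgments(pairs_with_choices, problem_id="P"):
    """Judgments from (item_a, item_b, rater, choice) tuples."""
    return JudgmentSet(
        Judgment(f"j{i}", problem_id, a, b, rater, choice)
        for i, (a, b, rater, choice) in enumerate(pairs_with_choices)
    )
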