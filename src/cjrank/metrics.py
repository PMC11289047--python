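"""Scalar measures over forced-choice judgment sets.

Covers the full reporting surface of a comparative-judgment study:
per-item winning percentages, per-problem normalized accuracy, choice
accuracy against the more accurate solution, inter-rater percent agreement
with a normal-approximation CI, the fraction of transitive triples,
Spearman evaluation of rankings against a reference, and Bayesian
team-size preference probabilities with probability-of-superiority effect
sizes (d = √2·Φ⁻¹(p)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import JudgmentSet, Problem, Rationale

__all__ = [
    "WinRecord",
    "NormalizedScore",
    "PreferenceMatrix",
    "winning_percentages",
    "normalize_scores",
    "compare_accuracy",
    "choice_accuracy",
    "percent_agreement",
    "transitivity_fraction",
    "spearman_rho",
    "reference_ranking",
    "team_size_matrix",
    "effect_size_from_prob",
]


@dataclass(frozen=True)
class WinRecord:
    """Wins and matchups of one item; ``win_pct`` is None when the item was
    never put in front of a rater."""

    item_id: str
    problem_id: str
    wins: int
    matchups: int

    @property
    def win_pct(self) -> Optional[float]:
        if self.matchups == 0:
            return None
        return self.wins / self.matchups


@dataclass(frozen=True)
class NormalizedScore:
    """Per-problem z-scored accuracy, oriented so that lower z = more
    accurate; ``defined`` is False when the problem has no score variance."""

    item_id: str
    problem_id: str
    raw_score: float
    z: float
    defined: bool = True


@dataclass
class PreferenceMatrix:
    """Posterior team-size preference summary.

    All frames are indexed by the smaller team size (rows) and the larger
    (columns): ``p.loc[s, l]`` is the posterior mean probability that the
    larger team's rationale is chosen, ``d`` the matching effect size.
    """

    team_sizes: list[int]
    p: pd.DataFrame
    sd: pd.DataFrame
    d: pd.DataFrame
    d_sd: pd.DataFrame
    n: pd.DataFrame
    wins: pd.DataFrame


def winning_percentages(
    judgments: JudgmentSet, rationales: Optional[Sequence[Rationale]] = None
) -> list[WinRecord]:
    """Wins / matchups per item. An item's matchups count every judgment it
    appeared in; with ``rationales`` given, items never judged are included
    with zero matchups (win_pct flagged None)."""
    if len(judgments) == 0 and rationales is None:
        raise ValueError("empty judgment set")
    wins: dict[tuple[str, str], int] = {}
    matchups: dict[tuple[str, str], int] = {}
    if rationales is not None:
        for r in rationales:
            wins[(r.problem_id, r.item_id)] = 0
            matchups[(r.problem_id, r.item_id)] = 0
    for j in judgments:
        for item in (j.item_a, j.item_b):
            key = (j.problem_id, item)
            matchups[key] = matchups.get(key, 0) + 1
            wins.setdefault(key, 0)
        wins[(j.problem_id, j.choice)] += 1
    return [
        WinRecord(item, pid, wins[(pid, item)], matchups[(pid, item)])
        for pid, item in sorted(matchups)
    ]


def win_pct_series(judgments: JudgmentSet, rationales=None) -> pd.Series:
    """Winning percentages as a float Series indexed by item_id (NaN for
    items without matchups)."""
    recs = winning_percentages(judgments, rationales)
    return pd.Series(
        {r.item_id: (np.nan if r.win_pct is None else r.win_pct) for r in recs},
        name="win_pct",
    )


def normalize_scores(
    rationales: Sequence[Rationale], problems: Sequence[Problem]
) -> list[NormalizedScore]:
    """Within-problem z-scores of mean question accuracy, sign-flipped so
    that higher raw accuracy gives a *lower* z (sample sd, ddof=1).

    Problems with fewer than two rationales or zero score variance get
    z = NaN with ``defined=False``.
    """
    known = {p.problem_id for p in problems}
    by_problem: dict[str, list[Rationale]] = {}
    for r in rationales:
        if r.problem_id not in known:
            raise ValueError(f"rationale {r.item_id!r} has unknown problem")
        by_problem.setdefault(r.problem_id, []).append(r)
    out: list[NormalizedScore] = []
    for pid in sorted(by_problem):
        group = by_problem[pid]
        raw = np.array([r.mean_score for r in group])
        sd = raw.std(ddof=1) if raw.size > 1 else 0.0
        if raw.size < 2 or sd == 0.0:
            out.extend(
                NormalizedScore(r.item_id, pid, float(s), float("nan"), False)
                for r, s in zip(group, raw)
            )
            continue
        z = -(raw - raw.mean()) / sd
        out.extend(
            NormalizedScore(r.item_id, pid, float(s), float(v))
            for r, s, v in zip(group, raw, z)
        )
    return out


def compare_accuracy(a: Rationale, b: Rationale) -> str:
    """Which rationale supports the more accurate solution.

    Question-by-question, the higher score wins that question; the
    rationale winning more questions is the more accurate overall. Equal
    question-win counts give ``"tie"``.
    """
    if a.problem_id != b.problem_id:
        raise ValueError(
            f"cannot compare accuracy across problems "
            f"({a.problem_id!r} vs {b.problem_id!r})"
        )
    if a.question_scores.size != b.question_scores.size:
        raise ValueError("mismatched question counts")
    a_wins = int(np.sum(a.question_scores > b.question_scores))
    b_wins = int(np.sum(b.question_scores > a.question_scores))
    if a_wins > b_wins:
        return "a_more"
    if b_wins > a_wins:
        return "b_more"
    return "tie"


def choice_accuracy(
    judgments: JudgmentSet, corpus
) -> tuple[float, float]:
    """Fraction of choices that favored the strictly more accurate rationale.

    Pairs tied on accuracy are excluded from numerator and denominator.
    Returns (proportion, SE) with SE = sqrt(p(1−p)/N) over the untied
    judgments; raises if every judged pair is tied.
    """
    rationales = corpus[1] if isinstance(corpus, tuple) else list(corpus)
    by_item = {r.item_id: r for r in rationales}
    correct = 0
    total = 0
    for j in judgments:
        verdict = compare_accuracy(by_item[j.item_a], by_item[j.item_b])
        if verdict == "tie":
            continue
        more_accurate = j.item_a if verdict == "a_more" else j.item_b
        correct += j.choice == more_accurate
        total += 1
    if total == 0:
        raise ValueError("no judged pair differs in accuracy; choice accuracy undefined")
    p = correct / total
    return p, float(np.sqrt(p * (1 - p) / total))


def percent_agreement(judgments: JudgmentSet) -> tuple[float, float]:
    """Inter-rater percent agreement with a 95% normal-approximation CI.

    The unit is the rater-pair: for every unordered item pair, each pair
    of judgments by distinct raters contributes agree (1) or disagree (0).
    Returns (percentage, CI half-width), both on the 0–100 scale. Chance
    level for a two-alternative choice is 50%.
    """
    agreements: list[int] = []
    for group in judgments.by_pair.values():
        for j1, j2 in combinations(group, 2):
            if j1.rater_id == j2.rater_id:
                continue
            agreements.append(int(j1.choice == j2.choice))
    if not agreements:
        raise ValueError("no item pair was judged by two distinct raters")
    arr = np.asarray(agreements, dtype=float)
    p = arr.mean()
    half = 1.96 * np.sqrt(p * (1 - p) / arr.size)
    return float(p * 100), float(half * 100)


def _majority_winners(judgments: JudgmentSet) -> dict[tuple[str, frozenset], str]:
    """Majority choice per (problem, unordered pair); ties are omitted."""
    winners: dict[tuple[str, frozenset], str] = {}
    for key, group in judgments.by_pair.items():
        counts: dict[str, int] = {}
        for j in group:
            counts[j.choice] = counts.get(j.choice, 0) + 1
        items = sorted(key[1])
        ca, cb = counts.get(items[0], 0), counts.get(items[1], 0)
        if ca == cb:
            continue
        winners[key] = items[0] if ca > cb else items[1]
    return winners


def transitivity_fraction(judgments: JudgmentSet) -> tuple[float, int]:
    """Fraction of item triples whose majority orientations contain no cycle.

    Within each problem, every triple of items with a defined (untied)
    majority on all three pairs is evaluated; a triple is transitive iff
    one item beats both others (equivalently, the 3-tournament is acyclic).
    Under uniform-random orientations 6 of the 8 configurations are
    acyclic, so the chance baseline is 0.75.
    """
    winners = _majority_winners(judgments)
    items_by_problem: dict[str, set[str]] = {}
    for (pid, pair) in winners:
        items_by_problem.setdefault(pid, set()).update(pair)
    transitive = 0
    total = 0
    for pid, items in items_by_problem.items():
        for a, b, c in combinations(sorted(items), 3):
            ws = []
            for pair in (frozenset((a, b)), frozenset((b, c)), frozenset((a, c))):
                w = winners.get((pid, pair))
                if w is None:
                    break
                ws.append(w)
            else:
                total += 1
                # cyclic iff each item wins exactly one of its two pairs
                counts = {a: 0, b: 0, c: 0}
                for w in ws:
                    counts[w] += 1
                transitive += max(counts.values()) == 2
    if total == 0:
        raise ValueError("no evaluable triple (need untied majorities on all three pairs)")
    return transitive / total, total


def spearman_rho(ranking_a: Sequence[str], ranking_b: Sequence[str]) -> float:
    """Spearman rank correlation between two rankings of the same item set."""
    if len(ranking_a) < 3:
        raise ValueError("need at least 3 items")
    if set(ranking_a) != set(ranking_b) or len(set(ranking_a)) != len(ranking_a):
        raise ValueError("rankings must be permutations of the same item set")
    pos_b = {item: i for i, item in enumerate(ranking_b)}
    ranks_a = np.arange(len(ranking_a))
    ranks_b = np.array([pos_b[item] for item in ranking_a])
    rho = stats.spearmanr(ranks_a, ranks_b).statistic
    return float(rho)


def reference_ranking(
    judgments: JudgmentSet,
    raters: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> list[str]:
    """Items ordered best-first by winning percentage over all comparisons
    made by the selected raters (all raters by default); ties broken by a
    seeded shuffle. Warns (and proceeds) if pair coverage is incomplete."""
    js = judgments if raters is None else judgments.subset_raters(raters)
    if len(js) == 0:
        raise ValueError("no judgments from the selected raters")
    recs = winning_percentages(js)
    items_per_problem: dict[str, set[str]] = {}
    for r in recs:
        items_per_problem.setdefault(r.problem_id, set()).add(r.item_id)
    n_pairs_expected = sum(
        len(g) * (len(g) - 1) // 2 for g in items_per_problem.values()
    )
    if len(js.by_pair) < n_pairs_expected:
        warnings.warn(
            "incomplete pair coverage; ranking uses available matchups only",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(len(recs))
    order = sorted(
        range(len(recs)),
        key=lambda i: (-(recs[i].win_pct or 0.0), tiebreak[i]),
    )
    return [recs[i].item_id for i in order]


def effect_size_from_prob(p: float) -> float:
    """Cohen's d matching a probability of superiority: d = √2·Φ⁻¹(p).

    Inverse of p = Φ(d/√2), the probability that a draw from a normal
    population shifted by d exceeds a draw from the reference population.
    Strictly increasing, odd about p = 0.5; infinite at p ∈ {0, 1}.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1); endpoints map to ±inf")
    return float(np.sqrt(2.0) * stats.norm.ppf(p))


def team_size_matrix(
    judgments: JudgmentSet,
    corpus,
    prior: tuple[float, float] = (1.0, 1.0),
    n_posterior_draws: int = 4000,
    seed: int = 0,
) -> PreferenceMatrix:
    """Posterior probability that the larger team's rationale is chosen,
    per team-size pair, under a Beta(α, β) prior on the choice probability.

    Judgments between equal team sizes are excluded. For each size pair
    the posterior is Beta(α + wins, β + n − wins); the posterior mean and
    sd are closed-form, while the effect-size sd comes from seeded
    posterior draws pushed through :func:`effect_size_from_prob`. Cells
    with no data stay NaN.
    """
    rationales = corpus[1] if isinstance(corpus, tuple) else list(corpus)
    size_of = {r.item_id: r.team_size for r in rationales}
    alpha, beta = prior
    if alpha <= 0 or beta <= 0:
        raise ValueError("prior parameters must be positive")

    tallies: dict[tuple[int, int], list[int]] = {}
    for j in judgments:
        sa, sb = size_of[j.item_a], size_of[j.item_b]
        if sa == sb:
            continue
        small, large = sorted((sa, sb))
        larger_item = j.item_a if sa > sb else j.item_b
        win, n = tallies.setdefault((small, large), [0, 0])
        tallies[(small, large)][0] += j.choice == larger_item
        tallies[(small, large)][1] += 1
    if not tallies:
        raise ValueError("judgments span fewer than 2 distinct team sizes")

    sizes = sorted({s for pair in tallies for s in pair})
    frames = {
        name: pd.DataFrame(np.nan, index=sizes, columns=sizes)
        for name in ("p", "sd", "d", "d_sd", "n", "wins")
    }
    rng = np.random.default_rng(seed)
    for (small, large), (wins, n) in sorted(tallies.items()):
        a_post = alpha + wins
        b_post = beta + n - wins
        p_mean = a_post / (a_post + b_post)
        p_sd = np.sqrt(
            a_post * b_post / ((a_post + b_post) ** 2 * (a_post + b_post + 1))
        )
        draws = rng.beta(a_post, b_post, size=n_posterior_draws)
        draws = np.clip(draws, 1e-12, 1 - 1e-12)
        d_draws = np.sqrt(2.0) * stats.norm.ppf(draws)
        frames["p"].loc[small, large] = p_mean
        frames["sd"].loc[small, large] = p_sd
        frames["d"].loc[small, large] = effect_size_from_prob(p_mean)
        frames["d_sd"].loc[small, large] = d_draws.std(ddof=1)
        frames["n"].loc[small, large] = n
        frames["wins"].loc[small, large] = wins
    return PreferenceMatrix(team_sizes=sizes, **frames)
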