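"""Thurstonian simulator for corpora and raters.

Stands in for human studies when validating the comparative-judgment
machinery. Each rationale carries a latent quality θ that increases with
the log of the producing team's size (larger teams write better-reasoned,
more accurate answers); per-question correctness follows a logistic link
on θ; and a rater choosing between two rationales picks the first with
probability Φ(β·(θ_a − θ_b)) — Thurstone's Case V — where β is the
rater's discriminability. β = 0 is a coin-flipping rater, β → ∞ a perfect
one; an optional lapse rate mixes in uniform-random choices. The probit
choice function makes the simulator's probability of superiority cohere
exactly with the d = √2·Φ⁻¹(p) effect-size convention used in
:mod:`cjrank.metrics`.

Texts are generated from the same θ: token count and the planted rates of
configurable lexicon tokens rise linearly with quality, with Gaussian
noise, so the linguistic-feature pipeline has a recoverable signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.special import expit

from .corpus import Judgment, JudgmentSet, Problem, Rationale
from .features import DEFAULT_LEXICONS, LexiconSet
from .schedulers import ComparisonRequest

__all__ = [
    "RaterModel",
    "TextConfig",
    "SimConfig",
    "SimulatedCorpus",
    "simulate_corpus",
    "simulate_choice",
    "simulate_judgments",
    "simulate_text",
]


@dataclass(frozen=True)
class RaterModel:
    """A simulated rater: discriminability ``beta`` (in latent-quality
    units⁻¹; may be ``inf`` for a deterministic rater) and a lapse rate in
    [0, 0.5] giving the probability of a uniform-random choice."""

    rater_id: str
    beta: float = 1.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0 or math.isnan(self.beta):
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5]")

    @property
    def deterministic(self) -> bool:
        return math.isinf(self.beta)


@dataclass(frozen=True)
class TextConfig:
    """Links from latent quality to text features.

    ``word_count_link`` is tokens per θ-unit; ``rate_links`` map lexicon
    names to (rate per 100 tokens) per θ-unit. ``theta_center`` anchors
    the linear links at the default corpus' mean quality so base values
    are corpus-typical.
    """

    base_word_count: float = 150.0
    word_count_link: float = 30.0
    word_count_sd: float = 40.0
    min_word_count: int = 20
    base_rate: float = 2.0
    rate_sd: float = 1.5
    max_rate: float = 30.0
    theta_center: float = 3.5
    rate_links: dict = field(
        default_factory=lambda: {
            "comparison_class": 1.5,
            "elaboration": 0.75,
            "dialectical": 0.75,
            "first_person_pronouns": 0.5,
        }
    )


# Neutral vocabulary disjoint from every default lexicon, so planted
# lexicon rates are exactly the configured ones.
_FILLER_WORDS = (
    "the a answer question team this that evidence because therefore shows "
    "data given problem solution correct reasoning argument based likely "
    "clearly each from with they their which statement information case "
    "follows consider possible both key detail supports conclusion"
).split()


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for a synthetic study corpus.

    Defaults mirror the scale of the motivating studies: nine problems of
    ~16 rationales each, teams of 5/10/15/21 members mixed 4:6:4:4 (the
    study's team composition), latent quality θ = slope·log2(team_size) +
    N(0, noise), and per-question P(correct) = logistic(link·(θ − center)).
    The center anchors corpus-mean accuracy near the 0.6 proportion
    correct typical of hard group reasoning tasks, so accuracy comparisons
    stay informative rather than saturating at the ceiling.
    """

    n_problems: int = 9
    items_per_problem: int = 16
    team_sizes: tuple = (5, 10, 15, 21)
    team_size_weights: tuple = (4.0, 6.0, 4.0, 4.0)
    quality_slope: float = 1.0
    quality_noise: float = 0.5
    accuracy_link: float = 1.0
    accuracy_center: float = 3.1
    n_questions: int = 3
    seed: int = 0
    text: Optional[TextConfig] = TextConfig()

    def __post_init__(self) -> None:
        if self.n_problems < 1 or self.items_per_problem < 1:
            raise ValueError("n_problems and items_per_problem must be >= 1")
        if len(self.team_sizes) != len(self.team_size_weights):
            raise ValueError("team_sizes and team_size_weights must align")
        if any(s < 1 for s in self.team_sizes):
            raise ValueError("team sizes must be positive")
        if any(w < 0 for w in self.team_size_weights) or not sum(
            self.team_size_weights
        ):
            raise ValueError("weights must be nonnegative and not all zero")
        if self.quality_noise < 0:
            raise ValueError("quality_noise must be >= 0")
        if self.n_questions < 1:
            raise ValueError("n_questions must be >= 1")


class SimulatedCorpus(NamedTuple):
    """A generated corpus plus its hidden ground truth θ (kept out of the
    Rationale objects so corpus round-trips cannot leak it)."""

    problems: list
    rationales: list
    theta: dict


def simulate_text(
    theta: float,
    lexicons: LexiconSet,
    rng: np.random.Generator,
    config: Optional[TextConfig] = None,
) -> str:
    """A synthetic rationale text whose length and planted lexicon-token
    rates track θ under the configured linear links."""
    cfg = config or TextConfig()
    if len(lexicons) == 0:
        raise ValueError("lexicons must be nonempty")
    dev = theta - cfg.theta_center
    n_tokens = int(
        max(
            cfg.min_word_count,
            round(rng.normal(cfg.base_word_count + cfg.word_count_link * dev,
                             cfg.word_count_sd)),
        )
    )
    tokens: list[str] = []
    for name in lexicons.names:
        link = cfg.rate_links.get(name, 0.0)
        rate = float(
            np.clip(rng.normal(cfg.base_rate + link * dev, cfg.rate_sd),
                    0.0, cfg.max_rate)
        )
        count = int(round(rate * n_tokens / 100.0))
        vocab = sorted(lexicons[name].tokens)
        if count and vocab:
            tokens.extend(rng.choice(vocab, size=count).tolist())
    tokens = tokens[: n_tokens // 2]  # planted tokens never crowd out filler
    tokens.extend(
        rng.choice(_FILLER_WORDS, size=n_tokens - len(tokens)).tolist()
    )
    perm = rng.permutation(len(tokens))
    return " ".join(tokens[i] for i in perm)


def simulate_corpus(config: Optional[SimConfig] = None) -> SimulatedCorpus:
    """Generate problems and rationales with team-size-dependent quality.

    θ_i = quality_slope·log2(team_size_i) + N(0, quality_noise); each of
    ``n_questions`` scores is Bernoulli(logistic(accuracy_link·(θ_i −
    accuracy_center))). Reproducible under ``config.seed``.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    weights = np.asarray(cfg.team_size_weights, dtype=float)
    weights = weights / weights.sum()

    problems: list[Problem] = []
    rationales: list[Rationale] = []
    theta: dict[str, float] = {}
    item_no = 0
    for p in range(cfg.n_problems):
        pid = f"P{p + 1:03d}"
        problems.append(Problem(pid, "binary", cfg.n_questions))
        for _ in range(cfg.items_per_problem):
            item_no += 1
            iid = f"R{item_no:04d}"
            size = int(rng.choice(cfg.team_sizes, p=weights))
            th = cfg.quality_slope * math.log2(size) + rng.normal(
                0.0, cfg.quality_noise
            )
            p_correct = expit(cfg.accuracy_link * (th - cfg.accuracy_center))
            scores = (rng.random(cfg.n_questions) < p_correct).astype(float)
            text = (
                simulate_text(th, DEFAULT_LEXICONS, rng, cfg.text)
                if cfg.text is not None
                else ""
            )
            rationales.append(
                Rationale(
                    item_id=iid,
                    problem_id=pid,
                    team_size=size,
                    text=text,
                    question_scores=scores,
                    protocol="delphi" if rng.random() < 0.5 else "free",
                )
            )
            theta[iid] = float(th)
    return SimulatedCorpus(problems, rationales, theta)


def simulate_choice(
    rater: RaterModel,
    theta_a: float,
    theta_b: float,
    rng: np.random.Generator,
) -> str:
    """One forced choice: returns ``"a"`` or ``"b"``.

    With probability ``lapse_rate`` the rater picks uniformly; otherwise
    P(a) = Φ(β(θ_a − θ_b)). A deterministic (β = ∞) rater always picks
    the higher θ, flipping a fair coin on exact ties.
    """
    if rater.lapse_rate and rng.random() < rater.lapse_rate:
        return "a" if rng.random() < 0.5 else "b"
    if rater.deterministic:
        if theta_a == theta_b:
            return "a" if rng.random() < 0.5 else "b"
        return "a" if theta_a > theta_b else "b"
    from scipy.stats import norm

    p_a = norm.cdf(rater.beta * (theta_a - theta_b))
    return "a" if rng.random() < p_a else "b"


def simulate_judgments(
    corpus: SimulatedCorpus,
    raters: Sequence[RaterModel],
    schedule: Sequence[ComparisonRequest],
    seed: int = 0,
) -> JudgmentSet:
    """Answer a comparison schedule with simulated raters.

    Request ``replicate_index`` k is answered by ``raters[(k − 1) mod
    len(raters)]``, so an r-replicate round-robin with r raters gives each
    pair one choice from each rater.
    """
    if not raters:
        raise ValueError("at least one rater is required")
    theta = corpus.theta
    problem_of = {r.item_id: r.problem_id for r in corpus.rationales}
    rng = np.random.default_rng(seed)
    judgments = []
    for i, req in enumerate(schedule):
        for item in (req.item_a, req.item_b):
            if item not in theta:
                raise ValueError(f"schedule references unknown item {item!r}")
        rater = raters[(req.replicate_index - 1) % len(raters)]
        side = simulate_choice(rater, theta[req.item_a], theta[req.item_b], rng)
        choice = req.item_a if side == "a" else req.item_b
        judgments.append(
            Judgment(
                judgment_id=f"J{i + 1:06d}",
                problem_id=req.problem_id or problem_of[req.item_a],
                item_a=req.item_a,
                item_b=req.item_b,
                rater_id=rater.rater_id,
                choice=choice,
            )
        )
    return JudgmentSet(judgments)
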