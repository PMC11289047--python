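"""Data model and file I/O for rationales, problems, and pairwise judgments.

The unit of comparison is a *rationale*: a team's written justification of
its answer to a reasoning problem. Each problem carries one or more scored
questions; per-question correctness lives on the rationale as a vector of
values in [0, 1] (1 = fully correct; graded problems use closeness to the
true answer on the same scale). A *judgment* is one forced choice by one
rater between two rationales for the same problem.

File formats are deliberately small: UTF-8 CSV with fixed headers, or a
JSON container with the same field names. ``corpus.csv`` columns are
``item_id, problem_id, team_size, protocol, text, q1..qk`` (trailing q
columns may be empty for problems with fewer questions); ``judgments.csv``
columns are ``judgment_id, problem_id, item_a, item_b, rater_id, choice,
response_time_s``.
"""

from __future__ import annotations

import json
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "Problem",
    "Rationale",
    "Judgment",
    "JudgmentSet",
    "read_corpus",
    "write_corpus",
    "read_judgments",
    "write_judgments",
    "read_ranking",
    "write_ranking",
]

SCORING_MODES = ("binary", "graded")
PROTOCOLS = ("delphi", "free")


class ValidationError(ValueError):
    """Malformed corpus or judgment input; the message names the offending row."""


@dataclass(frozen=True)
class Problem:
    """A reasoning problem with ``n_questions`` scored sub-questions.

    ``scoring_mode`` is ``"binary"`` (correct/incorrect questions) or
    ``"graded"`` (questions scored by closeness to the true answer).
    """

    problem_id: str
    scoring_mode: str = "binary"
    n_questions: int = 1

    def __post_init__(self) -> None:
        if not self.problem_id:
            raise ValidationError("problem_id must be a nonempty string")
        if self.scoring_mode not in SCORING_MODES:
            raise ValidationError(
                f"problem {self.problem_id!r}: scoring_mode must be one of "
                f"{SCORING_MODES}, got {self.scoring_mode!r}"
            )
        if self.n_questions < 1:
            raise ValidationError(
                f"problem {self.problem_id!r}: n_questions must be >= 1"
            )


@dataclass
class Rationale:
    """One team's written rationale, with per-question correctness scores."""

    item_id: str
    problem_id: str
    team_size: int
    text: str
    question_scores: np.ndarray
    protocol: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValidationError("item_id must be a nonempty string")
        if int(self.team_size) < 1:
            raise ValidationError(f"item {self.item_id!r}: team_size must be >= 1")
        self.team_size = int(self.team_size)
        if self.protocol is not None and self.protocol not in PROTOCOLS:
            raise ValidationError(
                f"item {self.item_id!r}: protocol must be one of {PROTOCOLS} or None"
            )
        self.question_scores = np.asarray(self.question_scores, dtype=float)
        if self.question_scores.ndim != 1 or self.question_scores.size < 1:
            raise ValidationError(
                f"item {self.item_id!r}: question_scores must be a nonempty vector"
            )
        if (
            not np.all(np.isfinite(self.question_scores))
            or self.question_scores.min() < 0.0
            or self.question_scores.max() > 1.0
        ):
            raise ValidationError(
                f"item {self.item_id!r}: question scores must lie in [0, 1]"
            )

    @property
    def mean_score(self) -> float:
        return float(self.question_scores.mean())


@dataclass(frozen=True)
class Judgment:
    """A single forced choice: ``rater_id`` picked ``choice`` out of the
    ordered presentation (``item_a``, ``item_b``)."""

    judgment_id: str
    problem_id: str
    item_a: str
    item_b: str
    rater_id: str
    choice: str
    response_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.item_a == self.item_b:
            raise ValidationError(
                f"judgment {self.judgment_id!r}: item_a and item_b are identical"
            )
        if self.choice not in (self.item_a, self.item_b):
            raise ValidationError(
                f"judgment {self.judgment_id!r}: choice {self.choice!r} is not "
                f"one of the presented items"
            )
        if self.response_time_s is not None and self.response_time_s < 0:
            raise ValidationError(
                f"judgment {self.judgment_id!r}: negative response time"
            )

    @property
    def pair(self) -> frozenset:
        """The unordered item pair; presentation order is metadata only."""
        return frozenset((self.item_a, self.item_b))

    @property
    def loser(self) -> str:
        return self.item_b if self.choice == self.item_a else self.item_a


class JudgmentSet:
    """A collection of judgments with unordered-pair and rater indices."""

    def __init__(self, judgments: Iterable[Judgment]):
        self.judgments: list[Judgment] = list(judgments)
        self.by_pair: dict[tuple[str, frozenset], list[Judgment]] = defaultdict(list)
        self.by_rater: dict[str, list[Judgment]] = defaultdict(list)
        seen_ids: set[str] = set()
        for j in self.judgments:
            if j.judgment_id in seen_ids:
                raise ValidationError(f"duplicate judgment_id {j.judgment_id!r}")
            seen_ids.add(j.judgment_id)
            self.by_pair[(j.problem_id, j.pair)].append(j)
            self.by_rater[j.rater_id].append(j)

    def __len__(self) -> int:
        return len(self.judgments)

    def __iter__(self) -> Iterator[Judgment]:
        return iter(self.judgments)

    @property
    def raters(self) -> list[str]:
        return sorted(self.by_rater)

    @property
    def problem_ids(self) -> list[str]:
        return sorted({j.problem_id for j in self.judgments})

    def subset_raters(self, raters: Sequence[str]) -> "JudgmentSet":
        keep = set(raters)
        return JudgmentSet(j for j in self.judgments if j.rater_id in keep)


# ---------------------------------------------------------------------------
# corpus I/O


def _q_columns(columns: Sequence[str]) -> list[str]:
    qcols = [c for c in columns if re.fullmatch(r"q\d+", c)]
    return sorted(qcols, key=lambda c: int(c[1:]))


_CORPUS_COLUMNS = ("item_id", "problem_id", "team_size", "protocol", "text")


def read_corpus(path) -> tuple[list[Problem], list[Rationale]]:
    """Load a corpus of problems and rationales from CSV or JSON.

    CSV: header ``item_id, problem_id, team_size, protocol, text, q1..qk``;
    a problem's question count is the number of populated q-columns, which
    must agree across its rows; scoring mode is inferred as ``graded`` when
    any score is strictly inside (0, 1). JSON: an object with ``problems``
    (explicit ``scoring_mode``/``n_questions``) and ``rationales`` lists.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_corpus_json(path)
    return _read_corpus_csv(path)


def _read_corpus_csv(path: Path) -> tuple[list[Problem], list[Rationale]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing corpus columns {missing}")
    qcols = _q_columns(df.columns)
    if not qcols:
        raise ValidationError(f"{path}: no question-score columns (q1..qk)")

    rationales: list[Rationale] = []
    seen: set[str] = set()
    problem_nq: dict[str, int] = {}
    problem_graded: dict[str, bool] = {}
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, plus header line
        raw_scores = []
        for c in qcols:
            v = str(row[c]).strip()
            if v == "":
                break
            try:
                raw_scores.append(float(v))
            except ValueError:
                raise ValidationError(
                    f"{path} row {rowno}: non-numeric score {v!r} in column {c}"
                ) from None
        # any populated column after the first blank one is a ragged row
        tail = [str(row[c]).strip() for c in qcols[len(raw_scores):]]
        if any(t != "" for t in tail):
            raise ValidationError(
                f"{path} row {rowno}: question scores must occupy q1..qk "
                f"contiguously"
            )
        if not raw_scores:
            raise ValidationError(f"{path} row {rowno}: no question scores")
        try:
            team_size = int(row["team_size"])
        except ValueError:
            raise ValidationError(
                f"{path} row {rowno}: team_size {row['team_size']!r} is not an "
                f"integer"
            ) from None
        protocol = str(row["protocol"]).strip() or None
        try:
            r = Rationale(
                item_id=row["item_id"],
                problem_id=row["problem_id"],
                team_size=team_size,
                text=row["text"],
                question_scores=np.array(raw_scores),
                protocol=protocol,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {rowno}: {exc}") from None
        if r.item_id in seen:
            raise ValidationError(
                f"{path} row {rowno}: duplicate item_id {r.item_id!r}"
            )
        seen.add(r.item_id)
        nq = problem_nq.setdefault(r.problem_id, len(raw_scores))
        if len(raw_scores) != nq:
            raise ValidationError(
                f"{path} row {rowno}: item {r.item_id!r} has {len(raw_scores)} "
                f"question scores but problem {r.problem_id!r} has {nq} questions"
            )
        graded = bool(np.any((r.question_scores > 0) & (r.question_scores < 1)))
        problem_graded[r.problem_id] = problem_graded.get(r.problem_id, False) or graded
        rationales.append(r)

    problems = [
        Problem(pid, "graded" if problem_graded[pid] else "binary", nq)
        for pid, nq in sorted(problem_nq.items())
    ]
    return problems, rationales


def _read_corpus_json(path: Path) -> tuple[list[Problem], list[Rationale]]:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    problems = [Problem(**p) for p in obj.get("problems", [])]
    pids = [p.problem_id for p in problems]
    if len(set(pids)) != len(pids):
        raise ValidationError(f"{path}: duplicate problem_id in problems list")
    by_pid = {p.problem_id: p for p in problems}
    rationales: list[Rationale] = []
    seen: set[str] = set()
    for i, rec in enumerate(obj.get("rationales", [])):
        try:
            r = Rationale(
                item_id=rec["item_id"],
                problem_id=rec["problem_id"],
                team_size=rec["team_size"],
                text=rec.get("text", ""),
                question_scores=np.asarray(rec["question_scores"], dtype=float),
                protocol=rec.get("protocol"),
            )
        except (KeyError, ValidationError) as exc:
            raise ValidationError(f"{path} rationale #{i}: {exc}") from None
        if r.item_id in seen:
            raise ValidationError(f"{path} rationale #{i}: duplicate item_id")
        seen.add(r.item_id)
        if r.problem_id not in by_pid:
            raise ValidationError(
                f"{path} rationale #{i}: unknown problem_id {r.problem_id!r}"
            )
        if r.question_scores.size != by_pid[r.problem_id].n_questions:
            raise ValidationError(
                f"{path} rationale #{i}: item {r.item_id!r} has "
                f"{r.question_scores.size} scores but problem "
                f"{r.problem_id!r} declares "
                f"{by_pid[r.problem_id].n_questions} questions"
            )
        rationales.append(r)
    return problems, rationales


def write_corpus(path, problems: Sequence[Problem], rationales: Sequence[Rationale]) -> None:
    """Write a corpus to CSV or JSON (chosen by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = {
            "problems": [
                {
                    "problem_id": p.problem_id,
                    "scoring_mode": p.scoring_mode,
                    "n_questions": p.n_questions,
                }
                for p in problems
            ],
            "rationales": [
                {
                    "item_id": r.item_id,
                    "problem_id": r.problem_id,
                    "team_size": r.team_size,
                    "protocol": r.protocol,
                    "text": r.text,
                    "question_scores": r.question_scores.tolist(),
                }
                for r in rationales
            ],
        }
        path.write_text(json.dumps(obj, indent=1), encoding="utf-8")
        return
    kmax = max((r.question_scores.size for r in rationales), default=1)
    qcols = [f"q{i}" for i in range(1, kmax + 1)]
    rows = []
    for r in rationales:
        row = {
            "item_id": r.item_id,
            "problem_id": r.problem_id,
            "team_size": r.team_size,
            "protocol": r.protocol or "",
            "text": r.text,
        }
        for i, c in enumerate(qcols):
            row[c] = (
                repr(float(r.question_scores[i]))
                if i < r.question_scores.size
                else ""
            )
        rows.append(row)
    pd.DataFrame(rows, columns=list(_CORPUS_COLUMNS) + qcols).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# judgment I/O

_JUDGMENT_COLUMNS = (
    "judgment_id",
    "problem_id",
    "item_a",
    "item_b",
    "rater_id",
    "choice",
    "response_time_s",
)


def read_judgments(path, corpus) -> JudgmentSet:
    """Load ``judgments.csv`` and validate it against a loaded corpus.

    ``corpus`` is either the ``(problems, rationales)`` pair from
    :func:`read_corpus` or a plain list of :class:`Rationale`.
    """
    rationales = corpus[1] if isinstance(corpus, tuple) else list(corpus)
    by_item = {r.item_id: r for r in rationales}
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = [c for c in _JUDGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing judgment columns {missing}")
    judgments = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2
        rt = str(row["response_time_s"]).strip()
        try:
            j = Judgment(
                judgment_id=row["judgment_id"],
                problem_id=row["problem_id"],
                item_a=row["item_a"],
                item_b=row["item_b"],
                rater_id=row["rater_id"],
                choice=row["choice"],
                response_time_s=float(rt) if rt else None,
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {rowno}: {exc}") from None
        for item in (j.item_a, j.item_b):
            if item not in by_item:
                raise ValidationError(
                    f"{path} row {rowno}: unknown item {item!r}"
                )
            if by_item[item].problem_id != j.problem_id:
                raise ValidationError(
                    f"{path} row {rowno}: item {item!r} belongs to problem "
                    f"{by_item[item].problem_id!r}, not {j.problem_id!r}"
                )
        judgments.append(j)
    return JudgmentSet(judgments)


def write_judgments(path, judgments: Iterable[Judgment]) -> None:
    rows = [
        {
            "judgment_id": j.judgment_id,
            "problem_id": j.problem_id,
            "item_a": j.item_a,
            "item_b": j.item_b,
            "rater_id": j.rater_id,
            "choice": j.choice,
            "response_time_s": "" if j.response_time_s is None else j.response_time_s,
        }
        for j in judgments
    ]
    pd.DataFrame(rows, columns=list(_JUDGMENT_COLUMNS)).to_csv(
        Path(path), index=False
    )


# ---------------------------------------------------------------------------
# ranking I/O


def write_ranking(path, ranking: Sequence[str], scores=None) -> None:
    """Write a best-first ranking to CSV with columns rank, item_id, score."""
    if scores is None:
        scores = [""] * len(ranking)
    if len(scores) != len(ranking):
        raise ValidationError("scores must align with ranking")
    pd.DataFrame(
        {
            "rank": np.arange(1, len(ranking) + 1, dtype=int),
            "item_id": list(ranking),
            "score": list(scores),
        }
    ).to_csv(Path(path), index=False)


def read_ranking(path) -> list[str]:
    df = pd.read_csv(Path(path), dtype={"item_id": str})
    return df.sort_values("rank")["item_id"].tolist()
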