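"""Open-lexicon linguistic features for written rationales.

Approximates the dictionary-based text measures used to study what makes
an argument read as well-reasoned: overall word count, comparison-class
language (appeals to past precedents, averages, and relative comparison),
elaborative connectives (reinforcing a position), dialectical connectives
(engaging an opposing view), first-person pronouns, negation, and spelled
numbers. Every lexicon is a small editable list of lowercase tokens and
multi-word phrases; scores are rates per 100 tokens, so they are invariant
to text length.

Lexicon config files are plain text: a ``[section]`` header per lexicon,
one term per line (multi-word lines become phrases), ``#`` comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .corpus import Rationale

__all__ = [
    "Lexicon",
    "LexiconSet",
    "DEFAULT_LEXICONS",
    "tokenize",
    "word_count",
    "lexicon_rate",
    "feature_matrix",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase tokens split on runs of non-alphanumeric characters."""
    return _TOKEN_RE.findall(text.lower())


def word_count(text: str) -> int:
    return len(tokenize(text))


@dataclass(frozen=True)
class Lexicon:
    """One named feature dictionary: single tokens plus multi-word phrases
    (phrases are matched on the token stream)."""

    name: str
    tokens: frozenset
    phrases: tuple = ()

    def __post_init__(self) -> None:
        terms = list(self.tokens) + [" ".join(p) for p in self.phrases]
        if not terms:
            raise ValueError(f"lexicon {self.name!r} is empty")
        for t in terms:
            if not t or t != t.lower():
                raise ValueError(
                    f"lexicon {self.name!r}: terms must be nonempty lowercase "
                    f"({t!r})"
                )
        if len(set(terms)) != len(terms):
            raise ValueError(f"lexicon {self.name!r}: duplicate terms")

    @classmethod
    def from_terms(cls, name: str, terms: Iterable[str]) -> "Lexicon":
        tokens, phrases = [], []
        for term in terms:
            parts = tokenize(term)
            if len(parts) == 1:
                tokens.append(parts[0])
            elif len(parts) > 1:
                phrases.append(tuple(parts))
        return cls(name, frozenset(tokens), tuple(phrases))


def lexicon_rate(text: str, lexicon: Lexicon) -> float:
    """Matches per 100 tokens: single-token hits plus phrase occurrences
    counted on the token stream. Empty text scores 0."""
    tokens = tokenize(text)
    if not tokens:
        return 0.0
    matches = sum(tok in lexicon.tokens for tok in tokens)
    for phrase in lexicon.phrases:
        k = len(phrase)
        matches += sum(
            tuple(tokens[i : i + k]) == phrase for i in range(len(tokens) - k + 1)
        )
    return 100.0 * matches / len(tokens)


_DEFAULT_TERMS: dict[str, list[str]] = {
    "comparison_class": [
        "than", "average", "last", "past", "previous", "compared",
        "typically", "historically", "precedent", "relative",
    ],
    "elaboration": [
        "moreover", "additionally", "furthermore", "also", "besides",
        "in addition",
    ],
    "dialectical": [
        "however", "although", "nevertheless", "whereas", "conversely",
        "alternatively", "on the other hand",
    ],
    "first_person_pronouns": [
        "i", "me", "my", "mine", "myself",
        "we", "us", "our", "ours", "ourselves",
    ],
    "negation": ["not", "no", "never", "none", "neither", "nor", "cannot", "without"],
    "numbers": [
        "one", "two", "three", "four", "five", "six", "seven", "eight",
        "nine", "ten", "hundred", "thousand", "percent", "half", "third",
        "quarter",
    ],
}


class LexiconSet(Mapping):
    """An ordered, named collection of lexicons."""

    def __init__(self, lexicons: Sequence[Lexicon]):
        names = [lx.name for lx in lexicons]
        if len(set(names)) != len(names):
            raise ValueError("duplicate lexicon names")
        self._lexicons = {lx.name: lx for lx in lexicons}

    def __getitem__(self, name: str) -> Lexicon:
        return self._lexicons[name]

    def __iter__(self):
        return iter(self._lexicons)

    def __len__(self) -> int:
        return len(self._lexicons)

    @property
    def names(self) -> list[str]:
        return list(self._lexicons)

    @classmethod
    def default(cls) -> "LexiconSet":
        return cls(
            [Lexicon.from_terms(name, terms) for name, terms in _DEFAULT_TERMS.items()]
        )

    @classmethod
    def from_config_text(cls, text: str) -> "LexiconSet":
        sections: dict[str, list[str]] = {}
        current: Optional[str] = None
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip()
                if not current:
                    raise ValueError(f"line {lineno}: empty section name")
                sections.setdefault(current, [])
            elif current is None:
                raise ValueError(f"line {lineno}: term before any [section] header")
            else:
                sections[current].append(line.lower())
        if not sections:
            raise ValueError("no lexicon sections found")
        return cls(
            [Lexicon.from_terms(name, terms) for name, terms in sections.items()]
        )

    @classmethod
    def from_config_file(cls, path) -> "LexiconSet":
        return cls.from_config_text(Path(path).read_text(encoding="utf-8"))

    def to_config_text(self) -> str:
        lines = []
        for lx in self._lexicons.values():
            lines.append(f"[{lx.name}]")
            lines.extend(sorted(lx.tokens))
            lines.extend(" ".join(p) for p in lx.phrases)
            lines.append("")
        return "\n".join(lines)


DEFAULT_LEXICONS = LexiconSet.default()


def feature_matrix(
    rationales: Sequence[Rationale],
    lexicons: Optional[LexiconSet] = None,
) -> pd.DataFrame:
    """One feature vector per rationale: ``word_count`` plus one rate per
    lexicon, in a fixed column order; indexed by item_id."""
    if lexicons is None:
        lexicons = DEFAULT_LEXICONS
    rows = {}
    for r in rationales:
        if r.text is None:
            raise ValueError(f"item {r.item_id!r} has no text")
        row = {"word_count": float(word_count(r.text))}
        for name in lexicons.names:
            row[name] = lexicon_rate(r.text, lexicons[name])
        rows[r.item_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "item_id"
    return df[["word_count"] + lexicons.names]
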