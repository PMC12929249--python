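"""Rule-based extraction of clinical-topic flags from visit notes.

A topic is marked present for a note when at least one of its include
tokens occurs in the text with no exclusion term within ``window`` words
on either side of the matched span.  Matching is exact (lowercased,
punctuation-split) — no stemming, no fuzzy matching.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "tokenize",
    "LexiconEntry",
    "TopicLexicon",
    "default_lexicon",
    "match_topic",
    "annotate_corpus",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")

DEFAULT_EXCLUDE: tuple[str, ...] = ("no", "neg")
DEFAULT_WINDOW: int = 3


def tokenize(text: str) -> list[str]:
    """Split ``text`` into lowercase word tokens.

    Any run of non-alphanumeric characters is a separator, so hyphenated
    and punctuated spans break apart ("HIV-1" -> ["hiv", "1"]).  Total
    function: empty input yields an empty list.
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class LexiconEntry:
    """One topic: its include token sequences and single-word exclusions."""

    topic: str
    include: tuple[str, ...]
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if not self.include:
            raise ValueError(f"topic {self.topic!r}: include tokens must be non-empty")
        if self.window < 1:
            raise ValueError(f"topic {self.topic!r}: window must be >= 1")
        for tok in self.exclude:
            if len(tokenize(tok)) != 1:
                raise ValueError(
                    f"topic {self.topic!r}: exclusion term {tok!r} must be a single word"
                )


@dataclass
class TopicLexicon:
    """Ordered collection of :class:`LexiconEntry`, keyed by topic name."""

    entries: dict[str, LexiconEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, entry in self.entries.items():
            if name != entry.topic:
                raise ValueError(f"entry key {name!r} != topic {entry.topic!r}")

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries.values())

    def __getitem__(self, topic: str) -> LexiconEntry:
        return self.entries[topic]

    def __contains__(self, topic: str) -> bool:
        return topic in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def topics(self) -> list[str]:
        return list(self.entries)

    def all_words(self) -> set[str]:
        """Every individual word appearing in any include or exclude token."""
        words: set[str] = set()
        for entry in self:
            for tok in entry.include:
                words.update(tokenize(tok))
            words.update(entry.exclude)
        return words

    @classmethod
    def from_dict(cls, raw: Mapping[str, Mapping]) -> "TopicLexicon":
        entries = {}
        for topic, spec in raw.items():
            entries[topic] = LexiconEntry(
                topic=topic,
                include=tuple(spec["include"]),
                exclude=tuple(spec.get("exclude", DEFAULT_EXCLUDE)),
                window=int(spec.get("window", DEFAULT_WINDOW)),
            )
        return cls(entries)

    @classmethod
    def from_json(cls, path: str | Path) -> "TopicLexicon":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        raw = {
            e.topic: {
                "include": list(e.include),
                "exclude": list(e.exclude),
                "window": e.window,
            }
            for e in self
        }
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2)
            fh.write("\n")


#: Illustrative default lexicon covering the twelve shipped topics.  The
#: token lists are placeholders users are expected to replace with their
#: own clinical vocabulary; only the topic names are load-bearing.
_DEFAULT_LEXICON_SPEC: dict[str, list[str]] = {
    "opportunistic_infection": ["pneumocystis", "toxoplasmosis", "opportunistic infection"],
    "comorbidities": ["hypertension", "diabetes", "asthma"],
    "poor_adherence": ["nonadherent", "missed doses"],
    "good_adherence": ["adherent", "takes medication daily"],
    "sexual_gender_minorities": ["msm", "transgender"],
    "heterosexual": ["heterosexual"],
    "life_stressors": ["homeless", "unemployed", "food insecurity"],
    "mental_illness": ["depression", "schizophrenia", "bipolar"],
    "pregnancy": ["pregnant", "pregnancy"],
    "preventive_health": ["vaccination", "screening"],
    "sti": ["syphilis", "gonorrhea", "chlamydia"],
    "substance_use_disorder": ["cocaine", "heroin", "substance use disorder"],
}


def default_lexicon() -> TopicLexicon:
    """The packaged 12-topic lexicon with exclusions {"no", "neg"}."""
    return TopicLexicon.from_dict(
        {topic: {"include": toks} for topic, toks in _DEFAULT_LEXICON_SPEC.items()}
    )


def _find_occurrences(tokens: list[str], needle: list[str]) -> list[tuple[int, int]]:
    """Start/end (half-open) positions of contiguous matches of ``needle``."""
    n, m = len(tokens), len(needle)
    return [(s, s + m) for s in range(n - m + 1) if tokens[s : s + m] == needle]


def match_topic(tokens: list[str], entry: LexiconEntry, window: int | None = None) -> int:
    """Return 1 iff some include-token occurrence has a clean window.

    An occurrence is clean when no exclusion term appears within
    ``window`` tokens on either side of the matched span; the window is
    measured from the outermost token of multi-word spans.
    """
    w = entry.window if window is None else window
    if w < 1:
        raise ValueError("window must be >= 1")
    exclude = set(entry.exclude)
    for inc in entry.include:
        needle = tokenize(inc)
        if not needle:
            raise ValueError(f"topic {entry.topic!r}: include token {inc!r} tokenizes to nothing")
        for start, end in _find_occurrences(tokens, needle):
            before = tokens[max(0, start - w) : start]
            after = tokens[end : end + w]
            if not any(t in exclude for t in before) and not any(t in exclude for t in after):
                return 1
    return 0


def annotate_corpus(
    corpus: Iterable[Mapping[str, str]],
    lexicon: TopicLexicon,
    window: int | None = None,
) -> pd.DataFrame:
    """Annotate every note with 0/1 presence flags for each lexicon topic.

    Parameters
    ----------
    corpus
        Iterable of records with ``visit_id`` and ``text`` keys (e.g. rows
        parsed from a JSONL notes file).
    lexicon
        Topic lexicon to apply.
    window
        Optional override of each entry's exclusion window.

    Returns
    -------
    DataFrame with a ``visit_id`` column plus one 0/1 column per topic.
    """
    rows = []
    seen: set[str] = set()
    for record in corpus:
        visit_id = record["visit_id"]
        if visit_id in seen:
            raise ValueError(f"duplicate visit_id in corpus: {visit_id!r}")
        seen.add(visit_id)
        tokens = tokenize(record["text"])
        row: dict[str, object] = {"visit_id": visit_id}
        for entry in lexicon:
            row[entry.topic] = match_topic(tokens, entry, window=window)
        rows.append(row)
    columns = ["visit_id", *lexicon.topics]
    return pd.DataFrame(rows, columns=columns)


def read_notes_jsonl(path: str | Path) -> list[dict]:
    """Load a JSONL note corpus ({"visit_id": ..., "text": ...} per line)."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records


def write_notes_jsonl(records: Iterable[Mapping[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for record in records:
            fh.write(json.dumps(dict(record), sort_keys=True))
            fh.write("\n")
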