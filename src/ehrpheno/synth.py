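"""Synthetic EHR cohort generator with known latent-class structure.

Produces a visit table, a viral-load lab table, a JSONL-style note corpus
and a ground-truth table from a configurable class-conditional Bernoulli
model, so that every downstream stage (annotation, feature construction,
outcome labelling, latent class recovery) can be tested against known
truth.

Visit timing is a per-patient renewal process whose inter-visit gap is a
two-component mixture: short gaps (uniform 30–180 days) and long gaps
(uniform 400–700 days), with a class-specific long-gap probability.  The
long component produces gaps exceeding 365 days, which makes the primary
loss-to-follow-up rate controllable per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .notes import TopicLexicon, default_lexicon, write_notes_jsonl

__all__ = [
    "ConfigError",
    "GapModel",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "plant_note_text",
    "default_generator_config",
    "AGE_BIN_RANGES",
]


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


#: Sampling range of integer ages for each of the five age bins.
AGE_BIN_RANGES: tuple[tuple[int, int], ...] = (
    (18, 25),
    (26, 35),
    (36, 45),
    (46, 55),
    (56, 85),
)

#: Filler vocabulary for note prose.  Must stay disjoint from every
#: lexicon token; validated at generation time.
FILLER_VOCAB: tuple[str, ...] = (
    "routine", "clinic", "reviewed", "stable", "plan", "continue",
    "today", "status", "followup", "general", "summary", "chart",
    "update", "discussed", "visit",
)

_SEXES = ("male", "female")
_SEX_P = (0.66, 0.34)
_RACES = ("black", "white", "other")
_RACE_P = (0.80, 0.12, 0.08)
_ETHNICITIES = ("non-hispanic", "hispanic")
_ETH_P = (0.95, 0.05)


@dataclass(frozen=True)
class GapModel:
    """Two-component inter-visit gap mixture with per-class long-gap weight."""

    long_gap_prob: tuple[float, ...]
    short_range: tuple[int, int] = (30, 180)
    long_range: tuple[int, int] = (400, 700)


@dataclass
class GeneratorConfig:
    n_patients: int
    true_C: int
    class_weights: Sequence[float]
    #: structured indicator name -> per-class P(indicator = 1)
    item_probs: Mapping[str, Sequence[float]]
    #: note topic name -> per-class P(topic planted in note)
    topic_probs: Mapping[str, Sequence[float]]
    #: per-class distribution over the five age bins, shape (true_C, 5)
    age_dist: Sequence[Sequence[float]]
    gap_model: GapModel
    #: per-class probability that a post-visit viral-load draw is high
    vl_detect_prob: Sequence[float]
    study_start: date
    study_end: date
    negation_rate: float = 0.0
    vl_threshold: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        C = self.true_C
        if C < 1:
            raise ConfigError("true_C must be >= 1")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if (self.study_end - self.study_start).days < 1:
            raise ConfigError("study window must span at least 1 day")
        w = np.asarray(self.class_weights, dtype=float)
        if w.shape != (C,) or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ConfigError("class_weights must be a length-true_C probability vector")
        for name, probs in {**dict(self.item_probs), **dict(self.topic_probs)}.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (C,) or (p < 0).any() or (p > 1).any():
                raise ConfigError(f"probabilities for {name!r} must be length-{C} in [0,1]")
        a = np.asarray(self.age_dist, dtype=float)
        if a.shape != (C, 5) or (a < 0).any() or np.abs(a.sum(axis=1) - 1.0).max() > 1e-9:
            raise ConfigError("age_dist must be true_C rows of 5-bin probability vectors")
        g = np.asarray(self.gap_model.long_gap_prob, dtype=float)
        if g.shape != (C,) or (g < 0).any() or (g > 1).any():
            raise ConfigError("gap_model.long_gap_prob must be length-true_C in [0,1]")
        v = np.asarray(self.vl_detect_prob, dtype=float)
        if v.shape != (C,) or (v < 0).any() or (v > 1).any():
            raise ConfigError("vl_detect_prob must be length-true_C in [0,1]")
        if not 0.0 <= self.negation_rate <= 1.0:
            raise ConfigError("negation_rate must be in [0,1]")


@dataclass
class SyntheticCohort:
    """Generated tables plus retained ground truth."""

    visits: pd.DataFrame
    labs: pd.DataFrame
    notes: list[dict]
    truth: pd.DataFrame
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write visits.csv, labs.csv, notes.jsonl, ground_truth.csv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "visits": outdir / "visits.csv",
            "labs": outdir / "labs.csv",
            "notes": outdir / "notes.jsonl",
            "truth": outdir / "ground_truth.csv",
        }
        self.visits.to_csv(paths["visits"], index=False)
        self.labs.to_csv(paths["labs"], index=False)
        write_notes_jsonl(self.notes, paths["notes"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def plant_note_text(
    topics_present: Sequence[str],
    lexicon: TopicLexicon,
    negate: Mapping[str, bool],
    rng: np.random.Generator,
) -> str:
    """Compose note text containing one planted mention per present topic.

    Every planted span is padded with three filler words on each side so
    that exclusion windows of adjacent plants can never interact.  A
    negated plant places an exclusion term immediately before the include
    token (within the default ±3-word window); a clean plant has no
    exclusion term anywhere near it.
    """
    for topic in topics_present:
        if topic not in lexicon:
            raise ConfigError(f"topic {topic!r} not in lexicon")
        if not lexicon[topic].include:
            raise ConfigError(f"topic {topic!r} has an empty lexicon entry")
    collisions = set(FILLER_VOCAB) & lexicon.all_words()
    if collisions:
        raise ConfigError(f"filler vocabulary collides with lexicon tokens: {sorted(collisions)}")

    def filler(k: int) -> list[str]:
        return list(rng.choice(FILLER_VOCAB, size=k))

    sentences: list[str] = []
    if not topics_present:
        sentences.append(" ".join(filler(6)))
    for topic in topics_present:
        entry = lexicon[topic]
        token = str(rng.choice(entry.include))
        core = [token]
        if negate.get(topic, False):
            excl = str(rng.choice(entry.exclude)) if entry.exclude else "no"
            core = [excl, token]
        sentences.append(" ".join(filler(3) + core + filler(3)))
    return ". ".join(sentences) + "."


def generate_cohort(
    config: GeneratorConfig, lexicon: TopicLexicon | None = None
) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``config``.

    Each patient is assigned a latent class once; all of their visits
    inherit it.  Identical config and seed reproduce identical outputs.
    """
    config.validate()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    for topic in config.topic_probs:
        if topic not in lexicon:
            raise ConfigError(f"topic_probs refers to unknown lexicon topic {topic!r}")

    rng = np.random.default_rng(config.seed)
    C = config.true_C
    item_names = sorted(config.item_probs)
    topic_names = sorted(config.topic_probs)
    span = (config.study_end - config.study_start).days
    short_lo, short_hi = config.gap_model.short_range
    long_lo, long_hi = config.gap_model.long_range

    visit_rows: list[dict] = []
    lab_rows: list[dict] = []
    notes: list[dict] = []
    truth_rows: list[dict] = []

    for p in range(config.n_patients):
        patient_id = f"P{p:05d}"
        c = int(rng.choice(C, p=np.asarray(config.class_weights, dtype=float)))
        age_bin = int(rng.choice(5, p=np.asarray(config.age_dist[c], dtype=float)))
        lo, hi = AGE_BIN_RANGES[age_bin]
        age = int(rng.integers(lo, hi + 1))
        sex = str(rng.choice(_SEXES, p=_SEX_P))
        race = str(rng.choice(_RACES, p=_RACE_P))
        ethnicity = str(rng.choice(_ETHNICITIES, p=_ETH_P))

        # renewal process: first visit anywhere in the window, then gaps
        dates = [config.study_start + timedelta(days=int(rng.integers(0, span)))]
        while True:
            if rng.random() < config.gap_model.long_gap_prob[c]:
                gap = int(rng.integers(long_lo, long_hi + 1))
            else:
                gap = int(rng.integers(short_lo, short_hi + 1))
            nxt = dates[-1] + timedelta(days=gap)
            if nxt > config.study_end:
                break
            dates.append(nxt)

        for k, d in enumerate(dates):
            visit_id = f"{patient_id}-{k:03d}"
            row = {
                "visit_id": visit_id,
                "patient_id": patient_id,
                "visit_date": d.isoformat(),
                "age_years": age,
                "sex": sex,
                "race": race,
                "ethnicity": ethnicity,
            }
            for name in item_names:
                row[name] = int(rng.random() < config.item_probs[name][c])
            visit_rows.append(row)

            planted = {t: rng.random() < config.topic_probs[t][c] for t in topic_names}
            negated = {
                t: bool(planted[t] and rng.random() < config.negation_rate)
                for t in topic_names
            }
            text = plant_note_text(
                [t for t in topic_names if planted[t]], lexicon, negated, rng
            )
            notes.append({"visit_id": visit_id, "text": text})

            # one viral-load draw per visit, 20-300 days after it
            draw = d + timedelta(days=int(rng.integers(20, 301)))
            if rng.random() < config.vl_detect_prob[c]:
                vl = int(rng.integers(int(config.vl_threshold), 50_001))
            else:
                vl = int(rng.integers(0, int(config.vl_threshold)))
            lab_rows.append(
                {
                    "patient_id": patient_id,
                    "draw_date": draw.isoformat(),
                    "viral_load_copies_ml": vl,
                }
            )

            if k + 1 < len(dates):
                ltfu = int((dates[k + 1] - d).days > 365)
            else:
                ltfu = int((config.study_end - d).days > 365)
            t_row = {
                "visit_id": visit_id,
                "patient_id": patient_id,
                "true_class": c + 1,
                "intended_ltfu": ltfu,
            }
            for t in topic_names:
                t_row[f"planted_{t}"] = int(planted[t])
                t_row[f"negated_{t}"] = int(negated[t])
            truth_rows.append(t_row)

    visits = pd.DataFrame(visit_rows)
    labs = pd.DataFrame(lab_rows)
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(visits=visits, labs=labs, notes=notes, truth=truth, config=config)


def default_generator_config(
    n_patients: int = 200,
    seed: int = 0,
    true_C: int = 3,
    study_start: date = date(2017, 1, 1),
    study_end: date = date(2020, 12, 31),
    negation_rate: float = 0.3,
) -> GeneratorConfig:
    """A patterned demo configuration usable for any small class count.

    Item probabilities cycle through (0.8, 0.4, 0.1) across class/item
    pairs so every pair of classes differs on most indicators.
    """
    pattern = (0.8, 0.4, 0.1)
    items = [
        "dx_hypertension", "dx_diabetes", "dx_mood_disorder", "dx_syphilis",
        "sh_alcohol", "sh_tobacco", "lab_syphilis_pos", "lab_gonorrhea_pos",
    ]
    topics = ["mental_illness", "pregnancy", "sti", "substance_use_disorder"]
    item_probs = {
        name: tuple(pattern[(c + j) % 3] for c in range(true_C))
        for j, name in enumerate(items)
    }
    topic_probs = {
        name: tuple(pattern[(c + j + 1) % 3] for c in range(true_C))
        for j, name in enumerate(topics)
    }
    base = np.array([0.10, 0.25, 0.20, 0.25, 0.20])
    age_dist = tuple(tuple(np.roll(base, c)) for c in range(true_C))
    return GeneratorConfig(
        n_patients=n_patients,
        true_C=true_C,
        class_weights=tuple([1.0 / true_C] * true_C),
        item_probs=item_probs,
        topic_probs=topic_probs,
        age_dist=age_dist,
        gap_model=GapModel(
            long_gap_prob=tuple(np.linspace(0.05, 0.35, true_C)),
        ),
        vl_detect_prob=tuple(np.linspace(0.15, 0.45, true_C)),
        study_start=study_start,
        study_end=study_end,
        negation_rate=negation_rate,
        seed=seed,
    )
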