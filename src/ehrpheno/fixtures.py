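"""Packaged small fixtures: published contingency counts and toy notes."""

from __future__ import annotations

import pandas as pd

__all__ = ["load_fixture", "FIXTURES"]

#: Per-class visit counts and outcome counts from the published six-class
#: comparison: class sizes, primary loss-to-follow-up counts, and
#: high-viral-load counts, with class 1 as the reference group.
_TABLE4 = {
    "class": [1, 2, 3, 4, 5, 6],
    "n": [874, 804, 670, 511, 758, 699],
    "ltfu": [111, 149, 92, 86, 82, 100],
    "high_vl": [241, 320, 186, 101, 241, 213],
}

#: Cohort-level published counts used by the percent checks.
_COHORT_SUMMARY = {
    "n_patients": 849,
    "n_visits": 4316,
    "n_consistently_retained": 286,
}

#: Hand-written notes with known topic truths under the default lexicon
#: (window 3, exclusions {"no", "neg"}).
_TOY_NOTES = [
    {"visit_id": "T1", "text": "Patient reports depression and is pregnant."},
    {"visit_id": "T2", "text": "No depression noted today."},
    {"visit_id": "T3", "text": "History of syphilis treated fully previously, neg gonorrhea screen."},
    {"visit_id": "T4", "text": "no history of chronic severe depression"},
    {"visit_id": "T5", "text": "screening reviewed, vaccination given"},
    {"visit_id": "T6", "text": "denies cocaine use"},
]

#: Topics expected present per toy note; all other topics are absent.
_TOY_TRUTH_PRESENT = {
    "T1": {"mental_illness", "pregnancy"},
    "T2": set(),
    "T3": {"sti"},
    "T4": {"mental_illness"},
    "T5": {"preventive_health"},
    "T6": {"substance_use_disorder"},
}


def _table4_counts() -> pd.DataFrame:
    return pd.DataFrame(_TABLE4)


def _cohort_summary() -> dict:
    return dict(_COHORT_SUMMARY)


def _toy_notes() -> tuple[list[dict], pd.DataFrame]:
    from .notes import default_lexicon

    topics = default_lexicon().topics
    rows = []
    for note in _TOY_NOTES:
        present = _TOY_TRUTH_PRESENT[note["visit_id"]]
        row = {"visit_id": note["visit_id"]}
        row.update({t: int(t in present) for t in topics})
        rows.append(row)
    truth = pd.DataFrame(rows, columns=["visit_id", *topics])
    return [dict(n) for n in _TOY_NOTES], truth


FIXTURES = {
    "table4_counts": _table4_counts,
    "cohort_summary": _cohort_summary,
    "toy_notes": _toy_notes,
}


def load_fixture(name: str):
    """Return a packaged fixture by name.

    ``table4_counts``: DataFrame of per-class sizes and outcome counts.
    ``cohort_summary``: dict of cohort-level counts.
    ``toy_notes``: (note corpus, truth flag table) pair.
    """
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return factory()
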