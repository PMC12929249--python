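"""Visit-level categorical feature construction for latent class analysis.

Assembles, per attended visit: a five-level age bin, a three-level
retention-history category, the structured 0/1 indicator columns carried
on the visit table, and the note-topic flags from the annotator.  The
output is entirely categorical with no missing cells.
"""

from __future__ import annotations

import json
import logging
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_BINS",
    "RETENTION_LEVELS",
    "bin_age",
    "diagnosis_flags",
    "retention_history",
    "lab_flags",
    "build_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]

AGE_BINS: tuple[str, ...] = ("<=25", "26-35", "36-45", "46-55", ">55")

RETENTION_LEVELS: tuple[str, ...] = (
    "retained_prev_year",
    "ltfu_prev_year",
    "prev_visit_was_first",
)

STI_LAB_TESTS: tuple[str, ...] = ("gonorrhea", "chlamydia", "syphilis", "trichomoniasis")

#: Visit-table columns that are metadata, not LCA indicators.
_META_COLUMNS = frozenset(
    {"visit_id", "patient_id", "visit_date", "age_years", "sex", "race", "ethnicity"}
)

#: Small illustrative diagnosis-code map used by tests and the demo CLI.
#: Real deployments supply their own YAML map covering all variables.
DEFAULT_CODE_MAP: dict[str, str] = {
    "I10": "hypertension",
    "E11": "diabetes",
    "F32": "mood_disorder",
    "F41": "anxiety",
    "A51": "syphilis",
    "A54": "gonorrhea",
    "J44": "pulmonary_condition",
    "B18": "liver_disease",
    "F10": "alcohol_use_disorder",
    "F17": "tobacco_use_disorder",
}


def bin_age(age: int) -> str:
    """Map an integer age in years to one of the five age bins.

    Bin edges are inclusive as labelled: <=25, 26-35, 36-45, 46-55, >55.
    Ages below 18 violate the adult-cohort precondition and raise.
    """
    if age < 18:
        raise ValueError(f"age {age} below adult-cohort minimum of 18")
    if age <= 25:
        return AGE_BINS[0]
    if age <= 35:
        return AGE_BINS[1]
    if age <= 45:
        return AGE_BINS[2]
    if age <= 55:
        return AGE_BINS[3]
    return AGE_BINS[4]


def diagnosis_flags(
    visit_codes: Iterable[str],
    problem_list_codes: Iterable[str],
    code_map: Mapping[str, str],
    variables: Sequence[str] | None = None,
) -> dict[str, int]:
    """Binary indicators from the union of encounter and problem-list codes.

    A variable is 1 iff any code in either list maps to it.  Codes absent
    from ``code_map`` are ignored with a logged warning.
    """
    if variables is None:
        variables = sorted(set(code_map.values()))
    flags = {v: 0 for v in variables}
    for code in list(visit_codes) + list(problem_list_codes):
        var = code_map.get(code)
        if var is None:
            logger.warning("diagnosis code %r not in code map; ignored", code)
        elif var in flags:
            flags[var] = 1
    return flags


def retention_history(visit_dates: Iterable[date], index_date: date) -> str:
    """Three-level retention history for the visit at ``index_date``.

    Precedence: if the index visit is the patient's first recorded visit,
    or the visit immediately before it is, the category is
    ``prev_visit_was_first``; otherwise a preceding gap over 365 days is
    ``ltfu_prev_year``; otherwise ``retained_prev_year``.  Input dates are
    sorted internally and duplicate same-day visits are collapsed.
    """
    dates = sorted(set(visit_dates))
    if index_date not in dates:
        raise ValueError(f"index date {index_date} not among the patient's visits")
    i = dates.index(index_date)
    if i <= 1:
        return "prev_visit_was_first"
    if (dates[i] - dates[i - 1]).days > 365:
        return "ltfu_prev_year"
    return "retained_prev_year"


def lab_flags(
    lab_records: Iterable[Mapping[str, str]],
    tests: Sequence[str] = STI_LAB_TESTS,
) -> dict[str, int]:
    """Positivity flags for the four STI lab tests linked to a visit.

    Each record needs ``test`` and ``result`` fields; a result string
    starting with "pos" (case-insensitive) counts as positive.  Unknown
    test names are ignored with a warning.
    """
    flags = {t: 0 for t in tests}
    for rec in lab_records:
        test = str(rec["test"]).strip().lower()
        if test not in flags:
            logger.warning("lab test %r not tracked; ignored", test)
            continue
        if str(rec["result"]).strip().lower().startswith("pos"):
            flags[test] = 1
    return flags


def build_feature_matrix(
    visits: pd.DataFrame, topic_flags: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Assemble the LCA input matrix and its per-column level sets.

    ``visits`` must carry visit_id, patient_id, visit_date, age_years plus
    0/1 indicator columns; ``topic_flags`` is the annotator output.  Both
    must cover exactly the same visit ids.

    Returns the matrix (rows sorted by visit_id) and a dict mapping each
    feature column to its declared ordered level list.
    """
    visit_ids = set(visits["visit_id"])
    flag_ids = set(topic_flags["visit_id"])
    if visit_ids != flag_ids:
        missing = sorted(visit_ids ^ flag_ids)[:10]
        raise ValueError(
            f"visit table and topic flags cover different visits; e.g. {missing}"
        )
    if visits["visit_id"].duplicated().any():
        dupes = visits.loc[visits["visit_id"].duplicated(), "visit_id"].tolist()[:10]
        raise ValueError(f"duplicate visit ids: {dupes}")
    for col in ("age_years", "sex", "race", "ethnicity"):
        if col in visits.columns and visits[col].isna().any():
            raise ValueError(f"missing values in demographic column {col!r}")

    v = visits.sort_values("visit_id").reset_index(drop=True)
    dates = pd.to_datetime(v["visit_date"]).dt.date
    indicator_cols = [c for c in v.columns if c not in _META_COLUMNS]
    for col in indicator_cols:
        bad = ~v[col].isin([0, 1])
        if bad.any():
            raise ValueError(f"indicator column {col!r} has non-binary values")

    patient_dates: dict[str, list[date]] = {}
    for pid, d in zip(v["patient_id"], dates):
        patient_dates.setdefault(pid, []).append(d)

    out = pd.DataFrame({"visit_id": v["visit_id"]})
    out["age_bin"] = [bin_age(int(a)) for a in v["age_years"]]
    out["retention_history"] = [
        retention_history(patient_dates[pid], d) for pid, d in zip(v["patient_id"], dates)
    ]
    for col in indicator_cols:
        out[col] = v[col].astype(int)

    topic_cols = [c for c in topic_flags.columns if c != "visit_id"]
    flags = topic_flags.set_index("visit_id").loc[out["visit_id"], topic_cols]
    for col in topic_cols:
        if col in out.columns:
            raise ValueError(f"topic column {col!r} collides with a visit-table column")
        out[col] = flags[col].astype(int).to_numpy()

    levels: dict[str, list] = {
        "age_bin": list(AGE_BINS),
        "retention_history": list(RETENTION_LEVELS),
    }
    for col in indicator_cols + topic_cols:
        levels[col] = [0, 1]
    return out, levels


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".levels.json")


def write_feature_matrix(
    matrix: pd.DataFrame, levels: Mapping[str, list], path: str | Path
) -> None:
    """Write the matrix CSV plus a JSON sidecar declaring level sets."""
    matrix.to_csv(path, index=False)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(dict(levels), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_feature_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, list]]:
    with open(_sidecar_path(path)) as fh:
        levels = json.load(fh)
    matrix = pd.read_csv(path)
    for col, lv in levels.items():
        if all(isinstance(x, int) for x in lv):
            matrix[col] = matrix[col].astype(int)
    return matrix, levels
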