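"""Visit-level care-retention and viral-load outcome labelling.

Three labels per attended visit:

* primary loss to follow-up — more than 365 days to the next attended
  visit (or to the end of the study window when no next visit exists);
* the National HIV/AIDS Strategy (NHAS) retention outcome — retained iff
  at least two attended visits more than 90 days apart fall inside the
  365-day window opening at the index visit;
* high viral load — any draw at or above the threshold (default 200
  copies/ml) in the 365 days following the index visit.

Visits too close to the study end to observe a full follow-up window are
flagged non-evaluable rather than silently labelled.
"""

from __future__ import annotations

from datetime import date
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "label_ltfu_primary",
    "label_nhas",
    "label_high_vl",
    "label_outcomes",
    "BOUNDARY_RULES",
]

BOUNDARY_RULES = ("exclude", "count_as_not_ltfu")


def label_ltfu_primary(
    visit_dates: Sequence[date], study_end: date
) -> list[tuple[int, int]]:
    """Per-visit (ltfu, evaluable) flags for a patient's sorted visits.

    LTFU=1 when the next attended visit is more than 365 days later, or
    when no next visit exists and more than 365 days remain to
    ``study_end`` (the gap is observably over a year).  When no next
    visit exists and 365 days have not elapsed by study end, the visit is
    non-evaluable.
    """
    dates = sorted(visit_dates)
    out = []
    for i, d in enumerate(dates):
        if d > study_end:
            raise ValueError(f"visit {d} after study end {study_end}")
        if i + 1 < len(dates):
            out.append((int((dates[i + 1] - d).days > 365), 1))
        elif (study_end - d).days > 365:
            out.append((1, 1))
        else:
            out.append((0, 0))
    return out


def label_nhas(visit_dates: Sequence[date], index_date: date) -> int:
    """NHAS LTFU flag (1 = not retained) for the visit at ``index_date``.

    Retained iff the 365-day window starting at the index visit contains
    at least two attended visits strictly more than 90 days apart (the
    index visit itself counts).
    """
    window = sorted(
        d for d in visit_dates if 0 <= (d - index_date).days <= 365
    )
    for i in range(len(window)):
        for j in range(i + 1, len(window)):
            if (window[j] - window[i]).days > 90:
                return 0
    return 1


def label_high_vl(
    index_date: date,
    draws: Iterable[tuple[date, float]],
    threshold: float = 200.0,
    include_same_day: bool = False,
) -> tuple[int, int]:
    """(high_vl, evaluable) for one visit from (draw_date, copies/ml) pairs.

    The follow-up window is half-open, (visit, visit+365] by default;
    ``include_same_day`` closes it at the left.  A visit with no draw in
    the window is non-evaluable.
    """
    low = 0 if include_same_day else 1
    seen = False
    high = 0
    for draw_date, value in draws:
        if value < 0:
            raise ValueError(f"negative viral load {value} on {draw_date}")
        offset = (draw_date - index_date).days
        if low <= offset <= 365:
            seen = True
            if value >= threshold:
                high = 1
    return high, int(seen)


def label_outcomes(
    visits: pd.DataFrame,
    labs: pd.DataFrame,
    study_end: date,
    vl_threshold: float = 200.0,
    include_same_day: bool = False,
) -> pd.DataFrame:
    """Label every visit; returns one row per visit_id.

    ``visits`` needs visit_id, patient_id, visit_date; ``labs`` needs
    patient_id, draw_date, viral_load_copies_ml.  Output columns:
    ltfu_primary, ltfu_primary_evaluable, nhas_ltfu, high_vl,
    high_vl_evaluable.  Duplicate identical lab rows and input row order
    have no effect on the labels.
    """
    v = visits[["visit_id", "patient_id", "visit_date"]].copy()
    v["visit_date"] = pd.to_datetime(v["visit_date"]).dt.date
    v = v.sort_values(["patient_id", "visit_date", "visit_id"]).reset_index(drop=True)

    draws_by_patient: dict[str, list[tuple[date, float]]] = {}
    if len(labs):
        lb = labs.copy()
        lb["draw_date"] = pd.to_datetime(lb["draw_date"]).dt.date
        for pid, dd, val in zip(
            lb["patient_id"], lb["draw_date"], lb["viral_load_copies_ml"]
        ):
            draws_by_patient.setdefault(pid, []).append((dd, float(val)))

    rows = []
    for pid, grp in v.groupby("patient_id", sort=False):
        dates = list(grp["visit_date"])
        ltfu = label_ltfu_primary(dates, study_end)
        draws = draws_by_patient.get(pid, [])
        for (vid, d), (flag, ok) in zip(zip(grp["visit_id"], dates), ltfu):
            high, vl_ok = label_high_vl(
                d, draws, threshold=vl_threshold, include_same_day=include_same_day
            )
            rows.append(
                {
                    "visit_id": vid,
                    "ltfu_primary": flag,
                    "ltfu_primary_evaluable": ok,
                    "nhas_ltfu": label_nhas(dates, d),
                    "high_vl": high,
                    "high_vl_evaluable": vl_ok,
                }
            )
    return pd.DataFrame(rows).sort_values("visit_id").reset_index(drop=True)
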