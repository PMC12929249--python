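"""Between-class comparisons: odds ratios, chi-squared, Kruskal-Wallis.

For a single binary group indicator the logistic-regression maximum
likelihood estimate of the odds ratio is the 2x2 cross-product ratio, so
the odds-ratio engine works directly on counts with Wald standard errors
on the log scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "ORResult",
    "odds_ratio",
    "chi_squared",
    "kruskal_wallis",
    "outcome_table",
    "outcome_table_from_counts",
    "profile_table",
]

#: Wald CI multiplier for two-sided 95% coverage.
Z_95 = 1.959964

SIGNIFICANCE_ALPHA = 0.001


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a/b: outcome-positive/negative in the comparison class; c/d: reference."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class ORResult:
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    counts: ContingencyTable2x2


def odds_ratio(table: ContingencyTable2x2, haldane: bool = False) -> ORResult:
    """Cross-product odds ratio with Wald 95% CI and two-sided p.

    Zero cells raise by default; ``haldane=True`` adds 0.5 to every cell
    (Haldane-Anscombe correction) with a logged note.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError(
                "zero cell in 2x2 table; pass haldane=True for the +0.5 correction"
            )
        logger.info("applying Haldane-Anscombe +0.5 correction to %s", table)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_point)
    ci_low = math.exp(log_or - Z_95 * se)
    ci_high = math.exp(log_or + Z_95 * se)
    z = log_or / se
    p = 2.0 * sps.norm.sf(abs(z))
    return ORResult(or_point=or_point, ci_low=ci_low, ci_high=ci_high, p_value=p, counts=table)


def chi_squared(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-squared on an r x c count table (no continuity correction).

    Returns (statistic, degrees of freedom, p-value).  Expected counts
    come from the margins; a zero margin is an input error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-squared p-value.

    Degenerate input with every value identical across all groups returns
    (0.0, 1.0) instead of erroring.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _or_row(a: int, b: int, c: int, d: int, haldane: bool) -> dict:
    res = odds_ratio(ContingencyTable2x2(a, b, c, d), haldane=haldane)
    return {
        "odds_ratio": res.or_point,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p_value": res.p_value,
    }


def outcome_table_from_counts(
    class_sizes: Mapping[int, int],
    outcome_counts: Mapping[int, int],
    reference: int = 1,
    haldane: bool = False,
) -> pd.DataFrame:
    """Per-class outcome report from raw counts.

    One row per class: n, outcome count, percent (1 decimal), and the
    odds ratio versus the reference class with Wald 95% CI.  The
    reference row carries NaN in the OR columns (rendered "Ref.").
    """
    if reference not in class_sizes:
        raise ValueError(f"reference class {reference} absent from class sizes")
    ref_n = class_sizes[reference]
    ref_pos = outcome_counts[reference]
    rows = []
    for cls in sorted(class_sizes):
        n = int(class_sizes[cls])
        pos = int(outcome_counts[cls])
        row = {
            "class": cls,
            "n": n,
            "count": pos,
            "percent": round(100.0 * pos / n, 1),
            "odds_ratio": math.nan,
            "ci_low": math.nan,
            "ci_high": math.nan,
            "p_value": math.nan,
            "reference": cls == reference,
        }
        if cls != reference:
            row.update(_or_row(pos, n - pos, ref_pos, ref_n - ref_pos, haldane))
        rows.append(row)
    return pd.DataFrame(rows)


def outcome_table(
    assignments: pd.DataFrame,
    outcome_labels: pd.DataFrame,
    outcome: str,
    reference: int = 1,
    evaluable_column: str | None = None,
    include_nonevaluable: bool = False,
    haldane: bool = False,
) -> pd.DataFrame:
    """Join class assignments with outcome labels and tabulate ORs.

    ``assignments`` needs visit_id and ``class`` columns.  Non-evaluable
    visits are dropped from denominators unless ``include_nonevaluable``
    (which mimics full-class-size denominators, counting them as
    outcome-negative unless flagged).
    """
    merged = assignments.merge(outcome_labels, on="visit_id", how="left")
    if merged[outcome].isna().any():
        missing = merged.loc[merged[outcome].isna(), "visit_id"].tolist()[:10]
        raise ValueError(f"visits without outcome labels, e.g. {missing}")
    if evaluable_column is not None and not include_nonevaluable:
        merged = merged[merged[evaluable_column] == 1]
    grouped = merged.groupby("class")[outcome]
    sizes = grouped.size().to_dict()
    counts = grouped.sum().astype(int).to_dict()
    if reference not in sizes:
        raise ValueError(f"reference class {reference} has no visits")
    return outcome_table_from_counts(sizes, counts, reference=reference, haldane=haldane)


def render_outcome_markdown(table: pd.DataFrame, outcome_name: str) -> str:
    """Markdown rendering with "Ref." in the reference row."""
    lines = [
        f"| Class | n | {outcome_name}, n (%) | OR (95% CI) | P |",
        "|---|---|---|---|---|",
    ]
    for _, r in table.iterrows():
        if r["reference"]:
            or_txt, p_txt = "Ref.", ""
        else:
            or_txt = f"{r['odds_ratio']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})"
            p_txt = f"{r['p_value']:.3g}"
        lines.append(
            f"| {int(r['class'])} | {int(r['n'])} | {int(r['count'])} ({r['percent']:.1f}) "
            f"| {or_txt} | {p_txt} |"
        )
    return "\n".join(lines) + "\n"


def profile_table(
    features: pd.DataFrame,
    levels: Mapping[str, Sequence],
    assignments: pd.DataFrame,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Per-variable class profile with chi-squared tests across classes.

    One row per (variable, level): overall and per-class counts and
    percentages, the across-class chi-squared p for the variable, and a
    significance flag at ``alpha``.  Percentages within a variable sum
    to 100 per column up to rounding.
    """
    merged = features.merge(assignments[["visit_id", "class"]], on="visit_id")
    if len(merged) != len(features):
        raise ValueError("assignments do not cover every feature row")
    classes = sorted(merged["class"].unique())
    rows = []
    for var in levels:
        if var not in merged.columns:
            continue
        lv = list(levels[var])
        counts = {
            cls: merged.loc[merged["class"] == cls, var].value_counts()
            for cls in classes
        }
        overall = merged[var].value_counts()
        table = [
            [int(counts[cls].get(level, 0)) for level in lv] for cls in classes
        ]
        if len(classes) >= 2:
            used = [i for i, level in enumerate(lv) if overall.get(level, 0) > 0]
            if len(used) >= 2:
                sub = [[r[i] for i in used] for r in table]
                _, _, p = chi_squared(sub)
            else:
                p = math.nan
        else:
            p = math.nan
        for level in lv:
            row = {
                "variable": var,
                "level": level,
                "overall_n": int(overall.get(level, 0)),
                "overall_pct": round(100.0 * overall.get(level, 0) / len(merged), 1),
                "p_value": p,
                "significant": bool(p < alpha) if not math.isnan(p) else False,
            }
            for cls in classes:
                n_cls = int((merged["class"] == cls).sum())
                cnt = int(counts[cls].get(level, 0))
                row[f"class{cls}_n"] = cnt
                row[f"class{cls}_pct"] = round(100.0 * cnt / n_cls, 1)
            rows.append(row)
    return pd.DataFrame(rows)
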