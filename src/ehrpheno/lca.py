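"""Latent class analysis for categorical indicators, fitted by EM.

The model: observation ``i`` belongs to latent class ``c`` with mixing
weight ``pi[c]``; conditional on the class, item ``j`` takes level ``l``
independently with probability ``theta[c][j][l]``.  Estimation is plain
EM with multiple random restarts, log-space likelihood evaluation, and a
light clip on ``theta`` to keep estimates off the boundary.

Model selection fits a contiguous range of class counts and reports four
information criteria (AIC, BIC, sample-size-adjusted BIC, consistent
AIC); the selected class count is the argmin of the chosen criterion,
with ties broken toward the smaller model.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

__all__ = [
    "LCAModel",
    "FitStatistics",
    "SelectionTable",
    "encode_features",
    "e_step",
    "m_step",
    "fit",
    "fit_statistics",
    "select_model",
    "assign_classes",
    "align_classes",
    "DegenerateClassError",
]

THETA_CLIP = 1e-6

CRITERIA = ("aic", "bic", "sabic", "caic")


class DegenerateClassError(RuntimeError):
    """A class's total responsibility collapsed to (numerically) zero."""


@dataclass
class LCAModel:
    """Fitted parameters: mixing weights and item-response probabilities."""

    pi: np.ndarray                 # shape (C,)
    theta: list[np.ndarray]        # per item, shape (C, L_j)
    item_names: list[str]
    item_levels: list[int]

    @property
    def C(self) -> int:
        return len(self.pi)

    def validate(self) -> None:
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if abs(self.pi.sum() - 1.0) > 1e-9 or (self.pi <= 0).any() or (self.pi >= 1).any():
            if not (self.C == 1 and np.isclose(self.pi[0], 1.0)):
                raise ValueError("pi must be a probability vector with entries in (0,1)")
        for j, th in enumerate(self.theta):
            if th.shape != (self.C, self.item_levels[j]):
                raise ValueError(f"theta[{j}] has shape {th.shape}")
            if np.abs(th.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"theta[{j}] rows must sum to 1")

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "pi": self.pi.tolist(),
            "theta": [th.tolist() for th in self.theta],
            "item_names": list(self.item_names),
            "item_levels": list(self.item_levels),
        }

    def to_json(self, path: str | Path, **metadata) -> None:
        payload = self.to_dict()
        if metadata:
            payload["metadata"] = metadata
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "LCAModel":
        return cls(
            pi=np.asarray(raw["pi"], dtype=float),
            theta=[np.asarray(t, dtype=float) for t in raw["theta"]],
            item_names=list(raw["item_names"]),
            item_levels=list(raw["item_levels"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LCAModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FitStatistics:
    logLik: float
    k: int
    n: int
    aic: float
    bic: float
    sabic: float
    caic: float


def encode_features(
    matrix: pd.DataFrame, levels: Mapping[str, Sequence]
) -> tuple[np.ndarray, list[str], list[int]]:
    """Integer-code a categorical feature matrix against declared levels.

    Returns the code array (n, J), item names, and per-item level counts.
    Values outside a column's declared level set are an input error.
    """
    item_names = [c for c in matrix.columns if c in levels]
    codes = np.empty((len(matrix), len(item_names)), dtype=np.int64)
    item_levels = []
    for j, name in enumerate(item_names):
        lv = list(levels[name])
        index = {v: i for i, v in enumerate(lv)}
        col = matrix[name].tolist()
        try:
            codes[:, j] = [index[v] for v in col]
        except KeyError as exc:
            raise ValueError(
                f"column {name!r} contains value {exc.args[0]!r} outside declared levels {lv}"
            ) from None
        item_levels.append(len(lv))
    return codes, item_names, item_levels


def _log_components(pi: np.ndarray, theta: list[np.ndarray], X: np.ndarray) -> np.ndarray:
    """log(pi[c]) + sum_j log theta[c][j][x_ij], shape (n, C)."""
    n = X.shape[0]
    logw = np.broadcast_to(np.log(pi), (n, len(pi))).copy()
    for j, th in enumerate(theta):
        xj = X[:, j]
        if xj.min() < 0 or xj.max() >= th.shape[1]:
            raise ValueError(f"item {j} has level codes outside [0, {th.shape[1] - 1}]")
        logw += np.log(th[:, xj]).T
    return logw


def e_step(model: LCAModel, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior responsibilities and total log-likelihood, in log space."""
    logw = _log_components(model.pi, model.theta, X)
    norm = logsumexp(logw, axis=1)
    resp = np.exp(logw - norm[:, None])
    return resp, float(norm.sum())


def m_step(
    resp: np.ndarray, X: np.ndarray, item_levels: Sequence[int],
    item_names: Sequence[str] | None = None,
) -> LCAModel:
    """Maximize pi and theta given responsibilities.

    theta rows are clipped to [1e-6, 1-1e-6] and renormalized so no cell
    is ever exactly 0 or 1.
    """
    n, C = resp.shape
    totals = resp.sum(axis=0)
    dead = np.where(totals < 1e-8)[0]
    if dead.size:
        raise DegenerateClassError(
            f"class(es) {dead.tolist()} have vanishing total responsibility"
        )
    pi = totals / n
    theta = []
    for j, L in enumerate(item_levels):
        onehot = np.zeros((n, L))
        onehot[np.arange(n), X[:, j]] = 1.0
        th = (resp.T @ onehot) / totals[:, None]
        th = np.clip(th, THETA_CLIP, 1.0 - THETA_CLIP)
        th /= th.sum(axis=1, keepdims=True)
        theta.append(th)
    names = list(item_names) if item_names is not None else [f"item_{j}" for j in range(len(item_levels))]
    return LCAModel(pi=pi, theta=theta, item_names=names, item_levels=list(item_levels))


def _random_model(
    C: int, item_levels: Sequence[int], rng: np.random.Generator,
    item_names: Sequence[str],
) -> LCAModel:
    pi = rng.dirichlet(np.full(C, 5.0))
    theta = [rng.dirichlet(np.ones(L), size=C) for L in item_levels]
    theta = [np.clip(t, 0.05, 0.95) for t in theta]
    theta = [t / t.sum(axis=1, keepdims=True) for t in theta]
    return LCAModel(pi=pi, theta=theta, item_names=list(item_names), item_levels=list(item_levels))


def _reorder(model: LCAModel, order: np.ndarray) -> LCAModel:
    return LCAModel(
        pi=model.pi[order],
        theta=[th[order] for th in model.theta],
        item_names=model.item_names,
        item_levels=model.item_levels,
    )


def fit(
    X: np.ndarray,
    item_levels: Sequence[int],
    C: int,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = None,
    item_names: Sequence[str] | None = None,
) -> tuple[LCAModel, FitStatistics, list[float]]:
    """Fit a C-class model; best of ``n_restarts`` random initializations.

    Convergence: relative log-likelihood change below ``tol`` or
    ``max_iter`` EM iterations.  The returned model has classes reordered
    by descending mixing weight; the trace is the per-iteration
    log-likelihood of the winning restart.
    """
    X = np.asarray(X, dtype=np.int64)
    n = X.shape[0]
    if C < 1:
        raise ValueError("C must be >= 1")
    if n < C:
        raise ValueError(f"need at least C={C} observations, got {n}")
    names = list(item_names) if item_names is not None else [f"item_{j}" for j in range(X.shape[1])]
    rng = np.random.default_rng(seed)

    best: tuple[float, LCAModel, list[float]] | None = None
    failures: list[str] = []
    for _ in range(max(1, n_restarts)):
        model = _random_model(C, item_levels, rng, names)
        trace: list[float] = []
        try:
            prev = -math.inf
            for _it in range(max_iter):
                resp, ll = e_step(model, X)
                trace.append(ll)
                if prev > -math.inf and (ll - prev) <= tol * abs(prev):
                    break
                prev = ll
                model = m_step(resp, X, item_levels, names)
        except DegenerateClassError as exc:
            failures.append(str(exc))
            continue
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], model, trace)
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts degenerate: {failures[:3]}")

    ll, model, trace = best
    order = np.argsort(-model.pi, kind="stable")
    model = _reorder(model, order)
    stats = fit_statistics(ll, C, item_levels, n)
    return model, stats, trace


def n_free_parameters(C: int, item_levels: Sequence[int]) -> int:
    """(C - 1) mixing weights plus C * sum_j (L_j - 1) response cells."""
    return (C - 1) + C * sum(L - 1 for L in item_levels)


def fit_statistics(
    logLik: float, C: int, item_levels: Sequence[int], n: int
) -> FitStatistics:
    """Information criteria for a fitted model.

    AIC = -2LL + 2k; BIC = -2LL + k ln n;
    SABIC = -2LL + k ln((n + 2) / 24) (Sclove's adjustment);
    CAIC = -2LL + k (ln n + 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = n_free_parameters(C, item_levels)
    d = -2.0 * logLik
    return FitStatistics(
        logLik=logLik,
        k=k,
        n=n,
        aic=d + 2.0 * k,
        bic=d + k * math.log(n),
        sabic=d + k * math.log((n + 2.0) / 24.0),
        caic=d + k * (math.log(n) + 1.0),
    )


@dataclass
class SelectionTable:
    """Fit statistics across a contiguous range of class counts."""

    records: pd.DataFrame          # columns: C, logLik, k, aic, bic, sabic, caic
    selected: dict[str, int]       # criterion -> argmin C (ties -> smaller C)
    criterion: str
    models: dict[int, LCAModel] = field(default_factory=dict)

    @property
    def selected_C(self) -> int:
        return self.selected[self.criterion]

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def plot(self, path: str | Path) -> None:
        """Criterion-vs-class-count curves (one line per criterion)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for crit in CRITERIA:
            ax.plot(self.records["C"], self.records[crit], marker="o", label=crit.upper())
        ax.set_xlabel("number of latent classes")
        ax.set_ylabel("criterion value")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def select_model(
    X: np.ndarray,
    item_levels: Sequence[int],
    c_range: Sequence[int] = range(1, 11),
    criterion: str = "bic",
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = None,
    item_names: Sequence[str] | None = None,
) -> SelectionTable:
    """Fit every class count in ``c_range`` and tabulate all four criteria."""
    c_list = list(c_range)
    if not c_list:
        raise ValueError("c_range must be non-empty")
    if sorted(c_list) != list(range(min(c_list), max(c_list) + 1)):
        raise ValueError("c_range must be contiguous")
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(c_list))
    rows = []
    models: dict[int, LCAModel] = {}
    for C, child in zip(c_list, child_seeds):
        try:
            model, stats, _ = fit(
                X, item_levels, C,
                n_restarts=n_restarts, tol=tol, max_iter=max_iter,
                seed=child, item_names=item_names,
            )
        except Exception as exc:
            raise RuntimeError(f"fitting failed at C={C}: {exc}") from exc
        models[C] = model
        rows.append(
            {
                "C": C, "logLik": stats.logLik, "k": stats.k,
                "aic": stats.aic, "bic": stats.bic,
                "sabic": stats.sabic, "caic": stats.caic,
            }
        )
    records = pd.DataFrame(rows).sort_values("C").reset_index(drop=True)
    selected = {
        crit: int(records.loc[records[crit].idxmin(), "C"]) for crit in CRITERIA
    }
    return SelectionTable(records=records, selected=selected, criterion=criterion, models=models)


def assign_classes(model: LCAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-posterior class per observation (1-based) plus posteriors.

    Ties go to the lower class index.
    """
    resp, _ = e_step(model, np.asarray(X, dtype=np.int64))
    return np.argmax(resp, axis=1) + 1, resp


def align_classes(model_a: LCAModel, model_b: LCAModel) -> np.ndarray:
    """Permutation ``p`` with ``p[c]`` = class of ``model_b`` matching class ``c`` of ``model_a``.

    Chosen to minimize the total absolute difference between the two
    models' item-response probabilities over all class pairings; the cost
    separates over pairs, so the Hungarian assignment is exact (identical
    to exhaustive search over all C! permutations).
    """
    if model_a.C != model_b.C or model_a.item_levels != model_b.item_levels:
        raise ValueError("models must share C and item level structure")
    flat_a = np.hstack([th for th in model_a.theta])
    flat_b = np.hstack([th for th in model_b.theta])
    cost = np.abs(flat_a[:, None, :] - flat_b[None, :, :]).sum(axis=2)
    _, cols = linear_sum_assignment(cost)
    return cols


def brute_force_align(model_a: LCAModel, model_b: LCAModel) -> np.ndarray:
    """Exhaustive counterpart of :func:`align_classes` (small C only)."""
    if model_a.C != model_b.C or model_a.item_levels != model_b.item_levels:
        raise ValueError("models must share C and item level structure")
    flat_a = np.hstack([th for th in model_a.theta])
    flat_b = np.hstack([th for th in model_b.theta])
    best_perm, best_cost = None, math.inf
    for perm in itertools.permutations(range(model_a.C)):
        cost = sum(
            np.abs(flat_a[c] - flat_b[p]).sum() for c, p in enumerate(perm)
        )
        if cost < best_cost - 1e-12:
            best_cost, best_perm = cost, perm
    return np.asarray(best_perm)
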