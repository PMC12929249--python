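"""End-to-end orchestration: simulate -> annotate -> features -> outcomes
-> latent class fit -> class comparison, driven by one YAML config.

Every stage writes plain-text outputs into a run directory; a provenance
manifest records the SHA-256 of each output so that a rerun with the
same config and seed can be verified byte-for-byte.  All randomness is
derived from one top-level seed via ``numpy.random.SeedSequence(seed)``
spawned once per randomized stage, in stage order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feats
from . import lca, notes, outcomes, stats, synth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    n_patients: int = 200
    true_C: int = 3
    study_start: date = date(2017, 1, 1)
    study_end: date = date(2020, 12, 31)
    lexicon_path: str | None = None      # None -> packaged default lexicon
    window: int | None = None
    c_min: int = 1
    c_max: int = 4
    criterion: str = "bic"
    n_restarts: int = 5
    tol: float = 1e-6
    max_iter: int = 500
    vl_threshold: float = 200.0
    include_same_day_vl: bool = False
    boundary_rule: str = "exclude"
    reference_class: int = 1
    negation_rate: float = 0.3

    def validate(self) -> None:
        if self.lexicon_path is not None and not Path(self.lexicon_path).exists():
            raise FileNotFoundError(f"lexicon file not found: {self.lexicon_path}")
        if self.boundary_rule not in outcomes.BOUNDARY_RULES:
            raise ValueError(f"boundary_rule must be one of {outcomes.BOUNDARY_RULES}")
        if self.criterion not in lca.CRITERIA:
            raise ValueError(f"criterion must be one of {lca.CRITERIA}")
        if not self.c_min >= 1 or self.c_max < self.c_min:
            raise ValueError("need 1 <= c_min <= c_max")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must follow study_start")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("study_start", "study_end"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = date.fromisoformat(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            **{k: v for k, v in self.__dict__.items() if not isinstance(v, date)},
            "study_start": self.study_start.isoformat(),
            "study_end": self.study_end.isoformat(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def demo_config(outdir: str, seed: int = 0, n_patients: int = 200) -> PipelineConfig:
    """Small deterministic demo: 3 true classes, class range 1..4."""
    return PipelineConfig(outdir=outdir, seed=seed, n_patients=n_patients)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all six stages; returns the provenance manifest.

    Stage failures abort with the stage name attached.  Outputs land in
    ``config.outdir``; the manifest (also written there) maps every
    output file to its SHA-256.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lexicon = (
        notes.TopicLexicon.from_json(config.lexicon_path)
        if config.lexicon_path
        else notes.default_lexicon()
    )
    top = np.random.SeedSequence(config.seed)
    sim_seed, lca_seed = top.spawn(2)

    manifest: dict = {"seed": config.seed, "stages": []}

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": {p.name: _sha256(p) for p in paths.values()},
            }
        )

    def stage(name):
        def deco(fn):
            def wrapped(*args):
                logger.info("[%s] running", name)
                try:
                    return fn(*args)
                except Exception as exc:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return wrapped
        return deco

    @stage("simulate")
    def _simulate():
        gen = synth.default_generator_config(
            n_patients=config.n_patients,
            seed=int(sim_seed.generate_state(1)[0]),
            true_C=config.true_C,
            study_start=config.study_start,
            study_end=config.study_end,
            negation_rate=config.negation_rate,
        )
        cohort = synth.generate_cohort(gen, lexicon=lexicon)
        paths = cohort.write(outdir)
        record("simulate", paths)
        return cohort

    @stage("annotate")
    def _annotate(cohort):
        flags = notes.annotate_corpus(cohort.notes, lexicon, window=config.window)
        path = outdir / "topic_flags.csv"
        flags.to_csv(path, index=False)
        record("annotate", {"flags": path})
        return flags

    @stage("features")
    def _features(cohort, flags):
        matrix, levels = feats.build_feature_matrix(cohort.visits, flags)
        path = outdir / "features.csv"
        feats.write_feature_matrix(matrix, levels, path)
        record("features", {"matrix": path, "levels": Path(str(path) + ".levels.json")})
        return matrix, levels

    @stage("outcomes")
    def _outcomes(cohort):
        labels = outcomes.label_outcomes(
            cohort.visits,
            cohort.labs,
            study_end=config.study_end,
            vl_threshold=config.vl_threshold,
            include_same_day=config.include_same_day_vl,
        )
        path = outdir / "outcomes.csv"
        labels.to_csv(path, index=False)
        record("outcomes", {"labels": path})
        return labels

    @stage("lca")
    def _lca(matrix, levels):
        X, item_names, item_levels = lca.encode_features(matrix, levels)
        table = lca.select_model(
            X, item_levels,
            c_range=range(config.c_min, config.c_max + 1),
            criterion=config.criterion,
            n_restarts=config.n_restarts,
            tol=config.tol,
            max_iter=config.max_iter,
            seed=lca_seed,
            item_names=item_names,
        )
        model = table.models[table.selected_C]
        classes, resp = lca.assign_classes(model, X)
        assignments = pd.DataFrame({"visit_id": matrix["visit_id"], "class": classes})
        for c in range(model.C):
            assignments[f"posterior_{c + 1}"] = resp[:, c]
        sel_path = outdir / "selection.csv"
        model_path = outdir / "model.json"
        asg_path = outdir / "assignments.csv"
        table.to_csv(sel_path)
        model.to_json(model_path, seed=config.seed, criterion=config.criterion)
        assignments.to_csv(asg_path, index=False, float_format="%.10g")
        record("lca", {"selection": sel_path, "model": model_path, "assignments": asg_path})
        return assignments

    @stage("compare")
    def _compare(matrix, levels, assignments, labels):
        include_all = config.boundary_rule == "count_as_not_ltfu"
        paths = {}
        for outcome, evaluable in (
            ("ltfu_primary", "ltfu_primary_evaluable"),
            ("nhas_ltfu", None),
            ("high_vl", "high_vl_evaluable"),
        ):
            table = stats.outcome_table(
                assignments, labels, outcome,
                reference=config.reference_class,
                evaluable_column=evaluable,
                include_nonevaluable=include_all,
            )
            path = outdir / f"outcome_{outcome}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.6g")
            paths[outcome] = path
        profile = stats.profile_table(matrix, levels, assignments)
        ppath = outdir / "profile.tsv"
        profile.to_csv(ppath, sep="\t", index=False, float_format="%.6g")
        paths["profile"] = ppath
        record("compare", paths)

    cohort = _simulate()
    flags = _annotate(cohort)
    matrix, levels = _features(cohort, flags)
    labels = _outcomes(cohort)
    assignments = _lca(matrix, levels)
    _compare(matrix, levels, assignments, labels)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
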