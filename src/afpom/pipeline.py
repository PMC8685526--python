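"""Stage orchestration: population -> simulate -> classify -> train.

Each stage writes its products plus a manifest entry into a run directory and
is skipped on re-run when its output already exists (idempotent, resumable).
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cell_model as cm
from . import experiment_ml as ml
from . import population as pop
from . import reentry_analysis as ra
from . import synthetic_data as sd
from . import tissue_sim as ts
from .config import RunConfig
from .drug_model import condition_drug, default_drug_library
from .errors import MissingStageError

STAGES = ("population", "simulate", "classify", "train")


def _manifest_update(outdir: Path, stage: str, info: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest[stage] = info
    path.write_text(json.dumps(manifest, indent=2, default=str))


def _geometry(cfg: RunConfig, size: str) -> ts.TissueGeometry:
    if cfg.plane_nodes is None:
        return ts.build_geometry(size)
    return ts.desk_geometry(size, cfg.plane_nodes)


def _constraints(cfg: RunConfig) -> pop.BiomarkerConstraints:
    if cfg.constraint_source == "synthetic":
        return sd.gen_constraint_box()
    if cfg.constraint_source == "synthetic-surrogate":
        return sd.gen_constraint_box(variant="surrogate")
    return pop.BiomarkerConstraints.from_csv(cfg.constraint_source)


def run_pipeline(cfg: RunConfig, stages: Sequence[str] = STAGES,
                 outdir: str | Path = "run") -> Path:
    """Execute the requested stages in canonical order; returns the run dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    for stage in STAGES:
        if stage in stages:
            globals()[f"stage_{stage}"](cfg, outdir)
    return outdir


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_population(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    out = outdir / "population.csv"
    if out.exists():
        return pd.read_csv(out)
    t0 = time.time()
    constraints = _constraints(cfg)
    records = []
    n_accepted = 0
    target = cfg.population_target
    max_batches = 1 if target is None else 6
    for batch in range(max_batches):
        candidates = pop.sample_profiles(cfg.lhs_n, cfg.seed + batch,
                                         prefix=f"p{batch}_")
        records.extend(pop.calibrate_population(
            candidates, constraints, model=cfg.model,
            n_beats=cfg.strip.n_beats, cl=cfg.strip.cl, n_last=cfg.strip.n_last,
            dx=cfg.strip.dx, D_baseline=cfg.D_baseline))
        n_accepted = sum(r.accepted for r in records)
        if target is None or n_accepted >= target:
            break
    table = pop.population_table(records)
    table.to_csv(out, index=False)
    _manifest_update(outdir, "population", {
        "config_hash": cfg.config_hash(), "seed": cfg.seed, "n": cfg.lhs_n,
        "accepted": int(table["accepted"].sum()), "wall_s": time.time() - t0})
    return table


def _load_accepted(cfg: RunConfig, outdir: Path) -> list[cm.IonicProfile]:
    path = outdir / "population.csv"
    if not path.exists():
        raise MissingStageError("population output missing; run the 'population' stage first")
    table = pd.read_csv(path)
    acc = table[table["accepted"]]
    if cfg.population_target is not None:
        acc = acc.head(cfg.population_target)
    return [cm.IonicProfile.from_array(r["profile_id"],
                                       [r[n] for n in cm.MULTIPLIER_NAMES])
            for _, r in acc.iterrows()]


def stage_simulate(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    out = outdir / "outcomes.csv"
    if out.exists():
        return pd.read_csv(out)
    t0 = time.time()
    profiles = _load_accepted(cfg, outdir)
    library = default_drug_library(cfg.agonist_law)
    protocol = ts.StimulusProtocol(
        n_s1=cfg.protocol.n_s1, cl=cfg.protocol.cl,
        s2_coupling=cfg.protocol.s2_coupling, amplitude=cfg.protocol.amplitude,
        duration=cfg.protocol.duration, observation=cfg.protocol.observation)
    rows = []
    for prof in profiles:
        for size in cfg.sizes:
            geom = _geometry(cfg, size)
            for cond in cfg.conditions:
                drug = condition_drug(cond, library)
                result, outcome, tracks = ts.run_s1s2_induction(
                    prof, geom, drug, protocol, model=cfg.model,
                    dt=cfg.dt, D_baseline=cfg.D_baseline)
                rows.append({
                    "profile_id": prof.profile_id, "tissue": size,
                    "condition": cond, "induced": outcome.induced,
                    "maintained": outcome.maintained,
                    "n_tracks": outcome.n_tracks,
                    "apd90_strip": result.apd90_strip,
                    "failed": result.failed})
    outcomes = pd.DataFrame(rows)
    outcomes.to_csv(out, index=False)
    _manifest_update(outdir, "simulate", {
        "config_hash": cfg.config_hash(), "n_simulations": len(rows),
        "n_induced": int(outcomes["induced"].sum()),
        "n_maintained": int(outcomes["maintained"].sum()),
        "wall_s": time.time() - t0})
    return outcomes


def stage_classify(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    out = outdir / "labeled_table.csv"
    if out.exists():
        return pd.read_csv(out)
    t0 = time.time()
    opath = outdir / "outcomes.csv"
    if not opath.exists():
        raise MissingStageError("outcomes missing; run the 'simulate' stage first")
    outcomes = pd.read_csv(opath)
    profiles = _load_accepted(cfg, outdir)
    design = ml.build_design(profiles, cfg.sizes, cfg.conditions,
                             default_drug_library(cfg.agonist_law))
    merged = design.merge(outcomes[["profile_id", "tissue", "condition",
                                    "induced", "maintained"]],
                          on=["profile_id", "tissue", "condition"], how="left")
    if merged["induced"].isna().any():
        raise MissingStageError("outcomes table does not cover the design grid; "
                                "re-run the 'simulate' stage")
    merged["label"] = np.where(merged["maintained"], "induced", "non_inducible")
    merged.to_csv(out, index=False)
    _manifest_update(outdir, "classify", {
        "config_hash": cfg.config_hash(), "rows": len(merged),
        "wall_s": time.time() - t0})
    return merged


def stage_train(cfg: RunConfig, outdir: Path) -> ml.TrainedClassifier:
    t0 = time.time()
    tpath = outdir / "labeled_table.csv"
    if not tpath.exists():
        raise MissingStageError("labeled table missing; run the 'classify' stage first")
    table = pd.read_csv(tpath)
    clf = ml.train_classifier(table, cfg.ml.train_frac, cfg.ml.k,
                              seed=cfg.ml.seed, n_estimators=cfg.ml.n_estimators)
    summary = ml.extract_decision_paths(table, cfg.ml.max_depth, seed=cfg.ml.seed)
    (outdir / "model.json").write_text(json.dumps({
        "features": clf.features,
        "importances": clf.importances.to_dict(),
        "cv_scores": clf.cv_scores.tolist(),
        "cv_mean": float(clf.cv_scores.mean()),
        "cv_sd": float(clf.cv_scores.std()),
        "holdout_accuracy": clf.holdout_accuracy,
        "n_train": clf.n_train, "n_test": clf.n_test,
        "root_feature": summary.root_feature,
        "root_threshold": summary.root_threshold,
    }, indent=2))
    (outdir / "sunburst.json").write_text(json.dumps(summary.sunburst, indent=2))
    _manifest_update(outdir, "train", {
        "config_hash": cfg.config_hash(), "seed": cfg.ml.seed,
        "holdout_accuracy": clf.holdout_accuracy, "wall_s": time.time() - t0})
    return clf
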