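"""Staged pipeline orchestration.

Stages: phantoms -> split -> train -> optimize -> evaluate, plus classify
(full-scan labelling). Each stage reads the artifacts of its
prerequisites from the run directory, is idempotent given an identical
configuration and seed, and appends a structured log line recording the
config hash and the seeds it used. Missing prerequisites raise
:class:`StageDependencyError` naming the absent artifact.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .augment import (RosterEntry, apply_geometric, draw_sponge_params,
                      sponge_augment)
from .config import RunConfig
from .ensemble import (EnsembleWeights, SearchConfig, WeightedEnsemble,
                       balanced_accuracy_objective, geometric_mean_objective,
                       optimize_weights)
from .evaluation import (SplitPlan, confusion, macro_roc,
                         metrics_from_confusion, make_split)
from .fullscan import classify_scan, ila_score, write_ila_scores, write_label_map
from .nn.core import TrainConfig
from .phantoms import PhantomSpec, generate_phantom
from .sampling import (NormalizationStats, apply_normalization, extract_roi,
                       fit_normalization)
from .tissue import TissueClass
from .volume import (AnnotatedPoint, CTVolume, read_annotations, read_volume,
                     write_annotations, write_mask, write_volume)
from .zoo import ENSEMBLE_ORDER, ArchSpec, PatchClassifier

STAGES = ("phantoms", "split", "train", "optimize", "evaluate", "classify")


class StageDependencyError(RuntimeError):
    pass


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise StageDependencyError(
            f"stage '{stage}' requires {path} (produced by stage "
            f"'{produced_by}'); run that stage first")
    return path


def _log(out: Path, stage: str, cfg: RunConfig, extra: dict) -> None:
    entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
             "config_hash": cfg.config_hash(), "seed": cfg.stage_seed(stage),
             "version": __version__, "python": platform.python_version()}
    entry.update(extra)
    with (out / "pipeline.log.jsonl").open("a") as fh:
        fh.write(json.dumps(entry) + "\n")


def run_pipeline(cfg: RunConfig, stage: str) -> dict:
    """Run one stage; returns a dict describing the artifacts written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = _STAGE_FUNCS[stage](cfg, out)
    _log(out, stage, cfg, {"artifacts": sorted(map(str, result.values()))
                           if result else []})
    return result


# ------------------------------------------------------------- phantoms

def stage_phantoms(cfg: RunConfig, out: Path) -> dict:
    pdir = out / "phantoms"
    pdir.mkdir(exist_ok=True)
    seed = cfg.stage_seed("phantoms")
    all_points: List[AnnotatedPoint] = []
    for i in range(cfg.phantoms.n_phantoms):
        spec = PhantomSpec(shape=tuple(cfg.phantoms.shape),
                           noise_hu=cfg.phantoms.noise_hu,
                           rng_seed=(seed + i) % 2 ** 31)
        vol, pts = generate_phantom(spec)
        write_volume(vol, pdir / f"{vol.scan_id}.nii")
        write_mask(vol, pdir / f"{vol.scan_id}_mask.nii")
        all_points.extend(pts)
    ann = pdir / "annotations.csv"
    write_annotations(all_points, ann)
    return {"annotations": ann, "dir": pdir}


def _volume_index(cfg: RunConfig, stage: str) -> Dict[str, Path]:
    vdir = Path(cfg.volume_dir) if cfg.volume_dir else Path(cfg.out_dir) / "phantoms"
    _require(vdir, stage, "phantoms")
    index = {}
    for p in sorted(vdir.glob("*.nii*")):
        if "_mask" in p.name:
            continue
        index[p.name.split(".")[0]] = p
    if not index:
        raise StageDependencyError(f"no volumes found under {vdir}")
    return index


def _load_volume(path: Path) -> CTVolume:
    mask = path.with_name(path.name.replace(".nii", "_mask.nii", 1))
    return read_volume(path, mask_path=mask if mask.exists() else None)


def _annotation_path(cfg: RunConfig, stage: str) -> Path:
    if cfg.annotations:
        return _require(Path(cfg.annotations), stage, "phantoms")
    return _require(Path(cfg.out_dir) / "phantoms" / "annotations.csv",
                    stage, "phantoms")


# ---------------------------------------------------------------- split

def stage_split(cfg: RunConfig, out: Path) -> dict:
    points = read_annotations(_annotation_path(cfg, "split"))
    plan = make_split(points, level=cfg.split.level,
                      rng_seed=cfg.stage_seed("split"),
                      target=cfg.split.target,
                      large_class_min=cfg.split.large_class_min,
                      train_fraction=cfg.split.train_fraction,
                      n_folds=cfg.split.n_folds,
                      n_test_subjects=cfg.split.n_test_subjects)
    path = out / "split.json"
    path.write_text(json.dumps(_plan_to_dict(plan), indent=2))
    return {"split": path}


def _point_to_dict(p: AnnotatedPoint) -> dict:
    return {"scan_id": p.scan_id, "subject_id": p.subject_id,
            "coord": list(p.coord), "label": p.label.name, "kernel": p.kernel}


def _point_from_dict(d: dict) -> AnnotatedPoint:
    return AnnotatedPoint(scan_id=d["scan_id"], subject_id=d["subject_id"],
                          coord=tuple(d["coord"]),
                          label=TissueClass.from_name(d["label"]),
                          kernel=d["kernel"])


def _plan_to_dict(plan: SplitPlan) -> dict:
    from .augment import GeometricTransform

    def entry(e: RosterEntry) -> dict:
        t = e.transform
        return {"point": _point_to_dict(e.point),
                "transform": {"rotation": t.rotation, "shift": list(t.shift),
                              "flip_h": t.flip_h, "flip_v": t.flip_v,
                              "shear": t.shear}}

    return {
        "level": plan.level,
        "test_subjects": list(plan.test_subjects),
        "classes": {
            c.name: {
                "train": [_point_to_dict(p) for p in plan.per_class[c].train],
                "test": [_point_to_dict(p) for p in plan.per_class[c].test],
                "needs_augmentation": plan.per_class[c].needs_augmentation,
                "roster": [entry(e) for e in plan.rosters[c]],
                "fold_of": plan.fold_of[c].tolist(),
            }
            for c in sorted(plan.per_class, key=int)
        },
    }


def _plan_from_dict(d: dict) -> SplitPlan:
    from .augment import GeometricTransform
    from .evaluation import ClassSplit

    per_class, rosters, fold_of = {}, {}, {}
    for name, blob in d["classes"].items():
        c = TissueClass.from_name(name)
        per_class[c] = ClassSplit(
            train=[_point_from_dict(x) for x in blob["train"]],
            test=[_point_from_dict(x) for x in blob["test"]],
            needs_augmentation=blob["needs_augmentation"])
        rosters[c] = [
            RosterEntry(_point_from_dict(e["point"]),
                        GeometricTransform(
                            rotation=e["transform"]["rotation"],
                            shift=tuple(e["transform"]["shift"]),
                            flip_h=e["transform"]["flip_h"],
                            flip_v=e["transform"]["flip_v"],
                            shear=e["transform"]["shear"]))
            for e in blob["roster"]]
        fold_of[c] = np.asarray(blob["fold_of"])
    return SplitPlan(level=d["level"], per_class=per_class, rosters=rosters,
                     fold_of=fold_of, test_subjects=tuple(d["test_subjects"]))


# ---------------------------------------------------------------- train

def _roster_samples(entries: Sequence[RosterEntry], volumes: Dict[str, CTVolume],
                    mode: str, cfg: RunConfig, rng: np.random.Generator):
    """Extract (and augment) HU patches for roster entries in one mode."""
    samples = []
    for e in entries:
        vol = volumes[e.point.scan_id]
        s = extract_roi(vol, e.point, mode)
        if e.is_augmented:
            s = apply_geometric(s, e.transform)
        if cfg.sponge.enabled:
            lv = vol.lung_volume_ml() or cfg.sponge.default_lung_volume_ml
            p = draw_sponge_params(rng, lung_volume=lv,
                                   delta_v_range=tuple(cfg.sponge.delta_v_range_ml),
                                   air_hu=cfg.sponge.air_hu)
            s = sponge_augment(s, p)
        samples.append(s)
    return samples


def stage_train(cfg: RunConfig, out: Path) -> dict:
    plan = _plan_from_dict(json.loads(
        _require(out / "split.json", "train", "split").read_text()))
    vol_index = _volume_index(cfg, "train")
    volumes = {sid: _load_volume(p) for sid, p in vol_index.items()}
    seed = cfg.stage_seed("train")
    rng = np.random.default_rng(seed)
    mdir = out / "models"
    mdir.mkdir(exist_ok=True)

    train_entries, val_entries = plan.fold_rosters(fold=0)
    artifacts = {}
    norm_stats_by_mode: Dict[str, NormalizationStats] = {}
    samples_cache: Dict[str, tuple] = {}
    for mode in ("axial2d", "ortho2p5d", "slab3d"):
        tr = _roster_samples(train_entries, volumes, mode, cfg, rng)
        va = _roster_samples(val_entries, volumes, mode, cfg, rng)
        stats = fit_normalization(tr + va)
        norm_stats_by_mode[mode] = stats
        samples_cache[mode] = ([apply_normalization(s, stats) for s in tr],
                               [apply_normalization(s, stats) for s in va])

    tcfg_base = cfg.train.to_dict()
    for i, name in enumerate(ENSEMBLE_ORDER):
        spec = ArchSpec(name, channels=tuple(cfg.zoo.channels),
                        dense_units=cfg.zoo.dense_units)
        tcfg = TrainConfig(**{**tcfg_base, "rng_seed": (seed + 7 + i) % 2 ** 31})
        model = PatchClassifier(spec=spec, seed=(seed + i) % 2 ** 31)
        tr, va = samples_cache[spec.input_mode]
        model.fit(tr, va, tcfg)
        model.save(mdir / name, train_cfg=tcfg,
                   norm_stats=norm_stats_by_mode[spec.input_mode])
        artifacts[name] = mdir / (name + ".npz")

    stats_path = out / "normalization.json"
    stats_path.write_text(json.dumps(
        {m: {"mean": s.mean, "std": s.std}
         for m, s in norm_stats_by_mode.items()}, indent=2))
    artifacts["normalization"] = stats_path
    return artifacts


def _load_models(out: Path, stage: str) -> List[PatchClassifier]:
    mdir = _require(out / "models", stage, "train")
    models = []
    for name in ENSEMBLE_ORDER:
        _require(mdir / f"{name}.npz", stage, "train")
        models.append(PatchClassifier.load(mdir / name))
    return models


def _load_norm_stats(out: Path, stage: str) -> Dict[str, NormalizationStats]:
    blob = json.loads(_require(out / "normalization.json", stage,
                               "train").read_text())
    return {m: NormalizationStats(**v) for m, v in blob.items()}


class _NormalizingMember:
    """Wraps a zoo member so point classification standardizes with the
    mode's training statistics."""

    def __init__(self, model: PatchClassifier, stats: NormalizationStats):
        self.model = model
        self.stats = stats
        self.spec = model.spec

    def classify_points(self, vol, points, batch_size=128):
        return self.model.classify_points(vol, points, batch_size=batch_size,
                                          norm_stats=self.stats)


def _validation_probs(models, plan, volumes, cfg, rng):
    probs, labels = [], None
    _, val_entries = plan.fold_rosters(fold=0)
    stats = _load_norm_stats(Path(cfg.out_dir), "optimize")
    for model in models:
        mode = model.spec.input_mode
        va = _roster_samples(val_entries, volumes, mode, cfg, rng)
        va = [apply_normalization(s, stats[mode]) for s in va]
        if labels is None:
            labels = np.asarray([int(s.label) for s in va])
        probs.append(model.predict_proba(va))
    return np.stack(probs), labels


def stage_optimize(cfg: RunConfig, out: Path) -> dict:
    plan = _plan_from_dict(json.loads(
        _require(out / "split.json", "optimize", "split").read_text()))
    models = _load_models(out, "optimize")
    volumes = {sid: _load_volume(p)
               for sid, p in _volume_index(cfg, "optimize").items()}
    seed = cfg.stage_seed("optimize")
    rng = np.random.default_rng(seed)
    probs, labels = _validation_probs(models, plan, volumes, cfg, rng)
    objective = (geometric_mean_objective if cfg.search.objective == "gm"
                 else balanced_accuracy_objective)
    scfg = SearchConfig(method=cfg.search.method, n_trials=cfg.search.n_trials,
                        gamma=cfg.search.gamma,
                        n_candidates=cfg.search.n_candidates,
                        rng_seed=seed, objective=objective)
    weights, history = optimize_weights(probs, labels, scfg)
    wpath = out / "weights.json"
    wpath.write_text(weights.to_json(
        ENSEMBLE_ORDER, method=cfg.search.method, seed=seed,
        n_trials=cfg.search.n_trials, objective=cfg.search.objective,
        best_score=min(t.score for t in history)))
    return {"weights": wpath}


def stage_evaluate(cfg: RunConfig, out: Path) -> dict:
    plan = _plan_from_dict(json.loads(
        _require(out / "split.json", "evaluate", "split").read_text()))
    models = _load_models(out, "evaluate")
    stats = _load_norm_stats(out, "evaluate")
    weights = EnsembleWeights.from_json(
        _require(out / "weights.json", "evaluate", "optimize").read_text(),
        ENSEMBLE_ORDER)
    volumes = {sid: _load_volume(p)
               for sid, p in _volume_index(cfg, "evaluate").items()}
    members = [_NormalizingMember(m, stats[m.spec.input_mode]) for m in models]
    ens = WeightedEnsemble(models=members, weights=weights)

    test_points = plan.all_test_points()
    by_scan: Dict[str, List[AnnotatedPoint]] = {}
    for p in test_points:
        by_scan.setdefault(p.scan_id, []).append(p)
    fused_all, labels_all = [], []
    for sid, pts in sorted(by_scan.items()):
        fused_all.append(ens.classify_points(volumes[sid], pts,
                                             batch_size=cfg.fullscan.batch))
        labels_all.extend(int(p.label) for p in pts)
    fused = np.concatenate(fused_all)
    labels = np.asarray(labels_all)
    pred = fused.argmax(axis=1)

    cm = confusion(labels, pred)
    metrics = metrics_from_confusion(cm, classes=[TissueClass(c) for c in
                                                  np.unique(labels)])
    fpr, tpr, auc = macro_roc(fused, labels)
    report = {"macro": metrics.macro, "auc": auc,
              "per_class": {c.name: v for c, v in metrics.per_class.items()},
              "n_test": int(len(labels))}
    rpath = out / "metrics.json"
    rpath.write_text(json.dumps(report, indent=2))
    metrics.to_frame().to_csv(out / "metrics.csv")
    cm.to_frame().to_csv(out / "confusion.csv")
    np.savetxt(out / "roc.csv", np.column_stack([fpr, tpr]), delimiter=",",
               header="fpr,tpr", comments="")
    return {"metrics": rpath, "confusion": out / "confusion.csv",
            "roc": out / "roc.csv"}


def stage_classify(cfg: RunConfig, out: Path) -> dict:
    models = _load_models(out, "classify")
    stats = _load_norm_stats(out, "classify")
    weights = EnsembleWeights.from_json(
        _require(out / "weights.json", "classify", "optimize").read_text(),
        ENSEMBLE_ORDER)
    members = [_NormalizingMember(m, stats[m.spec.input_mode]) for m in models]
    ens = WeightedEnsemble(models=members, weights=weights)
    cdir = out / "labelmaps"
    cdir.mkdir(exist_ok=True)
    scores = []
    artifacts = {}
    for sid, path in _volume_index(cfg, "classify").items():
        vol = _load_volume(path)
        if vol.lung_mask is None:
            continue
        lmap = classify_scan(vol, ens, grid_spacing=cfg.fullscan.grid_spacing,
                             batch=cfg.fullscan.batch)
        write_label_map(lmap, cdir / f"{sid}_labels.nii")
        scores.append(ila_score(lmap, cfg.fullscan.certainty_threshold,
                                scan_id=sid))
        artifacts[sid] = cdir / f"{sid}_labels.nii"
    spath = out / "ila_scores.csv"
    write_ila_scores(scores, spath)
    artifacts["ila_scores"] = spath
    return artifacts


_STAGE_FUNCS = {
    "phantoms": stage_phantoms,
    "split": stage_split,
    "train": stage_train,
    "optimize": stage_optimize,
    "evaluate": stage_evaluate,
    "classify": stage_classify,
}
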