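"""End-to-end pipeline: simulate -> features -> phase I -> phase II ->
evaluate -> explain, with a resumable run directory.

Every stage writes its outputs under ``run_dir`` and is skipped on
``resume=True`` when those outputs already exist.  One global seed
drives all stages (sub-seeds are fixed offsets of it), so two runs with
identical config and seed produce identical artifacts.

The default configuration is the desk-scale profile: a synthetic
strong-effect cohort (16^3 grid, 8 regions, 120 frames, 40 subjects)
with reduced epoch counts.  ``full_scale_config()`` returns the
settings for 116-region, 61x73x61 data with the published
hyperparameters; it requires real atlas-aligned scans and long training.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .connectome import (compute_connectivity_vector, compute_fingerprint,
                         extract_roi_timeseries, n_pair_features,
                         ConnectivityVector, FingerprintMap)
from .dataio import (labels_to_indices, read_atlas, read_manifest,
                     read_volume4d, write_metrics_json)
from .errors import ValidationError
from .evaluation import compute_metrics, confusion_counts
from .explain import grad_cam, overlay, saliency_region_means
from .models import (FusionConfig, MLPConfig, ResNetConfig, build_mlp,
                     build_resnet3d, load_checkpoint, predict,
                     save_checkpoint)
from .synthetic import CohortGroundTruth, SyntheticCohortSpec, simulate_cohort
from .training import (SplitPlan, TrainConfig, split_dataset,
                       train_phase1_mlp, train_phase1_resnet,
                       train_phase2_multimodal)

import nibabel as nib

log = logging.getLogger("connfusion")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {
        "enabled": True,
        "grid": [16, 16, 16],
        "n_regions": 8,
        "T": 120,
        "n_per_group": 20,
        "base_corr": 0.2,
        "effect_delta": 0.6,
        "voxel_noise_sd": 0.5,
        "modality_split": 0.0,
        "effect_pairs": None,
    },
    "data": {  # used when simulate.enabled is false
        "manifest": None,
        "atlas": None,
    },
    "split": {"n_train": 30, "stratified": False},
    "model": {"head_sizes": [256, 64, 16, 2]},
    "train": {
        "batch_size": 8,
        "momentum": 0.9,
        "weight_decay": 0.0,
        "resnet": {"base_lr": 1e-2, "epochs": 10, "lr_step": 6},
        "mlp": {"base_lr": 1e-2, "epochs": 25, "lr_step": 5},
        "multimodal": {"base_lr": 1e-3, "epochs": 10, "lr_step": 8},
    },
    "explain": {"layer": "layer2", "n_subjects": 1, "target_class": "ASD"},
}


def full_scale_config() -> dict:
    """Published study conditions (116-region AAL on 61x73x61 grids)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cfg["simulate"]["enabled"] = False
    cfg["split"] = {"n_train": 900, "stratified": False}
    cfg["train"]["resnet"] = {"base_lr": 1e-2, "epochs": 30, "lr_step": 6}
    cfg["train"]["mlp"] = {"base_lr": 1e-2, "epochs": 50, "lr_step": 5}
    cfg["train"]["multimodal"] = {"base_lr": 1e-5, "epochs": 30, "lr_step": 8}
    cfg["explain"]["layer"] = "layer4"
    return cfg


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def resolve_config(config: dict | None) -> dict:
    return _merge(DEFAULT_CONFIG, config or {})


def load_config_file(path: str | Path) -> dict:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return payload


def _train_config(cfg: dict, phase: dict, seed: int) -> TrainConfig:
    return TrainConfig(
        batch_size=int(cfg["train"]["batch_size"]),
        momentum=float(cfg["train"]["momentum"]),
        weight_decay=float(cfg["train"]["weight_decay"]),
        base_lr=float(phase["base_lr"]),
        epochs=int(phase["epochs"]),
        lr_step=int(phase["lr_step"]),
        seed=seed,
    )


def _feature_paths(run_dir: Path, sid: str) -> tuple[Path, Path]:
    fdir = run_dir / "features"
    return fdir / f"{sid}_fingerprint.nii.gz", fdir / f"{sid}_vector.npy"


def _load_features(run_dir: Path, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    fps, vecs = [], []
    for sid in ids:
        fp_path, vec_path = _feature_paths(run_dir, sid)
        fp = np.asarray(nib.load(str(fp_path)).dataobj, dtype=nn.DTYPE)
        fps.append(np.moveaxis(fp, 3, 0))  # (N,H,W,D): regions as channels
        vecs.append(np.load(vec_path).astype(nn.DTYPE))
    return np.stack(fps), np.stack(vecs)


#: stage order used by ``run_pipeline(stop_after=...)``
STAGES = ("simulate", "features", "split", "phase1", "phase2", "evaluate",
          "explain")


def run_pipeline(config: dict | None = None, run_dir: str | Path = "run",
                 resume: bool = False, stop_after: str | None = None) -> dict:
    """Execute the stages in order; returns the final metrics payload
    (or a partial payload when ``stop_after`` names an earlier stage)."""
    if stop_after is not None and stop_after not in STAGES:
        raise ValidationError(
            f"unknown stage {stop_after!r}; valid stages: {list(STAGES)}")
    cfg = resolve_config(config)
    seed = int(cfg["seed"])
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=resume or not run_dir.exists())
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), 20))
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    # -- stage: simulate ------------------------------------------------
    truth = None
    if cfg["simulate"]["enabled"]:
        cohort_dir = run_dir / "cohort"
        manifest_path = cohort_dir / "manifest.csv"
        if not (resume and manifest_path.exists()):
            sim = cfg["simulate"]
            spec = SyntheticCohortSpec(
                grid=tuple(sim["grid"]), n_regions=int(sim["n_regions"]),
                T=int(sim["T"]), n_per_group=int(sim["n_per_group"]),
                base_corr=float(sim["base_corr"]),
                effect_pairs=sim["effect_pairs"],
                effect_delta=float(sim["effect_delta"]),
                voxel_noise_sd=float(sim["voxel_noise_sd"]),
                modality_split=float(sim["modality_split"]),
                seed=seed,
            )
            log.info("simulating cohort: %d subjects on grid %s",
                     2 * spec.n_per_group, spec.grid)
            simulate_cohort(spec, out_dir=cohort_dir)
        atlas_path = cohort_dir / "atlas.nii.gz"
        truth_path = cohort_dir / "ground_truth.json"
        if truth_path.exists():
            truth = CohortGroundTruth.from_json(truth_path)
        data_root = cohort_dir
    else:
        if not cfg["data"]["manifest"] or not cfg["data"]["atlas"]:
            raise ValidationError(
                "simulate.enabled is false but data.manifest/data.atlas unset")
        manifest_path = Path(cfg["data"]["manifest"])
        atlas_path = Path(cfg["data"]["atlas"])
        data_root = manifest_path.parent

    if stop_after == "simulate":
        return {"stage": "simulate", "manifest": str(manifest_path)}

    records = read_manifest(manifest_path)
    if not records:
        raise ValidationError("manifest contains no subjects")
    first_vol = read_volume4d(data_root / records[0].volume_path)
    atlas = read_atlas(atlas_path, expected_grid=first_vol.grid)

    # -- stage: features ------------------------------------------------
    (run_dir / "features").mkdir(exist_ok=True)
    for rec in records:
        fp_path, vec_path = _feature_paths(run_dir, rec.subject_id)
        if resume and fp_path.exists() and vec_path.exists():
            continue
        vol = read_volume4d(data_root / rec.volume_path)
        roits = extract_roi_timeseries(vol, atlas)
        fingerprint = compute_fingerprint(vol, roits)
        nib.save(nib.Nifti1Image(fingerprint.corr, np.eye(4)), str(fp_path))
        np.save(vec_path, compute_connectivity_vector(roits).values)
    log.info("features ready for %d subjects", len(records))
    if stop_after == "features":
        return {"stage": "features", "n_subjects": len(records)}

    # -- stage: split ---------------------------------------------------
    split_path = run_dir / "split.json"
    if resume and split_path.exists():
        plan = SplitPlan.from_json(split_path)
    else:
        plan = split_dataset(records, n_train=int(cfg["split"]["n_train"]),
                             seed=seed + 1,
                             stratified=bool(cfg["split"]["stratified"]))
        plan.to_json(split_path)

    if stop_after == "split":
        return {"stage": "split", "n_train": len(plan.train_ids),
                "n_test": len(plan.test_ids)}

    label_of = {r.subject_id: r.label for r in records}
    y_train = labels_to_indices([label_of[s] for s in plan.train_ids])
    y_test_names = [label_of[s] for s in plan.test_ids]

    n_regions = atlas.n_regions
    resnet_cfg = ResNetConfig(in_channels=n_regions)
    mlp_cfg = MLPConfig(in_features=n_pair_features(n_regions))
    fusion_cfg = FusionConfig(head_sizes=tuple(cfg["model"]["head_sizes"]))

    fp_train, vec_train = _load_features(run_dir, plan.train_ids)

    # -- stage: phase I -------------------------------------------------
    resnet_ckpt = run_dir / "resnet_phase1.npz"
    mlp_ckpt = run_dir / "mlp_phase1.npz"
    if resume and resnet_ckpt.exists() and mlp_ckpt.exists():
        resnet = load_checkpoint(resnet_ckpt)
        mlp = load_checkpoint(mlp_ckpt)
    else:
        resnet = build_resnet3d(resnet_cfg, seed=seed + 2)
        resnet, res_hist = train_phase1_resnet(
            resnet, fp_train, y_train,
            _train_config(cfg, cfg["train"]["resnet"], seed + 3))
        save_checkpoint(resnet_ckpt, resnet)
        mlp = build_mlp(mlp_cfg, seed=seed + 4)
        mlp, mlp_hist = train_phase1_mlp(
            mlp, vec_train, y_train,
            _train_config(cfg, cfg["train"]["mlp"], seed + 5))
        save_checkpoint(mlp_ckpt, mlp)
        (run_dir / "phase1_history.json").write_text(json.dumps({
            "resnet": {"loss": res_hist.loss_history,
                       "accuracy": res_hist.accuracy_history},
            "mlp": {"loss": mlp_hist.loss_history,
                    "accuracy": mlp_hist.accuracy_history},
        }, indent=2) + "\n")
        log.info("phase I complete (resnet acc %.3f, mlp acc %.3f)",
                 res_hist.accuracy_history[-1], mlp_hist.accuracy_history[-1])

    if stop_after == "phase1":
        return {"stage": "phase1", "resnet_checkpoint": str(resnet_ckpt),
                "mlp_checkpoint": str(mlp_ckpt)}

    # -- stage: phase II ------------------------------------------------
    fused_ckpt = run_dir / "multimodal_phase2.npz"
    if resume and fused_ckpt.exists():
        fused = load_checkpoint(fused_ckpt)
    else:
        fused, fused_hist = train_phase2_multimodal(
            resnet, mlp, fusion_cfg, fp_train, vec_train, y_train,
            _train_config(cfg, cfg["train"]["multimodal"], seed + 6))
        save_checkpoint(fused_ckpt, fused)
        (run_dir / "phase2_history.json").write_text(json.dumps({
            "loss": fused_hist.loss_history,
            "accuracy": fused_hist.accuracy_history,
        }, indent=2) + "\n")
        log.info("phase II complete (train acc %.3f)",
                 fused_hist.accuracy_history[-1])

    if stop_after == "phase2":
        return {"stage": "phase2", "checkpoint": str(fused_ckpt)}

    # -- stage: evaluate ------------------------------------------------
    fp_test, vec_test = _load_features(run_dir, plan.test_ids)
    payload: dict = {"n_train": len(plan.train_ids), "n_test": len(plan.test_ids)}
    for name, net, needs in (("resnet", resnet, "fp"), ("mlp", mlp, "vec"),
                             ("multimodal", fused, "both")):
        preds = []
        for i in range(len(plan.test_ids)):
            fingerprint = FingerprintMap(corr=np.moveaxis(fp_test[i], 0, 3),
                                         region_ids=list(atlas.region_ids))
            vector = ConnectivityVector(values=vec_test[i],
                                        region_ids=list(atlas.region_ids))
            if needs == "fp":
                result = predict(net, fingerprint=fingerprint)
            elif needs == "vec":
                result = predict(net, connectivity=vector)
            else:
                result = predict(net, fingerprint=fingerprint,
                                 connectivity=vector)
            preds.append(result.predicted_class)
        counts = confusion_counts(preds, y_test_names)
        metrics = compute_metrics(counts)
        payload[name] = {**metrics.as_dict(),
                         "counts": {"tp": counts.tp, "fp": counts.fp,
                                    "tn": counts.tn, "fn": counts.fn}}
    # headline metrics = the fused model's
    payload.update({k: payload["multimodal"][k]
                    for k in ("accuracy", "precision", "recall", "f1")})
    write_metrics_json(run_dir / "metrics.json", payload)
    log.info("test accuracy: multimodal %.3f, resnet %.3f, mlp %.3f",
             payload["multimodal"]["accuracy"], payload["resnet"]["accuracy"],
             payload["mlp"]["accuracy"])

    if stop_after == "evaluate":
        return payload

    # -- stage: explain -------------------------------------------------
    exp_cfg = cfg["explain"]
    exp_dir = run_dir / "explain"
    exp_dir.mkdir(exist_ok=True)
    explain_payload = []
    for sid in plan.test_ids[: int(exp_cfg["n_subjects"])]:
        i = plan.test_ids.index(sid)
        fingerprint = FingerprintMap(corr=np.moveaxis(fp_test[i], 0, 3),
                                     region_ids=list(atlas.region_ids))
        vector = ConnectivityVector(values=vec_test[i],
                                    region_ids=list(atlas.region_ids))
        sal = grad_cam(fused, fingerprint, vector,
                       target_class=str(exp_cfg["target_class"]),
                       layer=str(exp_cfg["layer"]))
        nib.save(nib.Nifti1Image(sal.heat.astype(np.float32), np.eye(4)),
                 str(exp_dir / f"{sid}_saliency.nii.gz"))
        vol = read_volume4d(data_root / [r for r in records
                                         if r.subject_id == sid][0].volume_path)
        overlay(sal, vol, exp_dir, prefix=sid)
        entry = {"subject_id": sid, "layer": sal.source_layer,
                 "degenerate": sal.degenerate}
        # inside/outside contrast only makes sense when some regions carry
        # no effect at all
        if (truth is not None and truth.effect_regions
                and set(truth.effect_regions) < set(atlas.region_ids)):
            inside, outside = saliency_region_means(
                sal, atlas.labels, truth.effect_regions)
            entry.update({"mean_inside_effect_regions": inside,
                          "mean_outside_effect_regions": outside})
        explain_payload.append(entry)
    (exp_dir / "explain.json").write_text(
        json.dumps(explain_payload, indent=2) + "\n")

    return payload
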