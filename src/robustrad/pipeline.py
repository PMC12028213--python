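"""End-to-end orchestration: phantom → maps → perturbation → features →
ICC gate → nested selection/classification.

Each stage writes its outputs under the run directory and records
parameters, seeds, counts and timing in ``manifest.json``; a rerun with
``resume=True`` skips stages the manifest marks complete, so a run is
resumable from any finished checkpoint.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from robustrad import io
from robustrad.aif import make_aif
from robustrad.config import PipelineConfig
from robustrad.core import ALL_MAP_NAMES
from robustrad.classify import make_fold_plan, run_nested_cv
from robustrad.diffusion import ivim_maps
from robustrad.features.extract import extract_features_for_maps, feature_columns
from robustrad.kinetic import fit_tofts_maps, model_free_maps
from robustrad.perturb import generate_artificial_rois, union_of_variants, VARIANT_NAMES
from robustrad.phantom import iter_cohort, truth_row
from robustrad.robustness import icc_matrix_report, robust_feature_set

log = logging.getLogger("robustrad.pipeline")

STAGES = ("phantom", "perturb", "maps", "features", "icc", "classify")


@dataclass
class RunResult:
    run_dir: Path
    manifest: dict


def _load_manifest(run_dir: Path) -> dict:
    p = run_dir / "manifest.json"
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _write_manifest(run_dir: Path, manifest: dict) -> None:
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _stage_done(manifest: dict, stage: str) -> bool:
    return manifest["stages"].get(stage, {}).get("complete", False)


def _record(manifest: dict, stage: str, t0: float, **info) -> None:
    manifest["stages"][stage] = {
        "complete": True,
        "elapsed_s": round(time.time() - t0, 2),
        **info,
    }


def _lesion_ids(run_dir: Path) -> list[str]:
    truth = pd.read_csv(run_dir / "truth.csv")
    return truth["lesion_id"].tolist()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_phantom(cfg: PipelineConfig, run_dir: Path) -> dict:
    lesion_dir = run_dir / "lesions"
    lesion_dir.mkdir(parents=True, exist_ok=True)
    aif = make_aif(cfg.aif_model)
    rows = []
    for les in iter_cohort(cfg.cohort, cfg.acquisition, aif=aif):
        io.save_series(les.dce, lesion_dir / f"{les.lesion_id}_dce.nii")
        io.save_series(les.dwi, lesion_dir / f"{les.lesion_id}_dwi.nii")
        io.save_mask(les.mask, lesion_dir / f"{les.lesion_id}_mask.nii.gz")
        rows.append(truth_row(les))
    truth = pd.DataFrame(rows)
    truth.to_csv(run_dir / "truth.csv", index=False)
    counts = truth["class"].value_counts().to_dict()
    log.info("phantom: %d lesions (%s)", len(truth), counts)
    return {"n_lesions": len(truth), "class_counts": counts}


def stage_perturb(cfg: PipelineConfig, run_dir: Path) -> dict:
    mask_dir = run_dir / "masks"
    mask_dir.mkdir(exist_ok=True)
    provenance = {}
    ids = _lesion_ids(run_dir)
    for lid in ids:
        mask = io.load_mask(run_dir / "lesions" / f"{lid}_mask.nii.gz")
        pset = generate_artificial_rois(mask)
        io.save_mask(mask, mask_dir / f"{lid}_original.nii.gz")
        for name, variant in pset.variants.items():
            io.save_mask(variant, mask_dir / f"{lid}_{name}.nii.gz")
        io.save_mask(union_of_variants(pset), mask_dir / f"{lid}_union.nii.gz")
        provenance[lid] = pset.provenance
    (run_dir / "perturbation_provenance.json").write_text(
        json.dumps(provenance, indent=2)
    )
    n_var = 1 + len(VARIANT_NAMES)
    log.info("perturb: %d lesions x %d ROI variants", len(ids), n_var)
    return {"n_lesions": len(ids), "n_variants_per_lesion": n_var}


def stage_maps(cfg: PipelineConfig, run_dir: Path) -> dict:
    map_dir = run_dir / "maps"
    map_dir.mkdir(exist_ok=True)
    aif = make_aif(cfg.aif_model)
    qc_all = {}
    ids = _lesion_ids(run_dir)
    for lid in ids:
        union = io.load_mask(run_dir / "masks" / f"{lid}_union.nii.gz")
        dce = io.load_series(run_dir / "lesions" / f"{lid}_dce.nii")
        io.check_same_grid(dce.grid_shape, union.data.shape)
        maps_mf, qc_mf = model_free_maps(dce, union)
        maps_tofts, qc_tofts = fit_tofts_maps(dce, union, aif, alpha=cfg.alpha)
        del dce
        dwi = io.load_series(run_dir / "lesions" / f"{lid}_dwi.nii")
        io.check_same_grid(dwi.grid_shape, union.data.shape)
        maps_ivim, qc_ivim = ivim_maps(dwi, union)
        del dwi
        for pmap in {**maps_mf, **maps_tofts, **maps_ivim}.values():
            io.save_map(pmap, map_dir / f"{lid}_{pmap.name}.nii.gz")
        qc_all[lid] = {"model_free": qc_mf, "tofts": qc_tofts, "ivim": qc_ivim}
        log.info("maps: %s done (12 maps)", lid)
    (run_dir / "maps_qc.json").write_text(json.dumps(qc_all, indent=2))
    return {"n_lesions": len(ids), "n_maps_per_lesion": len(ALL_MAP_NAMES)}


def stage_features(cfg: PipelineConfig, run_dir: Path) -> dict:
    ids = _lesion_ids(run_dir)
    variants = ("original",) + VARIANT_NAMES
    rows = []
    for lid in ids:
        maps = {
            name: io.load_map(run_dir / "maps" / f"{lid}_{name}.nii.gz", name)
            for name in ALL_MAP_NAMES
        }
        for variant in variants:
            mask = io.load_mask(run_dir / "masks" / f"{lid}_{variant}.nii.gz")
            bundle = {name: (maps[name], mask) for name in ALL_MAP_NAMES}
            vec = extract_features_for_maps(bundle, cfg.bin_widths)
            rows.append(
                pd.concat([pd.Series({"lesion_id": lid, "roi_variant": variant}), vec])
            )
        log.info("features: %s done (%d variants)", lid, len(variants))
    table = pd.DataFrame(rows)
    table = table[["lesion_id", "roi_variant"] + feature_columns()]
    io.save_feature_table(table, run_dir / "features.csv")
    return {
        "n_rows": len(table),
        "n_feature_columns": len(table.columns) - 2,
        "n_variants": len(variants),
    }


def stage_icc(cfg: PipelineConfig, run_dir: Path) -> dict:
    table = io.load_feature_table(run_dir / "features.csv")
    robust, report = robust_feature_set(table, threshold=cfg.icc_threshold)
    report.to_csv(run_dir / "icc_report.csv", index=False)
    icc_matrix_report(report).to_csv(run_dir / "icc_matrix.csv")
    (run_dir / "robust_features.txt").write_text("\n".join(robust) + "\n")
    log.info("icc: %d/%d features retained (ICC > %.2f)",
             len(robust), len(report), cfg.icc_threshold)
    return {
        "n_features": len(report),
        "n_robust": len(robust),
        "icc_threshold": cfg.icc_threshold,
    }


def stage_classify(cfg: PipelineConfig, run_dir: Path, seed: int) -> dict:
    table = io.load_feature_table(run_dir / "features.csv")
    robust = (run_dir / "robust_features.txt").read_text().split()
    truth = pd.read_csv(run_dir / "truth.csv")
    original = (
        table[table["roi_variant"] == "original"]
        .set_index("lesion_id")
        .loc[truth["lesion_id"]]
    )
    X = original[robust].to_numpy()
    y3 = truth["class"].to_numpy()
    y2 = (y3 == "malignant").astype(int)
    plan = make_fold_plan(y2, k=cfg.cv_k, repetitions=cfg.cv_repetitions, seed=seed)
    result = run_nested_cv(
        X, y2, y3, plan,
        selectors=cfg.selectors, classifiers=cfg.classifiers, seed=seed,
        selector_params={"relieff": {"n_permutations": cfg.relieff_permutations}},
        feature_names=robust,
    )
    result.performance.to_csv(run_dir / "performance.csv", index=False)
    result.records.to_csv(run_dir / "cv_records.csv", index=False)
    result.selection_frequency.to_csv(run_dir / "selection_frequency.csv", index=False)
    acc = result.performance.query("metric == 'accuracy'")
    log.info("classify: mean accuracy %.3f-%.3f across %d pairs",
             acc["mean"].min(), acc["mean"].max(), len(acc))
    return {
        "n_robust_features": len(robust),
        "cv_repetitions": cfg.cv_repetitions,
        "n_skipped_folds": result.n_skipped_folds,
        "mean_accuracy_min": float(acc["mean"].min()),
        "mean_accuracy_max": float(acc["mean"].max()),
    }


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> RunResult:
    """Run every stage in order, recording a manifest checkpoint after each."""
    cfg.validate()
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(run_dir) if resume else {"stages": {}}
    manifest["config"] = json.loads(json.dumps(_cfg_dict(cfg), default=str))
    manifest["seed"] = cfg.seed

    runners = {
        "phantom": lambda: stage_phantom(cfg, run_dir),
        "perturb": lambda: stage_perturb(cfg, run_dir),
        "maps": lambda: stage_maps(cfg, run_dir),
        "features": lambda: stage_features(cfg, run_dir),
        "icc": lambda: stage_icc(cfg, run_dir),
        "classify": lambda: stage_classify(cfg, run_dir, cfg.seed),
    }
    for stage in STAGES:
        if resume and _stage_done(manifest, stage):
            log.info("skipping completed stage %s", stage)
            continue
        t0 = time.time()
        try:
            info = runners[stage]()
        except Exception as e:
            manifest["stages"][stage] = {"complete": False, "error": str(e)}
            _write_manifest(run_dir, manifest)
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        _record(manifest, stage, t0, **info)
        _write_manifest(run_dir, manifest)
    return RunResult(run_dir=run_dir, manifest=manifest)


def _cfg_dict(cfg: PipelineConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)
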