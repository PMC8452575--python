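"""End-to-end orchestration: extract -> harmonise -> select -> train -> evaluate.

The pipeline honours strict train/test discipline: harmonisation parameters,
the correlation filter, model selection, and the Youden threshold are all
computed on the training set only and then applied unchanged to the test
set. Five model variants are supported: radiomics, signs, radiomics+signs,
clinical, and radiomics+clinical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import combat, elasticnet, evaluation, selection
from .cohort import CohortSpec, generate_cohort

CLINICAL_FACTORS = [
    "age", "gender", "onset_to_scan_h", "baseline_volume_ml",
    "antiplatelet", "ultra_early_growth",
]
SIGN_COLUMNS = ["blend_sign", "black_hole_sign", "hypodensities", "island_sign"]
VARIANTS = ("radiomics", "signs", "radiomics+signs", "clinical", "radiomics+clinical")
OUTCOMES = ("haematoma_expansion", "poor_outcome")

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {},
    "split": {"train_fraction": 0.7},
    "harmonisation": {"enabled": True, "covariates": ["age", "gender"],
                      "include_ultra_early_growth": True},
    "selection": {"cutoff": 0.9},
    "model": {"k": 10, "n_lambda": 100, "lambda_min_ratio": 1e-4,
              "alphas": [round(a, 1) for a in np.arange(0, 1.01, 0.1)]},
    "variants": ["radiomics"],
    "outcomes": list(OUTCOMES),
}


class PipelineError(RuntimeError):
    pass


def load_config(source) -> dict:
    if isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    bad = [v for v in cfg["variants"] if v not in VARIANTS]
    if bad:
        raise PipelineError(f"unknown variants {bad}; choose from {VARIANTS}")
    bad = [o for o in cfg["outcomes"] if o not in OUTCOMES]
    if bad:
        raise PipelineError(f"unknown outcomes {bad}; choose from {OUTCOMES}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _variant_matrix(variant, radiomics_tab, clinical):
    parts = []
    if "radiomics" in variant:
        parts.append(radiomics_tab)
        parts.append(clinical[["treatment"]])
    if variant in ("signs", "radiomics+signs"):
        parts.append(clinical[SIGN_COLUMNS])
    if variant in ("clinical", "radiomics+clinical"):
        parts.append(clinical[CLINICAL_FACTORS])
    x = pd.concat(parts, axis=1)
    return x.loc[:, ~x.columns.duplicated()]


def run_pipeline(config, output_dir=None) -> dict:
    """Run the full pipeline on a synthetic cohort; returns a results dict
    and (optionally) serialises every artefact under ``output_dir``."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    outdir = Path(output_dir or cfg.get("output_dir", "pipeline_run"))
    write = output_dir is not None or "output_dir" in cfg
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    cohort_kwargs = dict(cfg["cohort"])
    for key in ("batch_shift", "batch_scale", "batch_probs", "batch_thickness_mm"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = tuple(cohort_kwargs[key])
    spec = CohortSpec(seed=seed, **cohort_kwargs)
    features, clinical, outcomes = generate_cohort(spec)
    if write:
        features.to_csv(outdir / "features.csv")
        clinical.to_csv(outdir / "clinical.csv")
        outcomes.drop(columns=[], inplace=False).to_csv(outdir / "outcomes.csv")

    results: dict = {"config_hash": config_hash(cfg), "seed": seed, "outcomes": {}}
    needs_radiomics = any("radiomics" in v for v in cfg["variants"])

    for outcome in cfg["outcomes"]:
        y_all = outcomes[outcome]
        keep = y_all.notna()
        clin = clinical.loc[keep]
        feats = features.loc[keep]
        y = y_all.loc[keep].astype(float).astype(int)

        train_ids, test_ids = evaluation.matched_split(
            clin.assign(_y=y), train_fraction=cfg["split"]["train_fraction"],
            seed=seed, outcome_col="_y",
        )

        mixing = {}
        if needs_radiomics:
            harm_cols = list(feats.columns)
            tab = feats.copy()
            if cfg["harmonisation"].get("include_ultra_early_growth", True):
                tab["ultra_early_growth"] = clin["ultra_early_growth"]
                harm_cols.append("ultra_early_growth")
            if cfg["harmonisation"]["enabled"]:
                cov = clin[cfg["harmonisation"]["covariates"]]
                batches = clin["batch"]
                mixing["pre_train"] = combat.batch_mixing_score(
                    tab.loc[train_ids], batches.loc[train_ids]
                )
                model_cb, harm_train = combat.combat_fit(
                    tab.loc[train_ids], batches.loc[train_ids], cov.loc[train_ids]
                )
                harm_test = combat.combat_apply(
                    model_cb, tab.loc[test_ids], batches.loc[test_ids], cov.loc[test_ids]
                )
                mixing["post_train"] = combat.batch_mixing_score(
                    harm_train, batches.loc[train_ids]
                )
                if write:
                    model_cb.to_json(outdir / f"combat_{outcome}.json")
            else:
                harm_train, harm_test = tab.loc[train_ids], tab.loc[test_ids]
            retained = selection.correlation_filter(
                harm_train, cfg["selection"]["cutoff"]
            )
            rad_train = harm_train[retained]
            rad_test = harm_test[retained]
            if write:
                with open(outdir / f"retained_{outcome}.json", "w") as fh:
                    json.dump(retained, fh)
        else:
            rad_train = rad_test = None
            retained = []

        out_entry = {"n_train": len(train_ids), "n_test": len(test_ids),
                     "n_retained": len(retained), "mixing": mixing, "variants": {}}
        for variant in cfg["variants"]:
            x_train = _variant_matrix(variant, rad_train, clin.loc[train_ids])
            x_test = _variant_matrix(variant, rad_test, clin.loc[test_ids])
            grid = elasticnet.cv_grid_search(
                x_train, y.loc[train_ids].to_numpy(),
                alphas=cfg["model"]["alphas"], k=cfg["model"]["k"], seed=seed,
                n_lambda=cfg["model"]["n_lambda"],
                lambda_min_ratio=cfg["model"]["lambda_min_ratio"],
            )
            s_train = elasticnet.predict_probability(grid.model, x_train)
            s_test = elasticnet.predict_probability(grid.model, x_test)
            thr = evaluation.youden_threshold(s_train, y.loc[train_ids])
            rep_train = evaluation.metric_report(s_train, y.loc[train_ids], thr)
            rep_test = evaluation.metric_report(s_test, y.loc[test_ids], thr)
            ta = evaluation.threshold_analysis(s_train, y.loc[train_ids])
            ventry = {
                "alpha": grid.alpha, "lambda": grid.lam, "cv_auc": grid.cv_auc,
                "threshold": thr,
                "train": rep_train.to_dict(), "test": rep_test.to_dict(),
            }
            out_entry["variants"][variant] = ventry
            if write:
                tag = f"{outcome}_{variant.replace('+', '_')}"
                grid.model.to_json(outdir / f"model_{tag}.json")
                grid.per_alpha.to_csv(outdir / f"grid_{tag}.csv", index=False)
                ta.to_csv(outdir / f"threshold_analysis_{tag}.tsv", sep="\t", index=False)
                roc_pts, _, _ = evaluation.roc_auc(s_test, y.loc[test_ids])
                roc_pts.to_csv(outdir / f"roc_test_{tag}.tsv", sep="\t", index=False)
                with open(outdir / f"metrics_{tag}.json", "w") as fh:
                    json.dump(ventry, fh, indent=1)
        results["outcomes"][outcome] = out_entry

    if write:
        manifest = {
            "config": cfg, "config_hash": results["config_hash"], "seed": seed,
            "provenance": "harmonisation, feature selection, model selection and "
                          "threshold choice computed on training data only",
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(outdir / "results.json", "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True)
    return results
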