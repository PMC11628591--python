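"""End-to-end orchestration: generate → preprocess-check → split → train/CV
→ predict → quantify → evaluate → write reports.

Two execution profiles exist: ``full`` (384 px, ≥300 epochs, batch 26)
documents the full-scale settings; ``tiny`` (96 px, 20 epochs) runs the
whole pipeline end to end on one CPU in minutes and is the profile the test
suite exercises.  Every report is stamped with a configuration hash and the
seed; report files contain no timestamps, so identical runs produce
identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evalstats, quantify, segmodel, synthdata
from .annotations import split_experiments
from .preprocess import quality_report
from .segmodel import TrainConfig, collect_faces, maps_to_mask

logger = logging.getLogger("ttcseg")

__all__ = ["RunConfig", "run_all", "quantify_cohort"]


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    profile: str = "tiny"                 # "tiny" or "full"
    seed: int = 0
    phantom: synthdata.PhantomConfig | None = None
    train: TrainConfig | None = None
    n_test: int | None = None             # default: ~1/3 of experiments
    k: int = 3
    tolerance_px: float = 2.0
    out_dir: str | None = None

    def __post_init__(self):
        if self.profile not in ("tiny", "full"):
            raise ValueError("profile must be 'tiny' or 'full'")
        if self.phantom is None:
            size = 96 if self.profile == "tiny" else 384
            self.phantom = synthdata.PhantomConfig(
                n_experiments=24 if self.profile == "tiny" else 390,
                image_size=size, seed=self.seed)
        if self.train is None:
            self.train = (TrainConfig.tiny(seed=self.seed)
                          if self.profile == "tiny"
                          else TrainConfig(seed=self.seed))
        if self.n_test is None:
            self.n_test = (170 if self.profile == "full"
                           else max(1, self.phantom.n_experiments // 3))

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name))
                        for f in dataclasses.fields(o)
                        if f.name != "out_dir"}   # paths don't change science
            if isinstance(o, (tuple, list, np.ndarray)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs and isinstance(kwargs["phantom"], dict):
            ph = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in kwargs["phantom"].items()}
            kwargs["phantom"] = synthdata.PhantomConfig(**ph)
        if "train" in kwargs and isinstance(kwargs["train"], dict):
            tr = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in kwargs["train"].items()}
            kwargs["train"] = TrainConfig(**tr)
        return cls(**kwargs)


def quantify_cohort(experiments, predicted_masks=None) -> pd.DataFrame:
    """IS/AAR per experiment from annotations or from predicted masks.

    ``predicted_masks`` maps ``(experiment_id, slice_index, face)`` to a
    mask; when given, only experiments that have at least one predicted
    face are quantified.
    """
    rows = []
    for exp in experiments:
        if predicted_masks is None:
            masks = None
        else:
            masks = {(s, f): m for (e, s, f), m in predicted_masks.items()
                     if e == exp.experiment_id}
            if not masks:
                continue
        res = quantify.quantify_from_masks(exp, masks)
        rows.append({
            "experiment_id": exp.experiment_id, "group": exp.group,
            "is_pct_aar": res.is_pct_aar, "aar_pct_lv": res.aar_pct_lv,
            "total_infarct_g": res.total_infarct_g,
            "total_aar_g": res.total_aar_g, "total_lv_g": res.total_lv_g,
        })
    return pd.DataFrame(rows)


def _agreement_block(df: pd.DataFrame, col_a: str, col_b: str) -> dict:
    """Agreement panel for all data and per intervention subgroup."""
    out = {}
    for label, sub in [("all", df),
                       ("IR", df[df["group"] == "IR"]),
                       ("IR_protected", df[df["group"] == "IR_protected"])]:
        if len(sub) >= 4 and sub[col_a].nunique() > 1 and sub[col_b].nunique() > 1:
            out[label] = evalstats.agreement_report(
                sub[col_a].to_numpy(), sub[col_b].to_numpy()).to_dict()
        else:
            out[label] = {"n": int(len(sub)), "note": "insufficient data"}
    return out


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and return (and optionally write) the reports.

    The bundle holds per-experiment IS results for annotations, predictions
    and generator truth; the per-class metric table; agreement panels;
    the resize-quality report; and every fold's training history.
    """
    stamp = {"config_hash": config.config_hash(), "seed": config.seed,
             "profile": config.profile}
    logger.info("run_all start [%s]", stamp["config_hash"])

    logger.info("stage=generate n=%d", config.phantom.n_experiments)
    experiments, gt = synthdata.generate_cohort(config.phantom)
    by_id = {e.experiment_id: e for e in experiments}

    logger.info("stage=quality target=%dpx", config.train.image_size)
    images = [img for e in experiments for s in e.slices
              for _, img, _m in s.faces()]
    qr = quality_report(images[:40], config.train.image_size)

    logger.info("stage=split n_test=%d k=%d", config.n_test, config.k)
    cv_ids, test_ids = split_experiments(
        [e.experiment_id for e in experiments], config.n_test, config.seed)

    logger.info("stage=cross_validate")
    cv_exps = [by_id[i] for i in cv_ids]
    models, pooled_probs = segmodel.cross_validate(
        cv_exps, config.k, config.train,
        log=lambda h: logger.info("epoch=%(epoch)d loss=%(train_loss).4f "
                                  "val_dsc=%(val_dsc).4f", h))
    pooled_masks = {k: maps_to_mask(v) for k, v in pooled_probs.items()}

    logger.info("stage=predict_test")
    best = max(models, key=lambda m: max(h["val_dsc"] for h in m.history))
    test_probs = {}
    for key, img, _m in collect_faces([by_id[i] for i in test_ids],
                                      config.train.image_size):
        test_probs[key] = segmodel.predict(best, img)
    test_masks = {k: maps_to_mask(v) for k, v in test_probs.items()}

    logger.info("stage=quantify")
    is_ann = quantify_cohort(experiments)
    is_truth = pd.DataFrame([
        {"experiment_id": e.experiment_id, "group": e.group,
         "is_pct_aar": gt.is_pct_aar[e.experiment_id],
         "aar_pct_lv": gt.aar_pct_lv[e.experiment_id]}
        for e in experiments])
    is_pred_cv = quantify_cohort(cv_exps, pooled_masks)
    is_pred_test = quantify_cohort([by_id[i] for i in test_ids], test_masks)

    logger.info("stage=evaluate")
    eval_keys = sorted(pooled_masks)
    ann_at_size = {key: m for key, _i, m in collect_faces(
        cv_exps, config.train.image_size)}
    metrics = evalstats.metrics_report(
        [pooled_masks[k] for k in eval_keys],
        [ann_at_size[k] for k in eval_keys],
        prob_maps=[pooled_probs[k] for k in eval_keys],
        tolerance_px=config.tolerance_px)

    def merged(pred_df, ann_df):
        return pred_df.merge(ann_df, on=["experiment_id", "group"],
                             suffixes=("_pred", "_ann"))
    agree_cv = _agreement_block(merged(is_pred_cv, is_ann),
                                "is_pct_aar_pred", "is_pct_aar_ann")
    agree_test = _agreement_block(merged(is_pred_test, is_ann),
                                  "is_pct_aar_pred", "is_pct_aar_ann")
    agree_ann_truth = _agreement_block(
        is_ann.merge(is_truth, on=["experiment_id", "group"],
                     suffixes=("_ann", "_truth")),
        "is_pct_aar_ann", "is_pct_aar_truth")

    bundle = {
        "stamp": stamp,
        "split": {"cv_ids": cv_ids, "test_ids": test_ids, "k": config.k},
        "quality": qr.summary(),
        "metrics": {
            "per_class": metrics.per_class.round(6).to_dict(orient="index"),
            "overall": {"DSC": metrics.overall_dsc,
                        "ACC": metrics.weighted_acc,
                        "bF1": metrics.overall_bf1,
                        "AP": metrics.map},
        },
        "is_results": {
            "annotations": is_ann.to_dict(orient="records"),
            "truth": is_truth.to_dict(orient="records"),
            "predictions_cv": is_pred_cv.to_dict(orient="records"),
            "predictions_test": is_pred_test.to_dict(orient="records"),
        },
        "agreement": {"cv_pred_vs_ann": agree_cv,
                      "test_pred_vs_ann": agree_test,
                      "ann_vs_truth": agree_ann_truth},
        "training": {"best_epochs": [m.best_epoch for m in models],
                     "histories": [m.history for m in models]},
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as f:
            json.dump(bundle, f, indent=1, sort_keys=True, default=float)
        metrics.to_frame().to_csv(out / "metrics.csv")
        is_ann.to_csv(out / "is_annotations.csv", index=False)
        is_pred_cv.to_csv(out / "is_predictions_cv.csv", index=False)
        is_pred_test.to_csv(out / "is_predictions_test.csv", index=False)
        for i, m in enumerate(models):
            m.save(out / f"model_fold{i}.npz")
        logger.info("reports written to %s", out)
    return bundle
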