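"""End-to-end orchestration of the LFB attention-MIL analysis.

Two entry points:

* :func:`run_pipeline` executes the whole analysis in memory and returns a
  :class:`PipelineRun` with every intermediate object — what the tests and
  the acceptance script use;
* :func:`run_stage` executes named stages (``simulate``, ``label``,
  ``featurize``, ``split``, ``train``, ``evaluate``, ``interpret``,
  ``quantify``, ``associate``, ``report`` or ``all``) against a run
  directory, each stage idempotent under a config hash and resumable.

Every random draw flows from the seeds in :class:`~lfbmil.config.RunConfig`,
so a run is reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from . import interpret, mil, simulate, stain, stats, tiling
from .config import RunConfig
from .labels import label_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineRun", "run_pipeline", "run_stage", "STAGES"]

STAGES = ("simulate", "label", "featurize", "split", "train", "evaluate",
          "interpret", "quantify", "associate", "report")


@dataclass
class PipelineRun:
    """All artifacts of one in-memory pipeline execution."""

    config: RunConfig
    cohort: pd.DataFrame                       # labelled cohort incl. true_state
    bags: list[tiling.FeatureBag]
    labels: np.ndarray                         # 0/1 aligned with bags
    images: dict[str, np.ndarray]
    region_masks: dict[str, np.ndarray]
    true_densities: dict[str, np.ndarray]
    eval_result: mil.EvalResult
    models: list[mil.AttentionMILModel]
    split_plan: mil.SplitPlan
    p_ci: pd.Series                            # donor_id -> best-fold probability
    attention_maps: list[interpret.AttentionMap]
    region_summary: interpret.RegionAttentionSummary
    stain_slides: pd.DataFrame
    stain_tests: dict
    correlations: pd.DataFrame
    ci_tests: dict
    report: dict

    @property
    def best_model(self) -> mil.AttentionMILModel:
        return self.models[self.eval_result.best_fold]


def _simulate_cohort(config: RunConfig) -> tuple[pd.DataFrame, dict, dict, dict]:
    records = simulate.generate_cohort(config.sim)
    cohort = simulate.cohort_to_frame(records)
    cohort["true_state"] = [r.true_state for r in records]
    cohort = label_cohort(cohort, config.labels)
    images, masks, densities = {}, {}, {}
    for rec in records:
        slide = simulate.generate_slide(rec, config.sim, tile_size=config.tiling.tile_size)
        images[rec.donor_id] = slide.image
        masks[rec.donor_id] = slide.region_mask
        densities[rec.donor_id] = slide.true_tile_density
    return cohort, images, masks, densities


def _featurize(cohort: pd.DataFrame, images: dict, config: RunConfig,
               ) -> tuple[list[tiling.FeatureBag], np.ndarray]:
    usable = cohort[cohort["label"].isin(["CI", "NCI"])]
    bags, labels = [], []
    for _, row in usable.iterrows():
        bag = tiling.build_bag(images[row["donor_id"]], config.tiling,
                               donor_id=row["donor_id"])
        if bag is None:
            logger.warning("slide %s skipped: no tissue tiles", row["donor_id"])
            continue
        bags.append(bag)
        labels.append(1 if row["label"] == "CI" else 0)
    return bags, np.asarray(labels, dtype=int)


def _quantify(run_bags, amaps, images, config: RunConfig,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    ts = config.tiling.tile_size
    tile_rows, slide_rows = [], []
    for bag, amap in zip(run_bags, amaps):
        top = interpret.top_k_tiles(amap, k=config.top_k)
        image = images[bag.donor_id]
        counts = []
        for rank, idx in enumerate(top):
            _, _, x0, y0 = bag.coords[idx]
            c = stain.tile_counts(image[y0:y0 + ts, x0:x0 + ts],
                                  config.dark_band, config.light_band,
                                  donor_id=bag.donor_id, tile_index=int(idx))
            counts.append(c)
            tile_rows.append({"donor_id": bag.donor_id, "rank": rank,
                              "tile_row": int(bag.coords[idx][0]),
                              "tile_col": int(bag.coords[idx][1]),
                              "dark_count": c.dark_count,
                              "light_count": c.light_count,
                              "ratio": c.ratio})
        summary = stain.summarize_slide(counts, donor_id=bag.donor_id,
                                        zero_positive_rule=config.stats.zero_positive_rule)
        slide_rows.append({"donor_id": summary.donor_id,
                           "median_dark": summary.median_dark,
                           "median_ratio": summary.median_ratio,
                           "n_tiles_used": summary.n_tiles_used,
                           "n_tiles_dropped": summary.n_tiles_dropped})
    return pd.DataFrame(tile_rows), pd.DataFrame(slide_rows)


def _stain_group_tests(stain_slides: pd.DataFrame, groups: pd.Series) -> dict:
    out = {}
    merged = stain_slides.dropna(subset=["median_dark"]).copy()
    merged["group"] = merged["donor_id"].map(groups)
    for metric in ("median_dark", "median_ratio"):
        sub = merged.dropna(subset=[metric, "group"])
        a = sub.loc[sub["group"] == 1, metric]
        b = sub.loc[sub["group"] == 0, metric]
        if len(a) >= 2 and len(b) >= 2:
            out[metric] = stain.compare_groups(a, b)
        else:
            out[metric] = None
    return out


def _associate(cohort: pd.DataFrame, p_ci: pd.Series,
               stain_slides: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    df = cohort.set_index("donor_id").copy()
    df["p_ci"] = p_ci
    df["median_dark"] = stain_slides.set_index("donor_id")["median_dark"]
    df["label01"] = df["label"].map({"NCI": 0.0, "CI": 1.0})

    rows = []
    pairs = [("p_ci", "age"), ("p_ci", "braak"), ("p_ci", "artag"),
             ("p_ci", "cvd"), ("p_ci", "label01"),
             ("median_dark", "age"), ("median_dark", "braak"),
             ("median_dark", "artag"), ("median_dark", "cvd"),
             ("median_dark", "p_ci")]
    for a, b in pairs:
        rep = stats.spearman(df[a], df[b], names=(a, b))
        rows.append({"var_a": a, "var_b": b, "rho": rep.rho, "p": rep.p,
                     "n": rep.n, "method": "spearman"})
    correlations = pd.DataFrame(rows)

    sub = df.dropna(subset=["label01", "age", "median_dark"])
    ci_tests: dict = {}
    for name, (x, y, z) in {
        "label_age_given_dark": ("label01", "age", "median_dark"),
        "label_dark_given_age": ("label01", "median_dark", "age"),
    }.items():
        try:
            ci_tests[name] = dataclasses.asdict(stats.conditional_independence(
                sub[x], sub[y], sub[z], n_levels=config.stats.n_levels))
        except ValueError as exc:
            logger.warning("conditional-independence test %s skipped: %s", name, exc)
            ci_tests[name] = None
    return correlations, ci_tests


def run_pipeline(config: RunConfig) -> PipelineRun:
    """Execute the whole analysis in memory; deterministic under config seeds."""
    cohort, images, masks, densities = _simulate_cohort(config)
    bags, labels = _featurize(cohort, images, config)
    eval_result, models, plan = mil.run_cross_validation(
        bags, labels, config.mil, seed=config.seed)

    best = models[eval_result.best_fold]
    p_ci = pd.Series({b.donor_id: mil.predict_slide(b, best) for b in bags},
                     name="p_ci")
    amaps = []
    for bag in bags:
        attn, _ = mil.attention_pool(bag, best)
        amaps.append(interpret.AttentionMap(
            donor_id=bag.donor_id, attention=attn, coords=bag.coords,
            tile_size=config.tiling.tile_size))
    region_summary = interpret.region_attention(
        amaps, [masks[b.donor_id] for b in bags])

    _, stain_slides = _quantify(bags, amaps, images, config)
    predicted = (p_ci >= 0.5).astype(int)
    labeled = pd.Series(labels, index=[b.donor_id for b in bags])
    stain_tests = {"predicted": _stain_group_tests(stain_slides, predicted),
                   "labeled": _stain_group_tests(stain_slides, labeled)}

    correlations, ci_tests = _associate(cohort, p_ci, stain_slides, config)

    report = {
        "n_donors": int(len(cohort)),
        "n_slides_used": len(bags),
        "fold_auc": eval_result.fold_auc,
        "mean_auc": eval_result.mean_auc,
        "mean_balanced_accuracy": eval_result.mean_balanced_accuracy,
        "wilcoxon_auc_p": eval_result.wilcoxon_auc["p"],
        "wilcoxon_bacc_p": eval_result.wilcoxon_balanced_accuracy["p"],
        "best_fold": eval_result.best_fold,
        "wm_median_z": float(np.median(region_summary.wm_median)),
        "gm_median_z": float(np.median(region_summary.gm_median)),
        "region_paired_t": region_summary.t_statistic,
        "region_paired_p": region_summary.p_value,
        "stain_tests": stain_tests,
        "correlations": correlations.to_dict(orient="records"),
        "ci_tests": ci_tests,
        "config": config.to_dict(),
    }
    return PipelineRun(
        config=config, cohort=cohort, bags=bags, labels=labels, images=images,
        region_masks=masks, true_densities=densities, eval_result=eval_result,
        models=models, split_plan=plan, p_ci=p_ci, attention_maps=amaps,
        region_summary=region_summary, stain_slides=stain_slides,
        stain_tests=stain_tests, correlations=correlations, ci_tests=ci_tests,
        report=report,
    )


# ---------------------------------------------------------------------------
# Disk-backed staged execution


class StageError(RuntimeError):
    """An upstream artifact is missing; the message names the stage to run."""


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _marker(outdir: Path, stage: str) -> Path:
    return outdir / f".{stage}.done.json"


def _is_done(outdir: Path, stage: str, config: RunConfig) -> bool:
    marker = _marker(outdir, stage)
    if not marker.exists():
        return False
    return json.loads(marker.read_text()).get("config_hash") == _config_hash(config)


def _mark_done(outdir: Path, stage: str, config: RunConfig) -> None:
    _marker(outdir, stage).write_text(json.dumps(
        {"stage": stage, "config_hash": _config_hash(config)}))


def _require(outdir: Path, relpath: str, producing_stage: str) -> Path:
    path = outdir / relpath
    if not path.exists():
        raise StageError(
            f"missing artifact {relpath!r}; run stage {producing_stage!r} first")
    return path


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    (outdir / "slides").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    records = simulate.generate_cohort(config.sim)
    frame = simulate.cohort_to_frame(records, slide_dir=str(outdir / "slides"))
    frame["true_state"] = [r.true_state for r in records]
    frame.to_csv(outdir / "cohort.csv", index=False)
    density_frames = []
    for rec in records:
        slide = simulate.generate_slide(rec, config.sim,
                                        tile_size=config.tiling.tile_size)
        simulate.write_slide(slide, outdir / "slides" / f"{rec.donor_id}.png",
                             mask_path=outdir / "masks" / f"{rec.donor_id}.png")
        rows, cols = slide.true_tile_density.shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        density_frames.append(pd.DataFrame({
            "donor_id": rec.donor_id, "tile_row": rr.ravel(),
            "tile_col": cc.ravel(),
            "true_tile_density": slide.true_tile_density.ravel()}))
    pd.concat(density_frames).to_csv(outdir / "true_densities.csv", index=False)


def _stage_label(config: RunConfig, outdir: Path) -> None:
    cohort = pd.read_csv(_require(outdir, "cohort.csv", "simulate"))
    label_cohort(cohort, config.labels).to_csv(outdir / "cohort_labeled.csv", index=False)


def _load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def _stage_featurize(config: RunConfig, outdir: Path) -> None:
    cohort = pd.read_csv(_require(outdir, "cohort_labeled.csv", "label"))
    bags = []
    for _, row in cohort[cohort["label"].isin(["CI", "NCI"])].iterrows():
        image = _load_image(_require(outdir, f"slides/{row['donor_id']}.png", "simulate"))
        bag = tiling.build_bag(image, config.tiling, donor_id=row["donor_id"])
        if bag is not None:
            bags.append(bag)
    tiling.save_bags(bags, outdir / "bags.h5")


def _bags_and_labels(config: RunConfig, outdir: Path):
    bags = tiling.load_bags(_require(outdir, "bags.h5", "featurize"))
    cohort = pd.read_csv(_require(outdir, "cohort_labeled.csv", "label"))
    lab = cohort.set_index("donor_id")["label"].map({"CI": 1, "NCI": 0})
    labels = np.array([lab[b.donor_id] for b in bags], dtype=int)
    return bags, labels, cohort


def _stage_split(config: RunConfig, outdir: Path) -> None:
    bags, labels, _ = _bags_and_labels(config, outdir)
    plan = mil.make_splits([b.donor_id for b in bags], labels,
                           n_folds=config.mil.n_folds,
                           fractions=config.mil.fractions, seed=config.seed)
    (outdir / "splits.json").write_text(json.dumps(
        {"seed": plan.seed, "folds": plan.folds}, indent=2))


def _stage_train(config: RunConfig, outdir: Path) -> None:
    bags, labels, _ = _bags_and_labels(config, outdir)
    plan_raw = json.loads(_require(outdir, "splits.json", "split").read_text())
    plan = mil.SplitPlan(folds=plan_raw["folds"], seed=plan_raw["seed"])
    (outdir / "models").mkdir(exist_ok=True)
    for fold_no, idx in enumerate(plan.indices([b.donor_id for b in bags])):
        model = mil.train(bags, labels, idx["train"], idx["val"], config.mil,
                          seed=config.seed * 1000 + fold_no)
        model.save(outdir / "models" / f"fold_{fold_no}")


def _load_models(config: RunConfig, outdir: Path) -> list[mil.AttentionMILModel]:
    models = []
    for fold_no in range(config.mil.n_folds):
        _require(outdir, f"models/fold_{fold_no}.npz", "train")
        models.append(mil.AttentionMILModel.load(outdir / "models" / f"fold_{fold_no}"))
    return models


def _stage_evaluate(config: RunConfig, outdir: Path) -> None:
    bags, labels, cohort = _bags_and_labels(config, outdir)
    plan_raw = json.loads(_require(outdir, "splits.json", "split").read_text())
    plan = mil.SplitPlan(folds=plan_raw["folds"], seed=plan_raw["seed"])
    models = _load_models(config, outdir)
    fold_evals = []
    for model, idx in zip(models, plan.indices([b.donor_id for b in bags])):
        fold_evals.append(mil.evaluate(model, [bags[i] for i in idx["test"]],
                                       labels[idx["test"]]))
    result = mil.aggregate_folds(fold_evals)
    (outdir / "eval.json").write_text(json.dumps(result.to_dict(), indent=2))
    best = models[result.best_fold]
    p_ci = {b.donor_id: mil.predict_slide(b, best) for b in bags}
    scored = cohort.copy()
    scored["p_ci"] = scored["donor_id"].map(p_ci)
    scored.to_csv(outdir / "cohort_scored.csv", index=False)


def _attention_maps(config: RunConfig, outdir: Path):
    bags, _, _ = _bags_and_labels(config, outdir)
    result = json.loads(_require(outdir, "eval.json", "evaluate").read_text())
    best = mil.AttentionMILModel.load(outdir / "models" / f"fold_{result['best_fold']}")
    amaps = []
    for bag in bags:
        attn, _ = mil.attention_pool(bag, best)
        amaps.append(interpret.AttentionMap(
            donor_id=bag.donor_id, attention=attn, coords=bag.coords,
            tile_size=config.tiling.tile_size))
    return bags, amaps


def _stage_interpret(config: RunConfig, outdir: Path) -> None:
    bags, amaps = _attention_maps(config, outdir)
    rows = []
    for amap in amaps:
        z = amap.z_scores
        for i, (row, col, _, _) in enumerate(amap.coords):
            rows.append({"donor_id": amap.donor_id, "tile_row": int(row),
                         "tile_col": int(col),
                         "attention": float(amap.attention[i]),
                         "z_score": float(z[i])})
    pd.DataFrame(rows).to_csv(outdir / "attention.csv", index=False)

    masks = [np.asarray(Image.open(
        _require(outdir, f"masks/{b.donor_id}.png", "simulate")))
        for b in bags]
    summary = interpret.region_attention(amaps, masks)
    (outdir / "region_attention.json").write_text(json.dumps({
        "slide_ids": summary.slide_ids,
        "wm_median": summary.wm_median.tolist(),
        "gm_median": summary.gm_median.tolist(),
        "t": summary.t_statistic, "p": summary.p_value,
        "n_excluded": summary.n_excluded}, indent=2))

    (outdir / "heatmaps").mkdir(exist_ok=True)
    for bag, amap in list(zip(bags, amaps))[:2]:
        image = _load_image(outdir / "slides" / f"{bag.donor_id}.png")
        overlay = interpret.render_heatmap(amap, image)["overlay"]
        Image.fromarray(overlay).save(outdir / "heatmaps" / f"{bag.donor_id}.png")


def _stage_quantify(config: RunConfig, outdir: Path) -> None:
    bags, amaps = _attention_maps(config, outdir)
    images = {b.donor_id: _load_image(outdir / "slides" / f"{b.donor_id}.png")
              for b in bags}
    tile_df, slide_df = _quantify(bags, amaps, images, config)
    tile_df.to_csv(outdir / "stain_tiles.csv", index=False)
    slide_df.to_csv(outdir / "stain_slides.csv", index=False)

    scored = pd.read_csv(_require(outdir, "cohort_scored.csv", "evaluate"))
    p_ci = scored.set_index("donor_id")["p_ci"].dropna()
    predicted = (p_ci >= 0.5).astype(int)
    labeled = scored.set_index("donor_id")["label"].map({"CI": 1, "NCI": 0})
    tests = {"predicted": _stain_group_tests(slide_df, predicted),
             "labeled": _stain_group_tests(slide_df, labeled)}
    (outdir / "stain_tests.json").write_text(json.dumps(tests, indent=2))

    merged = slide_df.dropna(subset=["median_dark", "median_ratio"])
    if len(merged) >= 5:
        kde = stain.kde2d(merged[["median_dark", "median_ratio"]].to_numpy())
        pd.DataFrame(kde["density"], index=kde["x"], columns=kde["y"]).to_csv(
            outdir / "stain_kde.csv")
        geojson = {"type": "FeatureCollection", "features": [
            {"type": "Feature",
             "properties": {"level": c["level"]},
             "geometry": {"type": "LineString",
                          "coordinates": c["vertices"].tolist()}}
            for c in kde["contours"]]}
        (outdir / "stain_kde_contours.geojson").write_text(json.dumps(geojson))


def _stage_associate(config: RunConfig, outdir: Path) -> None:
    scored = pd.read_csv(_require(outdir, "cohort_scored.csv", "evaluate"))
    slide_df = pd.read_csv(_require(outdir, "stain_slides.csv", "quantify"))
    p_ci = scored.set_index("donor_id")["p_ci"]
    correlations, ci_tests = _associate(scored, p_ci, slide_df, config)
    correlations.to_csv(outdir / "correlations.csv", index=False)
    (outdir / "ci_tests.json").write_text(json.dumps(ci_tests, indent=2))


def _stage_report(config: RunConfig, outdir: Path) -> None:
    result = json.loads(_require(outdir, "eval.json", "evaluate").read_text())
    region = json.loads(_require(outdir, "region_attention.json", "interpret").read_text())
    tests = json.loads(_require(outdir, "stain_tests.json", "quantify").read_text())
    correlations = pd.read_csv(_require(outdir, "correlations.csv", "associate"))
    ci_tests = json.loads(_require(outdir, "ci_tests.json", "associate").read_text())
    summary = {
        "mean_auc": result["mean_auc"],
        "fold_auc": result["fold_auc"],
        "mean_balanced_accuracy": result["mean_balanced_accuracy"],
        "wilcoxon_auc": result["wilcoxon_auc"],
        "best_fold": result["best_fold"],
        "wm_median_z": float(np.median(region["wm_median"])),
        "gm_median_z": float(np.median(region["gm_median"])),
        "region_paired_t": region["t"], "region_paired_p": region["p"],
        "stain_tests": tests,
        "correlations": correlations.to_dict(orient="records"),
        "ci_tests": ci_tests,
        "config": config.to_dict(),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    lines = [
        "# Run summary", "",
        f"- mean test AUC: {summary['mean_auc']:.3f} "
        f"(Wilcoxon vs 0.5: p = {summary['wilcoxon_auc']['p']:.2e})",
        f"- mean balanced accuracy: {summary['mean_balanced_accuracy']:.3f}",
        f"- median WM attention z: {summary['wm_median_z']:.2f}; "
        f"GM: {summary['gm_median_z']:.2f} (paired t p = {summary['region_paired_p']:.2e})",
        "", "## Correlations", "",
        correlations.to_string(index=False),
    ]
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate, "label": _stage_label,
    "featurize": _stage_featurize, "split": _stage_split,
    "train": _stage_train, "evaluate": _stage_evaluate,
    "interpret": _stage_interpret, "quantify": _stage_quantify,
    "associate": _stage_associate, "report": _stage_report,
}


def run_stage(stage: str, config: RunConfig, outdir: Optional[str | Path] = None,
              force: bool = False) -> Path:
    """Run one pipeline stage (or ``all``) against a run directory.

    A completed stage whose config hash matches is skipped (no-op) unless
    ``force`` is given.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    names = list(STAGES) if stage == "all" else [stage]
    for name in names:
        if name not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
        if not force and _is_done(outdir, name, config):
            logger.info("stage %s already complete; skipping", name)
            continue
        logger.info("running stage %s", name)
        _STAGE_FUNCS[name](config, outdir)
        _mark_done(outdir, name, config)
    return outdir
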