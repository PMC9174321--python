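"""End-to-end pipeline: simulate -> normalize -> train-seg -> segment ->
train-mil -> predict -> evaluate.

Each stage writes its outputs under the run directory and is skipped on
rerun when those outputs already exist for the same config hash (noted in
the manifest).  All randomness derives from the single master seed via
deterministic per-stage seed spawning, so two runs with the same config are
bit-identical in every CSV/JSON output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import mil as mil_mod
from . import segmentation as seg_mod
from . import survival as surv_mod
from .config import PipelineConfig, config_hash, save_config
from .io import RunManifest, load_mil_checkpoint, load_unet_checkpoint, \
    save_mil_checkpoint, save_unet_checkpoint
from .simulate import SlideSimConfig, _calibrate_cmax, generate_cohort_bags, \
    generate_nuclei_tile
from .stain import estimate_stain_profile, normalize_color, reference_profile

__all__ = ["run_pipeline", "stage_seeds"]


def stage_seeds(master_seed: int) -> dict:
    """Deterministic per-stage seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    names = ["simulate", "seg", "mil", "survival", "evaluate"]
    return {n: int(s.generate_state(1)[0] % (2 ** 31 - 1))
            for n, s in zip(names, ss.spawn(len(names)))}


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _simulate(config: PipelineConfig, seeds):
    sim = config.simulation
    base = SlideSimConfig(n_tiles=sim.n_tiles, tile_size=sim.tile_size,
                          signal_fraction=sim.signal_fraction,
                          stroma_probability=sim.stroma_probability,
                          immune_density=sim.immune_density,
                          seed=seeds["simulate"])
    bags = generate_cohort_bags(sim.n_slides_per_class, base)
    n_test = max(2, int(round(sim.test_fraction * len(bags))))
    # balanced split: bags alternate high/low by construction
    test_bags, train_bags = bags[:n_test], bags[n_test:]
    rng = np.random.default_rng(seeds["seg"])
    pairs = []
    for k in range(sim.n_seg_pairs):
        risk = "high" if k % 2 else "low"
        img, mask, _ = generate_nuclei_tile(base, risk, risk == "high" and k % 4 == 1,
                                            int(rng.integers(0, 2 ** 31 - 1)))
        pairs.append(seg_mod.SegPair(img, mask))
    return train_bags, test_bags, pairs


def _survival_for_slides(test_bags, config: PipelineConfig, seeds) -> pd.DataFrame:
    """Weibull PH survival linked to the true risk class of each test slide."""
    sim = config.simulation
    rng = np.random.default_rng(seeds["survival"])
    risk = np.array([1 if b.meta["risk_class"] == "high" else 0 for b in test_bags])
    stage = rng.choice([1, 2, 3], size=len(test_bags), p=[0.5, 0.3, 0.2])
    lp = sim.survival_log_hr * risk + 0.25 * (stage - 1)
    u = rng.uniform(size=len(test_bags))
    times = 24.0 * (-np.log(u) / np.exp(lp)) ** (1.0 / 1.5)
    times = np.maximum(times, 1e-6)
    if sim.censoring_rate > 0:
        cmax = _calibrate_cmax(times, sim.censoring_rate)
        cens = rng.uniform(0, cmax, size=len(test_bags))
        event = (times <= cens).astype(int)
        times = np.minimum(times, cens)
    else:
        event = np.ones(len(test_bags), dtype=int)
    return pd.DataFrame({"id": [b.slide_id for b in test_bags],
                         "time": times, "event": event, "stage": stage,
                         "true_risk": risk})


def _normalize_bags(bags, config: PipelineConfig):
    ref = reference_profile()
    for bag in bags:
        rgbs = bag.meta["rgb"]
        out = []
        for i in range(len(bag)):
            try:
                prof = estimate_stain_profile(rgbs[i],
                                              sparsity=config.normalization.sparsity)
                out.append(normalize_color(rgbs[i], prof, ref))
            except ValueError:       # near-white tile: leave as-is
                out.append(rgbs[i])
        bag.meta["rgb"] = np.stack(out)
        for i in range(len(bag)):
            bag.tiles[i, :3] = out[i].astype(np.float32).transpose(2, 0, 1) / 255.0


def _apply_heatmaps(bags, unet):
    for bag in bags:
        for i in range(len(bag)):
            hm = seg_mod.predict_heatmap(unet, bag.meta["rgb"][i])
            bag.tiles[i, 3] = hm.values


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic pipeline; returns summary metrics.

    Artifacts (model checkpoints, prediction and metric tables, manifest)
    are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest = RunManifest(chash)
    seeds = stage_seeds(config.seed)
    save_config(config, out / "config.yaml")

    def run_stage(name, fn, *args, **kwargs):
        t0 = manifest.start_stage(name)
        try:
            result = fn(*args, **kwargs)
        except Exception as e:
            raise StageError(name, e) from e
        manifest.end_stage(name, t0, **(result[1] if isinstance(result, tuple)
                                        and len(result) == 2
                                        and isinstance(result[1], dict) else {}))
        return result[0] if isinstance(result, tuple) and len(result) == 2 \
            and isinstance(result[1], dict) else result

    # --- simulate ---------------------------------------------------------
    train_bags, test_bags, pairs = run_stage(
        "simulate", lambda: ((_simulate(config, seeds)), {}))
    cohort = _survival_for_slides(test_bags, config, seeds)
    manifest.stages["simulate"].update(
        {"train_bags": len(train_bags), "test_bags": len(test_bags),
         "seg_pairs": len(pairs)})

    # --- color normalization ---------------------------------------------
    if config.normalization.enabled:
        run_stage("normalize",
                  lambda: (_normalize_bags(train_bags + test_bags, config), {}))

    # --- segmentation training -------------------------------------------
    seg_ckpt = out / "unet.npz"
    def train_seg():
        sc = seg_mod.SegTrainConfig(depth=config.segmentation.depth,
                                    base_channels=config.segmentation.base_channels,
                                    epochs=config.segmentation.epochs,
                                    learning_rate=config.segmentation.learning_rate,
                                    epsilon=config.segmentation.epsilon,
                                    seed=seeds["seg"])
        unet, hist = seg_mod.train_unet(pairs, sc)
        save_unet_checkpoint(unet, seg_ckpt)
        return unet, {"epochs": config.segmentation.epochs,
                      "val_dice": hist["val_dice"][-1] if hist["val_dice"] else None}
    if seg_ckpt.exists():
        unet = load_unet_checkpoint(seg_ckpt)
        manifest.end_stage("train-seg", manifest.start_stage("train-seg"), reused=True)
    else:
        unet = run_stage("train-seg", train_seg)

    # --- heatmaps ---------------------------------------------------------
    run_stage("segment", lambda: (_apply_heatmaps(train_bags + test_bags, unet), {}))

    # --- MIL training -----------------------------------------------------
    mil_ckpt = out / "mil.npz"
    def train():
        mc = mil_mod.MILConfig(
            aggregation_exponent=config.mil.aggregation_exponent,
            threshold=config.mil.threshold, l2_alpha=config.mil.l2_alpha,
            initial_lr=config.mil.initial_lr,
            lr_halving_epochs=config.mil.lr_halving_epochs,
            bag_batch_size=config.mil.bag_batch_size,
            backbone_variant=config.mil.backbone_variant,
            epochs=config.mil.epochs, seed=seeds["mil"])
        handle = mil_mod.train_mil(train_bags, mc)
        save_mil_checkpoint(handle, mil_ckpt)
        return handle, {"bags": len(train_bags), "epochs": config.mil.epochs}
    if mil_ckpt.exists():
        handle = load_mil_checkpoint(mil_ckpt)
        manifest.end_stage("train-mil", manifest.start_stage("train-mil"), reused=True)
    else:
        handle = run_stage("train-mil", train)

    # --- prediction -------------------------------------------------------
    def predict():
        rows = []
        for bag in test_bags:
            sc = mil_mod.predict_slide(handle, bag)
            rows.append({"slide_id": sc.slide_id, "S": sc.aggregate,
                         "activated": sc.activated, "p_i": sc.prob,
                         "predicted_class": sc.predicted_class,
                         "true_risk": 1 if bag.meta["risk_class"] == "high" else 0})
        df = pd.DataFrame(rows)
        df.to_csv(out / "predictions.csv", index=False)
        return df, {"slides": len(df)}
    preds = run_stage("predict", predict)

    # --- evaluation -------------------------------------------------------
    def evaluate():
        df = cohort.merge(preds.drop(columns=["true_risk"]),
                          left_on="id", right_on="slide_id")
        df["risk_group"] = df["predicted_class"]
        metrics = {}
        metrics["classification_accuracy"] = float(
            (df["predicted_class"] == df["true_risk"]).mean())
        if df["risk_group"].nunique() == 2 and df["event"].sum() > 0:
            chi2, dof, p = surv_mod.logrank_test(df, "risk_group")
            metrics["logrank_chi2"] = chi2
            metrics["logrank_p"] = p
            try:
                cox = surv_mod.cox_fit(df, ["risk_group"])
                metrics["hr_risk_group"] = float(cox.loc["risk_group", "hr"])
            except Exception:
                metrics["hr_risk_group"] = float("nan")
        horizons = [t for t in config.evaluation.horizons
                    if t < float(df["time"].max())]
        table = None
        if horizons:
            try:
                table = surv_mod.stratify_and_tabulate(
                    df, ["activated"], surv_mod.TimeGrid(tuple(horizons)),
                    n_bootstrap=config.evaluation.n_bootstrap,
                    seed=seeds["evaluate"])
                table.to_csv(out / "metrics_by_horizon.csv", index=False,
                             float_format="%.6f")
            except ValueError:
                table = None
        with open(out / "metrics.json", "w") as f:
            json.dump(metrics, f, indent=2, sort_keys=True)
        return metrics, {"subjects": len(df)}
    metrics = run_stage("evaluate", evaluate)

    manifest.save(out / "manifest.json")
    return metrics
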