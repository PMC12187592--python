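"""Reproducible scaled-down study: active learning on synthetic tongues.

Runs the full loop on a seeded synthetic cohort (200 training + 50 test
images by default) for the hybrid instance-level query strategy and any
baselines, and summarizes the label-budget/accuracy curve, the accuracy
at the 50%-labeled checkpoint, the final accuracy, and the weak
localization hit rate on test positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .active import run_wsmial
from .config import WSMIALConfig
from .data import DataPools
from .evaluation import iou, top_detections
from .features import descriptor_batch
from .proposals import AnchorSet, build_grid
from .synthetic import SyntheticSpec, generate_dataset, split_pools


@dataclass
class StudyRun:
    """One strategy's trajectory on one seed."""

    seed: int
    strategy: str
    curve: list[tuple[int, float]]          # (labels trained on, accuracy)
    final_accuracy: float
    final_recall: float
    checkpoint_accuracy: dict[int, float]   # label budget -> accuracy
    localization_hits: int
    localization_total: int
    pools: DataPools = field(repr=False, default=None)
    model: object = field(repr=False, default=None)
    state: object = field(repr=False, default=None)


def accuracy_curve(state) -> list[tuple[int, float]]:
    """(labels trained on, test accuracy) for every evaluated supervised
    fit along a run, including pre-train and the closing fit."""
    pts = []
    for rec in state.history:
        if "pool_sizes_at_eval" in rec:
            pts.append((rec["pool_sizes_at_eval"]["labeled"],
                        rec["test_metrics"]["accuracy"]))
        elif rec.get("phase") in ("pretrain", "final"):
            pts.append((rec["pool_sizes"]["labeled"],
                        rec["test_metrics"]["accuracy"]))
    return pts


def localization_rate(model, pools: DataPools,
                      config: WSMIALConfig) -> tuple[int, int]:
    """(hits, total): test positives whose single top-scored proposal
    overlaps a ground-truth notch box (IoU > 0)."""
    grid = build_grid(config.image_size, config.downsample,
                      AnchorSet.preset(config.anchors))
    positives = [s for s in pools.test.values()
                 if s.y == 1 and s.gt_boxes]
    if not positives:
        return 0, 0
    bundles = model.score_bundles(descriptor_batch(positives, grid))
    hits = 0
    for sample, bundle in zip(positives, bundles):
        top = top_detections(bundle, 1)[0]
        box = tuple(int(v) for v in grid.proposals[top])
        if any(iou(box, g) > 0 for g in sample.gt_boxes):
            hits += 1
    return hits, len(positives)


def run_study_arm(seed: int, strategy: str, n_train: int = 200,
                  n_test: int = 50, A: int = 5, K: int = 20,
                  initial_labeled_frac: float = 0.2,
                  checkpoint_budgets: tuple[int, ...] = (100,),
                  **config_overrides) -> StudyRun:
    """One seed x strategy arm of the scaled-down study."""
    spec = SyntheticSpec(seed=seed)
    samples = generate_dataset(spec, n_train + n_test)
    pools = split_pools(samples, n_test, initial_labeled_frac, seed)
    config = replace(WSMIALConfig(), A=A, K=K, seed=seed,
                     n_restarts=3, **config_overrides)
    state, model = run_wsmial(config, pools, query_strategy=strategy)
    curve = accuracy_curve(state)
    checkpoints = {}
    for budget in checkpoint_budgets:
        at = [acc for n, acc in curve if n == budget]
        if at:
            checkpoints[budget] = at[0]
    hits, total = localization_rate(model, pools, config)
    final = state.history[-1]["test_metrics"]
    return StudyRun(seed=seed, strategy=strategy, curve=curve,
                    final_accuracy=final["accuracy"],
                    final_recall=final["recall"],
                    checkpoint_accuracy=checkpoints,
                    localization_hits=hits, localization_total=total,
                    pools=pools, model=model, state=state)


def run_study(seeds, strategies=("hybrid", "random"),
              **kwargs) -> dict[str, list[StudyRun]]:
    """The full comparison: every strategy on every seed."""
    return {strategy: [run_study_arm(seed, strategy, **kwargs)
                       for seed in seeds]
            for strategy in strategies}


def summarize(study: dict[str, list[StudyRun]],
              checkpoint_budget: int = 100) -> dict:
    """Mean final accuracy, checkpoint accuracy, and localization rate."""
    out = {}
    for strategy, runs in study.items():
        finals = [r.final_accuracy for r in runs]
        cps = [r.checkpoint_accuracy.get(checkpoint_budget) for r in runs]
        cps = [c for c in cps if c is not None]
        hits = sum(r.localization_hits for r in runs)
        total = sum(r.localization_total for r in runs)
        out[strategy] = {
            "final_accuracy_mean": float(np.mean(finals)),
            "final_accuracy_per_seed": finals,
            "checkpoint_accuracy_mean": float(np.mean(cps)) if cps else None,
            "checkpoint_accuracy_per_seed": cps,
            "final_recall_mean": float(np.mean([r.final_recall
                                                for r in runs])),
            "localization_hits": hits,
            "localization_total": total,
            "localization_rate": hits / total if total else None,
        }
    return out
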