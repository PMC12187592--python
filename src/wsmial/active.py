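"""Active-learning orchestration: informativeness, expert querying,
pseudo-labeling with threshold decay, baselines, and the full loop.

Each round: fine-tune on labeled + pseudo-labeled images, return all
pseudo-labels to the unlabeled pool, run the uncertainty sub-phase
(feature extractor frozen, classifiers ascend discrepancy) and the
representative sub-phase (classifiers frozen, feature extractor and
critic trained), score every unlabeled image's informativeness — the mean
reweighted discrepancy of its top instances after the uncertainty /
representativeness double ranking — query the expert oracle for the K
most informative images, pseudo-label the images whose informativeness
falls strictly below the decaying threshold delta, decay delta, and log
test metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .config import WSMIALConfig
from .data import DataPools
from .evaluation import confusion_and_metrics
from .features import DESCRIPTOR_DIM, descriptor_batch, region_descriptors
from .model import ScoreBundle, UncertaintyRecord, fit_ensemble
from .proposals import AnchorSet, build_grid
from .utils import seed_stream

BASELINE_STRATEGIES = ("random", "least_confidence", "entropy",
                       "kmeans_diversity")
QUERY_STRATEGIES = ("hybrid",) + BASELINE_STRATEGIES


@dataclass
class ALState:
    """Round counter, current threshold, and per-round history records."""

    a: int = 0
    delta: float = 0.01
    history: list[dict] = field(default_factory=list)


# --------------------------------------------------------------------- #
# informativeness                                                       #
# --------------------------------------------------------------------- #
def image_informativeness(bundle: ScoreBundle, record: UncertaintyRecord,
                          r_n: int) -> float:
    """Double-ranked instance selection -> image informativeness scalar.

    Rank instances by reweighted discrepancy ``w_r * u_r`` and keep the top
    ``2 * r_n``; among those keep the ``r_n`` most representative (highest
    critic score, i.e. closest to the labeled-pool distribution); return
    the mean reweighted discrepancy of the kept instances. Ties break by
    instance index. If fewer than ``2 * r_n`` instances exist, all are used.
    """
    rew = np.abs(record.w_r) * record.u_r
    R = rew.shape[0]
    if R <= 2 * r_n:
        cand = np.arange(R)
    else:
        # stable sort descending with index tie-break
        cand = np.lexsort((np.arange(R), -rew))[: 2 * r_n]
    if cand.shape[0] <= r_n:
        keep = cand
    else:
        repr_score = bundle.critic[cand]
        order = np.lexsort((cand, -repr_score))[:r_n]
        keep = cand[order]
    return float(rew[keep].mean())


# --------------------------------------------------------------------- #
# pool transitions                                                      #
# --------------------------------------------------------------------- #
def expert_query(pools: DataPools, scores: dict[str, float],
                 K: int) -> list[str]:
    """Move the top-K most informative unlabeled images to D_l with their
    true labels revealed by the (simulated) expert. Ties break by id."""
    if not pools.unlabeled:
        return []
    ids = sorted(pools.unlabeled, key=lambda i: (-scores[i], i))
    chosen = ids[:min(K, len(ids))]
    for sid in chosen:
        pools.move_to_labeled(sid)
    pools.check_invariants()
    return chosen


def pseudo_label(pools: DataPools, informativeness: dict[str, float],
                 image_scores: dict[str, np.ndarray], delta: float,
                 round_a: int) -> list[tuple[str, int]]:
    """Pseudo-label every unlabeled image whose informativeness is strictly
    below delta with the argmax of its image-level class score."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    assigned = []
    for sid in sorted(pools.unlabeled):
        if informativeness[sid] < delta:
            label = int(np.argmax(image_scores[sid]))
            assigned.append((sid, label))
    for sid, label in assigned:
        pools.move_to_pseudo(sid, label, round_a)
    pools.check_invariants()
    return assigned


def decay_threshold(state: ALState, delta0: float, dr: float) -> ALState:
    """Linear threshold decay, floored at zero: delta_a = max(0, delta0 - dr*a)."""
    if state.a < 0:
        raise ValueError("round counter must be >= 0")
    state.delta = delta0 if state.a == 0 else max(0.0, delta0 - dr * state.a)
    return state


def reset_pseudo_labels(pools: DataPools) -> DataPools:
    """Return every pseudo-labeled sample to D_u with its label stripped;
    pseudo-labels are re-earned each round."""
    for sid in list(pools.pseudo):
        pools.return_pseudo_to_unlabeled(sid)
    pools.check_invariants()
    return pools


# --------------------------------------------------------------------- #
# baseline query strategies                                             #
# --------------------------------------------------------------------- #
def baseline_query(strategy: str, pools: DataPools,
                   image_scores: dict[str, np.ndarray], K: int,
                   rng: np.random.Generator | None = None) -> list[str]:
    """Classic query strategies on image-level class scores, with the same
    pool mechanics as `expert_query`. Ties break by id."""
    if strategy not in BASELINE_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not pools.unlabeled:
        return []
    ids = sorted(pools.unlabeled)
    k = min(K, len(ids))
    if strategy == "random":
        if rng is None:
            raise ValueError("random strategy needs an rng")
        chosen = [ids[i] for i in rng.choice(len(ids), size=k, replace=False)]
    else:
        P = np.stack([_normalized(image_scores[i]) for i in ids])
        if strategy == "least_confidence":
            crit = 1.0 - P.max(axis=1)
            order = np.lexsort((np.array(ids), -crit))
            chosen = [ids[i] for i in order[:k]]
        elif strategy == "entropy":
            crit = -(P * np.log(np.clip(P, 1e-12, None))).sum(axis=1)
            order = np.lexsort((np.array(ids), -crit))
            chosen = [ids[i] for i in order[:k]]
        else:  # kmeans_diversity: one pick nearest each cluster centroid
            k_eff = min(k, len(ids))
            km = KMeans(n_clusters=k_eff, n_init=3, random_state=0)
            assign = km.fit_predict(P)
            chosen = []
            for c in range(k_eff):
                members = np.where(assign == c)[0]
                d = np.linalg.norm(P[members] - km.cluster_centers_[c], axis=1)
                best = members[np.lexsort((members, d))[0]]
                chosen.append(ids[best])
            chosen = sorted(set(chosen))[:k]
    for sid in chosen:
        pools.move_to_labeled(sid)
    pools.check_invariants()
    return list(chosen)


def _normalized(score: np.ndarray) -> np.ndarray:
    s = np.asarray(score, dtype=np.float64)
    tot = s.sum()
    return s / tot if tot > 0 else np.full_like(s, 1.0 / s.size)


# --------------------------------------------------------------------- #
# the full loop                                                         #
# --------------------------------------------------------------------- #
def run_wsmial(config: WSMIALConfig, pools: DataPools,
               query_strategy: str = "hybrid",
               checkpoints_at: set[int] | None = None):
    """Run the complete weakly supervised multiple-instance active-learning
    loop and return ``(state, model)``.

    ``checkpoints_at``: optional set of labeled-pool sizes; when |D_l|
    reaches one of them after a query, the current test metrics are stored
    in the round record under ``"checkpoint"``.
    """
    if query_strategy not in QUERY_STRATEGIES:
        raise ValueError(f"unknown query strategy {query_strategy!r}")
    if not pools.labeled:
        raise ValueError("run_wsmial needs a non-empty initial labeled pool")

    grid = build_grid(config.image_size, config.downsample,
                      AnchorSet.preset(config.anchors))
    all_samples = {**pools.labeled, **pools.unlabeled,
                   **pools.pseudo, **pools.test}
    feats = {sid: f for sid, f in zip(
        all_samples,
        descriptor_batch(list(all_samples.values()), grid))}
    if config.flip_augment:
        # tongues are bilaterally symmetric, marks favor both lateral edges
        flipped = [np.ascontiguousarray(s.pixels[:, ::-1])
                   for s in all_samples.values()]
        feats_flip = {sid: region_descriptors(p, grid)
                      for sid, p in zip(all_samples, flipped)}

    train_rng = seed_stream(config.seed, "train")
    query_rng = seed_stream(config.seed, "query")

    def stack(ids):
        return np.stack([feats[i] for i in ids])

    def labeled_arrays():
        ids = sorted(pools.labeled) + sorted(pools.pseudo)
        X = stack(ids)
        y = np.array([(pools.labeled | pools.pseudo)[i].y for i in ids])
        if config.flip_augment:
            X = np.concatenate([X, np.stack([feats_flip[i] for i in ids])])
            y = np.concatenate([y, y])
        return X, y

    def evaluate():
        ids = sorted(pools.test)
        scores = model.predict_image_scores(stack(ids))
        preds = scores.argmax(axis=1)
        truths = np.array([pools.test[i].y for i in ids])
        return confusion_and_metrics(preds, truths, positive_class=1)

    # line 1: pre-train on the initial labeled pool
    X_l, y_l = labeled_arrays()
    model = fit_ensemble(DESCRIPTOR_DIM, config, X_l, y_l,
                         config.effective_pretrain_epochs,
                         config.n_restarts, config.seed, "pretrain")

    state = ALState(a=0, delta=config.delta0)
    decay_threshold(state, config.delta0, config.dr)
    state.history.append({
        "round": -1, "phase": "pretrain",
        "pool_sizes": pools.sizes(),
        "test_metrics": evaluate().to_dict(),
    })

    while state.a < config.A:
        if not pools.unlabeled and not pools.pseudo:
            break  # unlabeled pool exhausted: clean early stop
        record: dict = {"round": state.a, "delta": state.delta}

        # line 3: re-fit on D_l + D_pl from fresh initializations (warm
        # starts were observed to carry bad basins across rounds); test
        # metrics are always taken on this supervised state so rounds and
        # strategies are comparable
        X_l, y_l = labeled_arrays()
        model = fit_ensemble(DESCRIPTOR_DIM, config, X_l, y_l,
                             config.epoch * 2, config.n_restarts,
                             config.seed, f"round-{state.a}")
        record["pool_sizes_at_eval"] = pools.sizes()
        record["test_metrics"] = evaluate().to_dict()

        # line 4: pseudo-labels are re-earned every round
        reset_pseudo_labels(pools)

        u_ids = sorted(pools.unlabeled)
        X_u = stack(u_ids)
        X_dl = stack(sorted(pools.labeled))
        y_dl = np.array([pools.labeled[i].y for i in sorted(pools.labeled)])

        info: dict[str, float] = {}
        if query_strategy == "hybrid":
            # the adversarial sub-phases exist to expose uncertainty; every
            # ensemble member carries them independently and the per-image
            # informativeness is averaged. Each member's supervised state
            # is snapshotted and restored afterwards so the training
            # trajectory stays purely supervised and strategies differ
            # only in which labels they harvest
            from .model import uncertainty_record
            member_info = []
            for carrier in model.members:
                snapshot = [p.copy() for p in carrier.state_arrays()]
                # lines 6-7: uncertainty sub-phase (FE frozen)
                carrier.train_uncertainty(X_dl, y_dl, X_u,
                                          max(1, config.epoch // 2),
                                          train_rng)
                # lines 8-9: representative sub-phase (f1, f2 frozen)
                carrier.train_representative(X_dl, y_dl, X_u,
                                             max(1, config.epoch // 2),
                                             train_rng)
                # line 10: image informativeness from instance information
                bundles = carrier.score_bundles(X_u)
                member_info.append([
                    uncertainty_record(b, config.R_n,
                                       reweight=config.reweight)
                    .informativeness for b in bundles])
                carrier.load_state_arrays(snapshot)
            mean_info = np.mean(member_info, axis=0)
            info = {sid: float(v) for sid, v in zip(u_ids, mean_info)}
            record["informativeness"] = dict(info)
            record["mean_informativeness"] = float(mean_info.mean())

        # image-level scores from the supervised model (baseline querying
        # and Eq. 18 pseudo-label assignment)
        scores_u = model.predict_image_scores(X_u)
        img_scores = {sid: scores_u[k] for k, sid in enumerate(u_ids)}

        # line 12: expert annotation of the top-K images
        if query_strategy == "hybrid":
            queried = expert_query(pools, info, config.K)
        else:
            queried = baseline_query(query_strategy, pools, img_scores,
                                     config.K, rng=query_rng)
        record["queried"] = queried

        # line 13: pseudo-label low-information images below delta (the
        # informativeness scalar exists only under the hybrid strategy;
        # baseline query strategies train the plain WSL detector)
        if query_strategy == "hybrid":
            remaining_info = {i: info[i] for i in pools.unlabeled}
            remaining_scores = {i: img_scores[i] for i in pools.unlabeled}
            assigned = pseudo_label(pools, remaining_info, remaining_scores,
                                    state.delta, state.a)
            record["pseudo_labeled"] = assigned

        # line 14: threshold decay
        state.a += 1
        decay_threshold(state, config.delta0, config.dr)

        record["pool_sizes"] = pools.sizes()
        if checkpoints_at and len(pools.labeled) in checkpoints_at:
            record["checkpoint"] = len(pools.labeled)
        state.history.append(record)

    # closing re-fit so the labels from the last query round are trained
    # on before the final test (each round's fit otherwise only sees the
    # previous round's pools)
    X_l, y_l = labeled_arrays()
    model = fit_ensemble(DESCRIPTOR_DIM, config, X_l, y_l,
                         config.effective_final_epochs,
                         config.final_restarts, config.seed, "final")
    state.history.append({
        "round": state.a, "phase": "final",
        "pool_sizes": pools.sizes(),
        "test_metrics": evaluate().to_dict(),
    })
    return state, model
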