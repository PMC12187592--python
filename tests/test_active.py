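"""Active-learning mechanics: informativeness ranking, pool transitions,
threshold decay, baselines, and loop bookkeeping."""

import numpy as np
import pytest

from wsmial.active import (baseline_query, decay_threshold, expert_query,
                           image_informativeness, pseudo_label,
                           reset_pseudo_labels, run_wsmial, ALState)
from wsmial.model import ScoreBundle, UncertaintyRecord
from wsmial.synthetic import SyntheticSpec, generate_dataset, split_pools


def make_bundle(R, critic=None, rng=None):
    rng = rng or np.random.default_rng(0)
    y_cls = rng.dirichlet((1, 1), size=R)
    y_det = rng.dirichlet(np.ones(R), size=2)
    return ScoreBundle(
        y_det=y_det, y_cls=y_cls, y_mil=y_cls / 2,
        y_cls1=y_cls, y_cls2=y_cls,
        image_score=np.array([0.5, 0.5]),
        image_score_star=np.array([0.25, 0.25]),
        critic=critic if critic is not None else np.zeros(R),
    )


# ------------------------------------------------------------------ #
# informativeness                                                    #
# ------------------------------------------------------------------ #
def test_informativeness_brute_force_double_ranking():
    """12 instances with discrepancies 1..12 and distinct critic scores:
    top-6 by discrepancy, then top-3 by critic, mean of the kept."""
    R, r_n = 12, 3
    u = np.arange(1.0, 13.0)
    w = np.ones(R)
    critic = np.array([0, 0, 0, 0, 0, 0, 5, 1, 4, 2, 3, 0], dtype=float)
    rec = UncertaintyRecord(u_r=u, w_r=w, informativeness=0.0)
    got = image_informativeness(make_bundle(R, critic), rec, r_n)
    # brute force: candidates {7..12} (indices 6..11), keep 3 highest critic
    cand = list(np.argsort(-u)[:2 * r_n])
    keep = sorted(cand, key=lambda i: -critic[i])[:r_n]
    assert got == pytest.approx(np.mean(u[keep]))
    assert got == pytest.approx(np.mean([7.0, 9.0, 11.0]))


def test_informativeness_tie_invariance_and_zero_case():
    R = 12
    rec = UncertaintyRecord(u_r=np.full(R, 0.4), w_r=np.ones(R),
                            informativeness=0.0)
    assert image_informativeness(make_bundle(R), rec, 6) == pytest.approx(0.4)
    rec0 = UncertaintyRecord(u_r=np.zeros(R), w_r=np.ones(R),
                             informativeness=0.0)
    assert image_informativeness(make_bundle(R), rec0, 6) == 0.0


def test_informativeness_small_bag_uses_all_instances():
    R = 4  # fewer than 2 * r_n
    rec = UncertaintyRecord(u_r=np.array([1.0, 2, 3, 4]), w_r=np.ones(R),
                            informativeness=0.0)
    got = image_informativeness(make_bundle(R), rec, r_n=6)
    assert got == pytest.approx(2.5)


# ------------------------------------------------------------------ #
# pool transitions                                                   #
# ------------------------------------------------------------------ #
@pytest.fixture()
def pools():
    samples = generate_dataset(SyntheticSpec(seed=9), 40)
    return split_pools(samples, test_n=10, initial_labeled_frac=0.2, seed=9)


def test_expert_query_moves_top_k_with_true_labels(pools):
    truth = {sid: pools.reveal_true_label(sid) for sid in pools.unlabeled}
    scores = {sid: float(i) for i, sid in enumerate(sorted(pools.unlabeled))}
    before = pools.sizes()
    chosen = expert_query(pools, scores, K=5)
    assert len(chosen) == 5
    assert chosen == sorted(scores, key=lambda s: (-scores[s], s))[:5]
    assert pools.sizes()["labeled"] == before["labeled"] + 5
    for sid in chosen:
        assert pools.labeled[sid].y == truth[sid]
    assert pools.total == 40


def test_expert_query_clamps_to_pool_and_handles_empty(pools):
    scores = {sid: 1.0 for sid in pools.unlabeled}
    n_u = len(pools.unlabeled)
    chosen = expert_query(pools, scores, K=10 * n_u)
    assert len(chosen) == n_u
    assert expert_query(pools, {}, K=3) == []


def test_expert_query_deterministic_tie_break(pools):
    scores = {sid: 1.0 for sid in pools.unlabeled}
    expect = sorted(pools.unlabeled)[:4]
    assert expert_query(pools, scores, K=4) == expect


def test_pseudo_label_equals_brute_force_filter(pools):
    rng = np.random.default_rng(1)
    info = {sid: float(rng.uniform(0, 0.02)) for sid in pools.unlabeled}
    scores = {sid: rng.dirichlet((1, 1)) for sid in pools.unlabeled}
    delta = 0.01
    expect = {sid for sid, v in info.items() if v < delta}
    assigned = pseudo_label(pools, info, scores, delta, round_a=2)
    assert {sid for sid, _ in assigned} == expect
    for sid, label in assigned:
        assert label == int(np.argmax(scores[sid]))
        assert pools.pseudo[sid].pseudo_round == 2
    pools.check_invariants()


def test_pseudo_label_strict_threshold_zero_disables(pools):
    info = {sid: 0.0 for sid in pools.unlabeled}
    scores = {sid: np.array([0.8, 0.2]) for sid in pools.unlabeled}
    assert pseudo_label(pools, info, scores, delta=0.0, round_a=0) == []


def test_reset_pseudo_labels_round_trips_exactly(pools):
    info = {sid: 0.0 for sid in pools.unlabeled}
    scores = {sid: np.array([0.2, 0.8]) for sid in pools.unlabeled}
    before_u = sorted(pools.unlabeled)
    pseudo_label(pools, info, scores, delta=1.0, round_a=0)
    assert len(pools.unlabeled) == 0
    reset_pseudo_labels(pools)
    assert sorted(pools.unlabeled) == before_u
    assert all(s.y is None for s in pools.unlabeled.values())
    assert len(pools.pseudo) == 0


def test_decay_threshold_linear_rule_and_floor():
    state = ALState(a=0)
    assert decay_threshold(state, 0.01, 0.001).delta == pytest.approx(0.01)
    state.a = 5
    assert decay_threshold(state, 0.01, 0.001).delta == pytest.approx(0.005)
    state.a = 10
    assert decay_threshold(state, 0.01, 0.001).delta == 0.0
    state.a = 50
    assert decay_threshold(state, 0.01, 0.001).delta == 0.0
    state.a = 3
    assert decay_threshold(state, 0.01, 0.0).delta == pytest.approx(0.01)


# ------------------------------------------------------------------ #
# baseline strategies                                                #
# ------------------------------------------------------------------ #
def test_baseline_random_is_seed_reproducible(pools):
    scores = {sid: np.array([0.5, 0.5]) for sid in pools.unlabeled}
    ids = sorted(pools.unlabeled)
    a = baseline_query("random", pools, scores, 5,
                       rng=np.random.default_rng(3))
    # rebuild an identical pool to replay
    samples = generate_dataset(SyntheticSpec(seed=9), 40)
    pools2 = split_pools(samples, test_n=10, initial_labeled_frac=0.2, seed=9)
    b = baseline_query("random", pools2, scores, 5,
                       rng=np.random.default_rng(3))
    assert a == b and len(a) == 5 and set(a) <= set(ids)


def test_entropy_ranks_even_scores_first(pools):
    ids = sorted(pools.unlabeled)
    scores = {sid: np.array([0.99, 0.01]) for sid in ids}
    scores[ids[7]] = np.array([0.5, 0.5])
    chosen = baseline_query("entropy", pools, scores, 1)
    assert chosen == [ids[7]]


def test_least_confidence_tie_breaks_by_id(pools):
    scores = {sid: np.array([0.6, 0.4]) for sid in pools.unlabeled}
    expect = sorted(pools.unlabeled)[:3]
    assert baseline_query("least_confidence", pools, scores, 3) == expect


def test_kmeans_diversity_selects_from_unlabeled(pools):
    rng = np.random.default_rng(5)
    scores = {sid: rng.dirichlet((1, 1)) for sid in pools.unlabeled}
    before = set(pools.unlabeled)
    chosen = baseline_query("kmeans_diversity", pools, scores, 4)
    assert 0 < len(chosen) <= 4 and set(chosen) <= before


def test_unknown_strategy_rejected(pools):
    with pytest.raises(ValueError):
        baseline_query("margin", pools, {}, 1)


# ------------------------------------------------------------------ #
# loop bookkeeping (fast config)                                     #
# ------------------------------------------------------------------ #
def test_run_requires_labeled_pool(fast_config):
    samples = generate_dataset(SyntheticSpec(seed=4), 20)
    pools = split_pools(samples, test_n=5, initial_labeled_frac=0.0, seed=4)
    with pytest.raises(ValueError):
        run_wsmial(fast_config, pools)


def test_zero_rounds_is_pretrain_only(fast_config):
    from dataclasses import replace
    samples = generate_dataset(SyntheticSpec(seed=4), 30)
    pools = split_pools(samples, test_n=5, initial_labeled_frac=0.3, seed=4)
    cfg = replace(fast_config, A=0)
    state, model = run_wsmial(cfg, pools)
    assert state.a == 0
    assert [r.get("phase") for r in state.history] == ["pretrain", "final"]
    assert len(pools.labeled) == 7  # int(0.3 * 25): no queries happened


def test_unlabeled_exhaustion_stops_early(fast_config):
    from dataclasses import replace
    samples = generate_dataset(SyntheticSpec(seed=6), 30)
    pools = split_pools(samples, test_n=5, initial_labeled_frac=0.5, seed=6)
    cfg = replace(fast_config, A=10, K=10)
    state, model = run_wsmial(cfg, pools)
    # 13 unlabeled at start, 10 then 3 queried -> loop stops at round 2
    assert state.a == 2
    assert len(pools.unlabeled) == 0
    assert state.history[-1]["phase"] == "final"


def test_loop_conservation_budget_and_delta_trajectory(fast_config):
    from dataclasses import replace
    samples = generate_dataset(SyntheticSpec(seed=13), 60)
    pools = split_pools(samples, test_n=10, initial_labeled_frac=0.2, seed=13)
    cfg = replace(fast_config, A=3, K=5)
    state, model = run_wsmial(cfg, pools)
    assert state.a == 3
    rounds = [r for r in state.history if "queried" in r]
    assert [len(r["queried"]) for r in rounds] == [5, 5, 5]
    assert [r["delta"] for r in rounds] == [
        pytest.approx(max(0.0, cfg.delta0 - cfg.dr * a)) for a in range(3)]
    for r in rounds:
        sizes = r["pool_sizes"]
        assert sum(sizes.values()) == 60
    assert len(pools.labeled) >= 10 + 15  # initial + 3 rounds of K=5
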