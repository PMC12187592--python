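"""Scoring heads and losses against independent scalar-loop oracles.

Each vectorized operation is re-derived here with explicit Python loops
over classes and regions; agreement is required to 1e-6 on batches of
random tensors, alongside the closed-form cases.
"""

import math

import numpy as np
import pytest

from wsmial import heads


# ------------------------------------------------------------------ #
# scalar-loop oracles                                                #
# ------------------------------------------------------------------ #
def oracle_detection(x):
    C, R = x.shape
    out = np.zeros((C, R))
    for c in range(C):
        m = max(x[c, r] for r in range(R))
        z = sum(math.exp(x[c, r] - m) for r in range(R))
        for r in range(R):
            out[c, r] = math.exp(x[c, r] - m) / z
    return out


def oracle_classification(x):
    T, R, C = x.shape
    mean = np.zeros((R, C))
    for r in range(R):
        for c in range(C):
            mean[r, c] = sum(x[t, r, c] for t in range(T)) / T
    out = np.zeros((R, C))
    for r in range(R):
        m = max(mean[r])
        z = sum(math.exp(v - m) for v in mean[r])
        for c in range(C):
            out[r, c] = math.exp(mean[r, c] - m) / z
    return out


def oracle_image_score(y_cls, y_det):
    R, C = y_cls.shape
    return np.array([sum(y_cls[r, c] * y_det[c, r] for r in range(R))
                     for c in range(C)])


def oracle_mil_scores(x_mil, y_cls):
    R, C = x_mil.shape
    out = np.zeros((R, C))
    for r in range(R):
        m = max(x_mil[r])
        z = sum(math.exp(v - m) for v in x_mil[r])
        for c in range(C):
            out[r, c] = math.exp(x_mil[r, c] - m) / z * y_cls[r, c]
    return out


def oracle_discrepancy(y1, y2, w=None):
    R, C = y1.shape
    total = 0.0
    for r in range(R):
        gap = sum(abs(y1[r, c] - y2[r, c]) for c in range(C))
        total += (abs(w[r]) if w is not None else 1.0) * gap
    return total


def random_case(rng):
    C, T = 2, 2
    R = int(rng.integers(2, 17))
    x_det = rng.normal(size=(C, R)) * 3
    x_cls = rng.normal(size=(T, R, C)) * 3
    x_mil = rng.normal(size=(R, C)) * 3
    return x_det, x_cls, x_mil


# ------------------------------------------------------------------ #
# oracle agreement on random tensors                                 #
# ------------------------------------------------------------------ #
def test_scoring_ops_match_scalar_oracles_on_random_tensors():
    rng = np.random.default_rng(42)
    for _ in range(100):
        x_det, x_cls, x_mil = random_case(rng)
        y_det = heads.detection_branch(x_det)
        y_cls = heads.classification_branch(x_cls)
        y_mil = heads.mil_reweighted_scores(x_mil, y_cls)
        assert np.allclose(y_det, oracle_detection(x_det), atol=1e-6)
        assert np.allclose(y_cls, oracle_classification(x_cls), atol=1e-6)
        assert np.allclose(y_mil, oracle_mil_scores(x_mil, y_cls), atol=1e-6)
        score = heads.image_score(y_cls, y_det)
        assert np.allclose(score, oracle_image_score(y_cls, y_det), atol=1e-6)
        y = int(rng.integers(0, 2))
        assert heads.image_loss(score, y) == pytest.approx(
            -math.log(max(oracle_image_score(y_cls, y_det)[y], 1e-8)),
            abs=1e-6)
        y_star = oracle_image_score(y_mil, y_det)
        p = y_star / y_star.sum()
        assert heads.mil_loss(y_mil, y_det, y) == pytest.approx(
            -math.log(max(p[y], 1e-8)), abs=1e-6)
        w = rng.normal(size=x_mil.shape[0])
        y1 = oracle_classification(rng.normal(size=x_cls.shape))
        y2 = oracle_classification(rng.normal(size=x_cls.shape))
        assert heads.discrepancy_loss(y1, y2, w) == pytest.approx(
            oracle_discrepancy(y1, y2, w), abs=1e-6)
        assert heads.discrepancy_loss(y1, y2) == pytest.approx(
            oracle_discrepancy(y1, y2), abs=1e-6)


# ------------------------------------------------------------------ #
# closed-form cases                                                  #
# ------------------------------------------------------------------ #
def test_detection_uniform_and_two_region_closed_forms():
    assert np.allclose(heads.detection_branch(np.zeros((2, 4))), 0.25)
    out = heads.detection_branch(np.array([[0.0, math.log(3.0)]]))
    assert np.allclose(out, [[0.25, 0.75]])


def test_classification_branch_mean_reduction():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(1, 5, 2))
    twin = np.concatenate([x, x])
    assert np.allclose(heads.classification_branch(twin),
                       heads.classification_branch(x))
    assert np.allclose(heads.classification_branch(np.zeros((2, 3, 2))), 0.5)


def test_image_score_one_hot_selector_and_uniform_average():
    y_cls = np.array([[0.9, 0.1], [0.3, 0.7], [0.5, 0.5]])
    y_det = np.zeros((2, 3))
    y_det[:, 0] = 1.0  # both classes attend region 0 only
    assert np.allclose(heads.image_score(y_cls, y_det), [0.9, 0.1])
    uniform = np.full((2, 3), 1 / 3)
    assert np.allclose(heads.image_score(y_cls, uniform),
                       y_cls.mean(axis=0))


def test_image_loss_perfect_and_even_scores():
    assert heads.image_loss(np.array([1.0, 0.0]), 0) == pytest.approx(0.0)
    assert heads.image_loss(np.array([0.5, 0.5]), 1) == pytest.approx(
        math.log(2))


def test_mil_uniform_head_scales_by_class_count():
    y_cls = np.array([[0.8, 0.2], [0.4, 0.6]])
    y_mil = heads.mil_reweighted_scores(np.zeros((2, 2)), y_cls)
    assert np.allclose(y_mil, y_cls / 2)


def test_mil_large_margin_suppresses_other_class():
    x_mil = np.array([[50.0, 0.0]])
    y_cls = np.array([[0.5, 0.5]])
    y_mil = heads.mil_reweighted_scores(x_mil, y_cls)
    assert y_mil[0, 1] < 1e-10


def test_discrepancy_zero_for_twins_and_maximal_for_opposed():
    y = np.array([[0.2, 0.8], [0.6, 0.4]])
    assert heads.discrepancy_loss(y, y) == 0.0
    assert heads.discrepancy_loss(np.array([[1.0, 0.0]]),
                                  np.array([[0.0, 1.0]])) == pytest.approx(2.0)


def test_critic_loss_mean_gap_and_empty_error():
    assert heads.critic_loss([0.3, 0.3], [0.1, 0.1]) == pytest.approx(0.2)
    assert heads.critic_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
    with pytest.raises(ValueError):
        heads.critic_loss([], [0.1])


def test_total_loss_phase_composition():
    assert heads.total_loss("supervised", 0.4, 0.6) == pytest.approx(1.0)
    assert heads.total_loss("uncertainty", 0.4, 0.6, l_dis=0.5,
                            beta=0.1) == pytest.approx(1.0 - 0.05)
    assert heads.total_loss("representative", 0.4, 0.6, l_dis=0.5, l_w=0.2,
                            beta=0.1) == pytest.approx(1.0 + 0.07)
    # beta = 0 with no unlabeled terms reduces to the supervised objective
    assert heads.total_loss("uncertainty", 0.4, 0.6, l_dis=0.0,
                            beta=0.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        heads.total_loss("warmup", 0.0, 0.0)


# ------------------------------------------------------------------ #
# invariants                                                         #
# ------------------------------------------------------------------ #
def test_branch_normalizations():
    rng = np.random.default_rng(5)
    for _ in range(20):
        x_det, x_cls, _ = random_case(rng)
        assert np.allclose(heads.detection_branch(x_det).sum(axis=1), 1.0,
                           atol=1e-5)
        assert np.allclose(heads.classification_branch(x_cls).sum(axis=1),
                           1.0, atol=1e-5)


def test_suppression_lowering_mil_score_never_raises_contribution():
    """Shrinking one instance's MIL softmax share cannot increase its
    contribution to the MIL-reweighted image score."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        x_det, x_cls, x_mil = random_case(rng)
        R = x_mil.shape[0]
        y_det = heads.detection_branch(x_det)
        y_cls = heads.classification_branch(x_cls)
        r = int(rng.integers(0, R))
        c = int(rng.integers(0, 2))
        before = heads.mil_reweighted_scores(x_mil, y_cls)[r, c] * y_det[c, r]
        x_pert = x_mil.copy()
        x_pert[r, c] -= float(rng.uniform(0.1, 3.0))  # lower the MIL logit
        after = heads.mil_reweighted_scores(x_pert, y_cls)[r, c] * y_det[c, r]
        assert after <= before + 1e-12


def test_non_finite_logits_rejected():
    bad = np.array([[np.nan, 0.0]])
    with pytest.raises(ValueError):
        heads.detection_branch(bad)
    with pytest.raises(ValueError):
        heads.classification_branch(bad[None])
    with pytest.raises(ValueError):
        heads.mil_reweighted_scores(bad, np.abs(bad))
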