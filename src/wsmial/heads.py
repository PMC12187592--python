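"""Scoring heads and losses of the weakly supervised MIL detector.

An image is a bag of R rectangular region proposals. Two complementary
softmax heads score the proposals: the *detection* branch normalizes each
class's logits across regions (which region does this class live in?), and
the *classification* branch normalizes each region's logits across classes
(which class does this region show?). Their Hadamard product, summed over
regions, yields the image-level class score that the image-level label
supervises. A parallel MIL head reweights the classification scores so
that background regions with confident but irrelevant class scores are
suppressed, and two antagonistic instance classifiers expose instance
uncertainty through their prediction discrepancy. A Wasserstein critic
scores how close an instance's feature lies to the labeled pool.

All functions here are pure numpy and operate on a single image's score
arrays; the trainable model in `wsmial.model` builds the identical
computations on autodiff tensors.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-8

__all__ = [
    "detection_branch",
    "classification_branch",
    "image_score",
    "image_loss",
    "mil_reweighted_scores",
    "mil_image_score",
    "mil_loss",
    "discrepancy_loss",
    "critic_loss",
    "total_loss",
]


def _check_finite(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries")
    return x


def _softmax(x: np.ndarray, axis: int) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def detection_branch(x_det: np.ndarray) -> np.ndarray:
    """Softmax over the region axis, per class.

    Parameters
    ----------
    x_det : (C, R) array of raw detection logits.

    Returns
    -------
    (C, R) array: for each class c a distribution over regions,
    ``y[c, r] = exp(x[c, r]) / sum_r' exp(x[c, r'])``.
    """
    x_det = _check_finite("x_det", x_det)
    if x_det.ndim != 2 or x_det.shape[1] < 1:
        raise ValueError("x_det must be a C x R matrix with R >= 1")
    return _softmax(x_det, axis=1)


def classification_branch(x_cls_t: np.ndarray) -> np.ndarray:
    """Average T branch logits, then softmax over classes per region.

    Parameters
    ----------
    x_cls_t : (T, R, C) stacked classification logits, T >= 1.

    Returns
    -------
    (R, C) array of per-region class distributions.
    """
    x = _check_finite("x_cls_t", x_cls_t)
    if x.ndim != 3 or x.shape[0] < 1:
        raise ValueError("x_cls_t must be T x R x C with T >= 1")
    mean_logits = x.mean(axis=0)
    return _softmax(mean_logits, axis=1)


def image_score(y_cls: np.ndarray, y_det: np.ndarray) -> np.ndarray:
    """Image-level class scores: region-summed Hadamard product of the
    classification distribution with the detection distribution.

    ``y[c] = sum_r y_cls[r, c] * y_det[c, r]``
    """
    y_cls = np.asarray(y_cls, dtype=np.float64)
    y_det = np.asarray(y_det, dtype=np.float64)
    if y_cls.ndim != 2 or y_det.ndim != 2 or y_cls.shape != y_det.T.shape:
        raise ValueError("y_cls must be R x C and y_det C x R")
    return np.einsum("rc,cr->c", y_cls, y_det)


def image_loss(score: np.ndarray, y_gt: int) -> float:
    """Negative log-likelihood of the true class under the image score."""
    score = np.asarray(score, dtype=np.float64)
    if not 0 <= y_gt < score.shape[0]:
        raise ValueError("y_gt out of range")
    return float(-np.log(max(score[y_gt], EPS)))


def mil_reweighted_scores(x_mil: np.ndarray, y_cls: np.ndarray) -> np.ndarray:
    """Elementwise product of the MIL head's class softmax with the
    classification-branch scores; background regions get tiny MIL scores
    and are thereby suppressed.
    """
    x_mil = _check_finite("x_mil", x_mil)
    y_cls = np.asarray(y_cls, dtype=np.float64)
    if x_mil.shape != y_cls.shape or x_mil.ndim != 2:
        raise ValueError("x_mil and y_cls must both be R x C")
    return _softmax(x_mil, axis=1) * y_cls


def mil_image_score(y_mil: np.ndarray, y_det: np.ndarray) -> np.ndarray:
    """MIL-reweighted image score ``y*[c] = sum_r y_mil[r, c] * y_det[c, r]``."""
    y_mil = np.asarray(y_mil, dtype=np.float64)
    y_det = np.asarray(y_det, dtype=np.float64)
    if y_mil.shape != y_det.T.shape:
        raise ValueError("y_mil must be R x C and y_det C x R")
    return np.einsum("rc,cr->c", y_mil, y_det)


def mil_loss(y_mil: np.ndarray, y_det: np.ndarray, y_gt: int) -> float:
    """NLL of the true class under the MIL-reweighted image score.

    The raw Hadamard sum need not lie on the simplex, so y* is renormalized
    to a probability vector before the log.
    """
    y_star = mil_image_score(y_mil, y_det)
    total = y_star.sum()
    if total < EPS:
        total = EPS
    p = y_star / total
    if not 0 <= y_gt < p.shape[0]:
        raise ValueError("y_gt out of range")
    return float(-np.log(max(p[y_gt], EPS)))


def discrepancy_loss(y_cls1: np.ndarray, y_cls2: np.ndarray,
                     w: np.ndarray | None = None) -> float:
    """Instance-uncertainty discrepancy: per-instance L1 gap between the two
    antagonistic classifiers, optionally reweighted per instance.

    ``sum_r |w_r| * sum_c |y1[r, c] - y2[r, c]|`` (w defaults to ones).
    """
    y1 = np.asarray(y_cls1, dtype=np.float64)
    y2 = np.asarray(y_cls2, dtype=np.float64)
    if y1.shape != y2.shape or y1.ndim != 2:
        raise ValueError("classifier outputs must both be R x C")
    per_instance = np.abs(y1 - y2).sum(axis=1)
    if w is None:
        return float(per_instance.sum())
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (y1.shape[0],):
        raise ValueError("w must have one weight per instance")
    return float((np.abs(w) * per_instance).sum())


def critic_loss(f_labeled: np.ndarray, f_unlabeled: np.ndarray) -> float:
    """Empirical Wasserstein surrogate: mean critic score on labeled-pool
    instances minus mean on unlabeled-pool instances.
    """
    f_l = np.asarray(f_labeled, dtype=np.float64).ravel()
    f_u = np.asarray(f_unlabeled, dtype=np.float64).ravel()
    if f_l.size == 0 or f_u.size == 0:
        raise ValueError("critic_loss needs non-empty labeled and unlabeled scores")
    return float(f_l.mean() - f_u.mean())


_PHASES = ("supervised", "uncertainty", "representative")


def total_loss(phase: str, l_img: float, l_mil: float,
               l_dis: float = 0.0, l_w: float = 0.0,
               beta: float = 0.5) -> float:
    """Compose the phase objective from its already-computed terms.

    supervised      : L_img + L_mil                       (labeled data only)
    uncertainty     : L_img + L_mil - beta * L_dis        (classifiers ascend
                      discrepancy on unlabeled data; feature extractor fixed)
    representative  : L_img + L_mil + beta * (L_dis + L_W) (classifiers fixed;
                      feature extractor descends discrepancy and the
                      Wasserstein gap)
    """
    if phase not in _PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {_PHASES}")
    base = l_img + l_mil
    if phase == "supervised":
        return float(base)
    if phase == "uncertainty":
        return float(base - beta * l_dis)
    return float(base + beta * (l_dis + l_w))
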