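"""Trainable detector: forward consistency with the functional heads,
training-phase behavior, critic clipping, ensembling."""

import numpy as np
import pytest

from wsmial import heads
from wsmial.config import WSMIALConfig
from wsmial.features import DESCRIPTOR_DIM
from wsmial.model import (EnsembleModel, WSMILModel, fit_ensemble,
                          uncertainty_record)
from wsmial.utils import seed_stream


@pytest.fixture()
def model():
    return WSMILModel(DESCRIPTOR_DIM, WSMIALConfig(), seed_stream(0, "m"))


def random_feats(rng, b=3, r=12):
    return rng.normal(size=(b, r, DESCRIPTOR_DIM))


def test_forward_matches_functional_heads_per_image(model, rng):
    """The batched autodiff forward must reproduce the single-image
    functional scoring path exactly."""
    feats = random_feats(rng)
    out = model.forward(feats)
    cfg = model.config
    import wsmial.autodiff as ad
    for b in range(feats.shape[0]):
        z_np = model.fe(ad.Tensor(feats[b:b + 1])).data[0]
        x_det = (z_np @ model.f_det.weight.data + model.f_det.bias.data)
        y_det = heads.detection_branch(x_det.T / cfg.det_temp)
        x_cls = np.stack([z_np @ h.weight.data + h.bias.data
                          for h in model.f_cls])
        y_cls = heads.classification_branch(x_cls)
        x_mil = z_np @ model.f_mil.weight.data + model.f_mil.bias.data
        y_mil = heads.mil_reweighted_scores(x_mil, y_cls)
        assert np.allclose(out["y_det"].data[b].T, y_det, atol=1e-9)
        assert np.allclose(out["y_cls"].data[b], y_cls, atol=1e-9)
        assert np.allclose(out["y_mil"].data[b], y_mil, atol=1e-9)
        assert np.allclose(out["image_score"].data[b],
                           heads.image_score(y_cls, y_det), atol=1e-9)
        assert np.allclose(out["y_star"].data[b],
                           heads.mil_image_score(y_mil, y_det), atol=1e-9)


def test_score_bundles_align_with_forward(model, rng):
    feats = random_feats(rng)
    out = model.forward(feats)
    bundles = model.score_bundles(feats)
    assert len(bundles) == feats.shape[0]
    for b, bundle in enumerate(bundles):
        assert np.allclose(bundle.y_det, out["y_det"].data[b].T)
        assert np.allclose(bundle.image_score, out["image_score"].data[b])
        assert bundle.critic.shape == (feats.shape[1],)


def test_antagonistic_classifiers_are_the_branches(model, rng):
    """With T = 2 the branch softmaxes are f1/f2; identical branch weights
    force zero discrepancy."""
    feats = random_feats(rng)
    for p, q in zip(model.f_cls[0].parameters(), model.f_cls[1].parameters()):
        q.data = p.data.copy()
    out = model.forward(feats)
    assert np.allclose(out["y_cls1"].data, out["y_cls2"].data)
    assert model.discrepancy(out).data == pytest.approx(0.0)


def test_supervised_training_reduces_loss_and_fits_labels(model, rng):
    feats = random_feats(rng, b=24)
    labels = (feats[:, :, 0].mean(axis=1) > 0).astype(int)
    hist = model.train_supervised(feats, labels, epochs=30,
                                  rng=seed_stream(0, "t"))
    assert hist[-1] < hist[0]
    preds = model.predict_image_scores(feats).argmax(axis=1)
    assert (preds == labels).mean() >= 0.9


def test_uncertainty_phase_leaves_feature_extractor_untouched(model, rng):
    feats_l = random_feats(rng, b=8)
    labels = np.zeros(8, dtype=int)
    feats_u = random_feats(rng, b=8)
    fe_before = [p.data.copy() for p in model.fe.parameters()]
    cls_before = [p.data.copy() for h in model.f_cls for p in h.parameters()]
    model.train_uncertainty(feats_l, labels, feats_u, epochs=2,
                            rng=seed_stream(0, "u"))
    assert all(np.array_equal(a, p.data)
               for a, p in zip(fe_before, model.fe.parameters()))
    assert any(not np.array_equal(a, p.data) for a, p in zip(
        cls_before, [p for h in model.f_cls for p in h.parameters()]))


def test_representative_phase_freezes_classifiers_and_clips_critic(model, rng):
    feats_l = random_feats(rng, b=8)
    labels = np.zeros(8, dtype=int)
    feats_u = random_feats(rng, b=8)
    cls_before = [p.data.copy() for h in model.f_cls for p in h.parameters()]
    fe_before = [p.data.copy() for p in model.fe.parameters()]
    model.train_representative(feats_l, labels, feats_u, epochs=3,
                               rng=seed_stream(0, "r"))
    assert all(np.array_equal(a, p.data) for a, p in zip(
        cls_before, [p for h in model.f_cls for p in h.parameters()]))
    assert any(not np.array_equal(a, p.data)
               for a, p in zip(fe_before, model.fe.parameters()))
    Q = model.config.Q
    for p in model.critic.parameters():
        assert np.all(np.abs(p.data) <= Q + 1e-15)


def test_instance_weight_modes(model, rng):
    feats = random_feats(rng)
    out = model.forward(feats)
    y_mil = out["y_mil"].data
    assert np.allclose(model.instance_weights(out), y_mil.max(axis=2))
    model.config.reweight = "l2"
    assert np.allclose(model.instance_weights(out),
                       np.linalg.norm(y_mil, axis=2))
    model.config.reweight = "true_class"
    labels = np.array([0, 1, 0])
    w = model.instance_weights(out, labels)
    assert np.allclose(w[1], y_mil[1, :, 1])


def test_uncertainty_record_discrepancy_and_weights(model, rng):
    bundle = model.score_bundles(random_feats(rng, b=1))[0]
    rec = uncertainty_record(bundle, r_n=3)
    assert np.allclose(rec.u_r,
                       np.abs(bundle.y_cls1 - bundle.y_cls2).sum(axis=1))
    assert np.all(rec.u_r >= 0)
    assert np.allclose(rec.w_r, bundle.y_mil.max(axis=1))
    assert rec.informativeness >= 0


def test_ensemble_averages_normalized_scores(rng):
    cfg = WSMIALConfig()
    members = [WSMILModel(DESCRIPTOR_DIM, cfg, seed_stream(k, "e"))
               for k in range(2)]
    ens = EnsembleModel(members)
    feats = random_feats(rng)
    expect = np.mean([
        m.predict_image_scores(feats)
        / m.predict_image_scores(feats).sum(axis=1, keepdims=True)
        for m in members], axis=0)
    assert np.allclose(ens.predict_image_scores(feats), expect, atol=1e-8)


def test_fit_ensemble_is_seed_deterministic(rng):
    cfg = WSMIALConfig(epoch=2)
    feats = random_feats(rng, b=10)
    labels = (feats[:, :, 0].mean(axis=1) > 0).astype(int)
    a = fit_ensemble(DESCRIPTOR_DIM, cfg, feats, labels, 2, 2, 5, "x")
    b = fit_ensemble(DESCRIPTOR_DIM, cfg, feats, labels, 2, 2, 5, "x")
    assert np.allclose(a.predict_image_scores(feats),
                       b.predict_image_scores(feats))
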