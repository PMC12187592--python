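"""The weakly supervised MIL detector: feature extractor, scoring heads,
antagonistic instance classifiers, Wasserstein critic, and the three
training phases of each active-learning round.

Architecture (test scale): fixed per-proposal pixel descriptors
(`wsmial.features`) -> trainable MLP feature extractor -> linear heads:

* ``f_det``  — detection branch, softmax over regions per class
* ``f_cls``  — T parallel classification branches, logits averaged, softmax
  over classes per region. With T = 2 the two branches double as the
  antagonistic instance classifiers f1 and f2: each branch's own softmax
  is an instance prediction, their L1 gap is the instance uncertainty,
  and the supervised image loss anchors both through the average.
* ``f_mil``  — MIL head whose class softmax reweights the classification
  scores so background regions are suppressed
* ``critic`` — Wasserstein critic scoring how close an instance feature
  lies to the labeled-pool distribution; its parameters are clipped to
  [-Q, Q] after every update (Lipschitz constraint)

Training phases per round: *supervised* fine-tuning on labeled (+pseudo)
images; *uncertainty* (feature extractor frozen, classifiers ascend the
reweighted discrepancy on unlabeled data); *representative* (classifiers
f1/f2 frozen, feature extractor descends discrepancy plus the critic gap
while the critic ascends it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax
from .config import WSMIALConfig
from .heads import EPS
from .nn import AdamW, Linear, MLP, Module, clip_parameters_
from .utils import seed_stream


@dataclass
class ScoreBundle:
    """All per-region scores and derived image-level scores for one image."""

    y_det: np.ndarray            # (C, R) detection softmax over regions
    y_cls: np.ndarray            # (R, C) classification softmax over classes
    y_mil: np.ndarray            # (R, C) MIL-reweighted class scores
    y_cls1: np.ndarray           # (R, C) antagonistic classifier 1
    y_cls2: np.ndarray           # (R, C) antagonistic classifier 2
    image_score: np.ndarray      # (C,)  Hadamard image score
    image_score_star: np.ndarray  # (C,) MIL-reweighted image score
    critic: np.ndarray           # (R,)  critic score per instance


@dataclass
class UncertaintyRecord:
    """Per-instance discrepancy, reweighting, and the image scalar."""

    u_r: np.ndarray              # (R,) L1 discrepancy per instance
    w_r: np.ndarray              # (R,) instance reweight
    informativeness: float


class WSMILModel(Module):
    def __init__(self, d_in: int, config: WSMIALConfig,
                 rng: np.random.Generator):
        C, T = config.C, config.T
        d = config.feature_dim
        self.config = config
        self.fe = MLP([d_in, config.hidden_dim, d], rng)
        self.f_det = Linear(d, C, rng)
        self.f_cls = [Linear(d, C, rng) for _ in range(T)]
        self.f_mil = Linear(d, C, rng)
        self.critic = MLP([d, config.critic_hidden, 1], rng)

    # ------------------------------------------------------------------ #
    # forward                                                            #
    # ------------------------------------------------------------------ #
    def forward(self, feats: Tensor | np.ndarray) -> dict[str, Tensor]:
        """Batched forward. `feats` is (B, R, d_in); every returned score
        tensor is laid out (B, R, C) with regions on axis 1.
        """
        x = feats if isinstance(feats, Tensor) else Tensor(feats)
        z = self.fe(x)                                   # (B, R, d)
        # low detection temperature sharpens the attention over regions so
        # a few true instances are not diluted among hundreds of proposals
        x_det = self.f_det(z) * (1.0 / self.config.det_temp)
        y_det = softmax(x_det, axis=1)                   # over regions
        branch_logits = [head(z) for head in self.f_cls]
        cls_logits = branch_logits[0]
        for extra in branch_logits[1:]:
            cls_logits = cls_logits + extra
        cls_logits = cls_logits * (1.0 / len(branch_logits))
        y_cls = softmax(cls_logits, axis=2)              # over classes
        y_mil = softmax(self.f_mil(z), axis=2) * y_cls
        # the first two branches are the antagonistic classifiers f1, f2
        y1 = softmax(branch_logits[0], axis=2)
        y2 = softmax(branch_logits[-1], axis=2)
        image_score = (y_cls * y_det).sum(axis=1)        # (B, C)
        y_star = (y_mil * y_det).sum(axis=1)             # (B, C)
        f_critic = self.critic(z)                        # (B, R, 1)
        return {
            "z": z, "y_det": y_det, "y_cls": y_cls, "y_mil": y_mil,
            "y_cls1": y1, "y_cls2": y2,
            "image_score": image_score, "y_star": y_star,
            "critic": f_critic,
        }

    def score_bundles(self, feats: np.ndarray) -> list[ScoreBundle]:
        """Inference-only scoring; returns one ScoreBundle per image."""
        out = self.forward(feats)
        B = feats.shape[0]
        bundles = []
        for b in range(B):
            bundles.append(ScoreBundle(
                y_det=out["y_det"].data[b].T.copy(),
                y_cls=out["y_cls"].data[b].copy(),
                y_mil=out["y_mil"].data[b].copy(),
                y_cls1=out["y_cls1"].data[b].copy(),
                y_cls2=out["y_cls2"].data[b].copy(),
                image_score=out["image_score"].data[b].copy(),
                image_score_star=out["y_star"].data[b].copy(),
                critic=out["critic"].data[b, :, 0].copy(),
            ))
        return bundles

    def predict_image_scores(self, feats: np.ndarray) -> np.ndarray:
        """(B, C) image-level class scores."""
        return self.forward(feats)["image_score"].data.copy()

    # ------------------------------------------------------------------ #
    # loss terms (autodiff)                                              #
    # ------------------------------------------------------------------ #
    @staticmethod
    def _nll(score: Tensor, onehot: np.ndarray) -> Tensor:
        """Batch-mean NLL of the true class after renormalizing the score
        vector to the simplex. Each class carries its own detection
        distribution, so the raw Hadamard sums need not lie on the simplex
        and can be large for several classes at once; the renormalization
        makes the objective match the argmax decision rule."""
        p = score / (score.sum(axis=1, keepdims=True) + EPS)
        s_true = (p * Tensor(onehot)).sum(axis=1)
        return -((s_true + EPS).log().mean())

    def supervised_loss(self, out: dict[str, Tensor],
                        labels: np.ndarray) -> tuple[Tensor, Tensor]:
        """(L_img, L_mil) for a labeled batch; both batch means."""
        C = out["image_score"].shape[1]
        onehot = np.eye(C)[labels]
        l_img = self._nll(out["image_score"], onehot)
        l_mil = self._nll(out["y_star"], onehot)
        return l_img, l_mil

    def instance_weights(self, out: dict[str, Tensor],
                         labels: np.ndarray | None = None) -> np.ndarray:
        """(B, R) detached instance reweights from the MIL-suppressed class
        scores ``y_mil``; background instances carry near-zero weight.

        Modes (``config.reweight``): ``max`` — largest class entry of
        ``y_mil[r, :]``; ``true_class`` — the true-class entry (labeled data
        only, falls back to ``max`` without labels); ``l2`` — Euclidean norm
        of ``y_mil[r, :]``.
        """
        y_mil = out["y_mil"].data
        mode = self.config.reweight
        if mode == "true_class" and labels is not None:
            idx = np.arange(y_mil.shape[0])[:, None]
            return y_mil[idx, np.arange(y_mil.shape[1])[None, :], labels[:, None]]
        if mode == "l2":
            return np.linalg.norm(y_mil, axis=2)
        return y_mil.max(axis=2)

    def discrepancy(self, out: dict[str, Tensor],
                    weights: np.ndarray | None = None) -> Tensor:
        """Batch- and region-mean (reweighted) L1 discrepancy between f1 and
        f2. The per-region mean keeps the term on the same O(1) scale as the
        image-level NLLs regardless of the proposal count."""
        diff = (out["y_cls1"] - out["y_cls2"]).abs().sum(axis=2)  # (B, R)
        if weights is not None:
            diff = diff * Tensor(np.abs(weights))
        return diff.mean(axis=1).mean()

    def critic_gap(self, out_l: dict[str, Tensor],
                   out_u: dict[str, Tensor]) -> Tensor:
        """mean critic score on labeled instances minus mean on unlabeled."""
        return out_l["critic"].mean() - out_u["critic"].mean()

    # ------------------------------------------------------------------ #
    # training phases                                                    #
    # ------------------------------------------------------------------ #
    def _minibatches(self, n: int, rng: np.random.Generator):
        order = rng.permutation(n)
        bs = self.config.batch_size
        for k in range(0, n, bs):
            yield order[k:k + bs]

    def train_supervised(self, feats: np.ndarray, labels: np.ndarray,
                         epochs: int, rng: np.random.Generator) -> list[float]:
        """Fine-tune everything on labeled (+pseudo-labeled) images with
        L_img + L_mil. Returns the per-epoch mean losses."""
        params = (self.fe.parameters() + self.f_det.parameters()
                  + [p for h in self.f_cls for p in h.parameters()]
                  + self.f_mil.parameters())
        opt = AdamW(params, lr=self.config.lr,
                    weight_decay=self.config.weight_decay)
        history = []
        for _ in range(epochs):
            losses = []
            for idx in self._minibatches(len(feats), rng):
                out = self.forward(feats[idx])
                l_img, l_mil = self.supervised_loss(out, labels[idx])
                # f1/f2 also fit the labeled data so their discrepancy is
                # meaningful; their image-level NLLs are added here
                onehot = np.eye(out["image_score"].shape[1])[labels[idx]]
                aux = self._nll((out["y_cls1"] * out["y_det"]).sum(axis=1),
                                onehot) \
                    + self._nll((out["y_cls2"] * out["y_det"]).sum(axis=1),
                                onehot)
                loss = l_img + l_mil + 0.5 * aux
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
        return history

    def train_uncertainty(self, feats_l: np.ndarray, labels_l: np.ndarray,
                          feats_u: np.ndarray, epochs: int,
                          rng: np.random.Generator) -> list[float]:
        """Feature extractor frozen; the heads minimize the supervised loss
        while *maximizing* the reweighted discrepancy on unlabeled data."""
        params = (self.f_det.parameters()
                  + [p for h in self.f_cls for p in h.parameters()]
                  + self.f_mil.parameters())
        opt = AdamW(params, lr=self.config.lr,
                    weight_decay=self.config.weight_decay)
        beta = self.config.beta
        history = []
        for _ in range(epochs):
            losses = []
            for idx_l, idx_u in self._paired_batches(len(feats_l),
                                                     len(feats_u), rng):
                out_l = self.forward(feats_l[idx_l])
                l_img, l_mil = self.supervised_loss(out_l, labels_l[idx_l])
                out_u = self.forward(feats_u[idx_u])
                w = self.instance_weights(out_u)
                l_dis = self.discrepancy(out_u, w)
                loss = l_img + l_mil - beta * l_dis
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
        return history

    def train_representative(self, feats_l: np.ndarray, labels_l: np.ndarray,
                             feats_u: np.ndarray, epochs: int,
                             rng: np.random.Generator) -> list[float]:
        """f1/f2 frozen; the feature extractor descends the supervised loss,
        the discrepancy, and the Wasserstein gap, while the critic ascends
        the gap under the clip bound Q."""
        fe_params = (self.fe.parameters() + self.f_det.parameters()
                     + self.f_mil.parameters())
        opt_fe = AdamW(fe_params, lr=self.config.lr,
                       weight_decay=self.config.weight_decay)
        opt_c = AdamW(self.critic.parameters(), lr=self.config.critic_lr,
                      weight_decay=0.0)
        beta = self.config.beta
        Q = self.config.Q
        clip_parameters_(self.critic.parameters(), Q)
        history = []
        for _ in range(epochs):
            losses = []
            for idx_l, idx_u in self._paired_batches(len(feats_l),
                                                     len(feats_u), rng):
                # critic ascent on detached features
                z_l = self.fe(Tensor(feats_l[idx_l])).data
                z_u = self.fe(Tensor(feats_u[idx_u])).data
                gap = self.critic(Tensor(z_l)).mean() \
                    - self.critic(Tensor(z_u)).mean()
                critic_obj = -gap
                opt_c.zero_grad()
                critic_obj.backward()
                opt_c.step()
                clip_parameters_(self.critic.parameters(), Q)

                # feature-extractor descent (critic parameters fixed)
                out_l = self.forward(feats_l[idx_l])
                l_img, l_mil = self.supervised_loss(out_l, labels_l[idx_l])
                out_u = self.forward(feats_u[idx_u])
                w = self.instance_weights(out_u)
                l_dis = self.discrepancy(out_u, w)
                l_w = self.critic_gap(out_l, out_u)
                loss = l_img + l_mil + beta * (l_dis + l_w)
                opt_fe.zero_grad()
                loss.backward()
                opt_fe.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
        return history

    def _paired_batches(self, n_l: int, n_u: int, rng: np.random.Generator):
        """Yield aligned labeled/unlabeled minibatch index pairs, cycling
        the smaller pool."""
        bs = self.config.batch_size
        steps = max(1, int(np.ceil(max(n_l, n_u) / bs)))
        order_l = rng.permutation(n_l)
        order_u = rng.permutation(n_u)
        reps_l = int(np.ceil(steps * bs / n_l))
        reps_u = int(np.ceil(steps * bs / n_u))
        cyc_l = np.concatenate([rng.permutation(n_l) if k else order_l
                                for k in range(reps_l)])
        cyc_u = np.concatenate([rng.permutation(n_u) if k else order_u
                                for k in range(reps_u)])
        for k in range(steps):
            yield cyc_l[k * bs:(k + 1) * bs], cyc_u[k * bs:(k + 1) * bs]


class EnsembleModel:
    """Average of independently initialized detectors.

    Image scores are the mean of the members' simplex-normalized scores;
    score bundles are field-wise means. Small ensembles smooth out the
    initialization lottery of the non-convex MIL objective.
    """

    def __init__(self, members: list[WSMILModel]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members
        self.config = members[0].config

    def predict_image_scores(self, feats: np.ndarray) -> np.ndarray:
        acc = None
        for m in self.members:
            s = m.predict_image_scores(feats)
            s = s / (s.sum(axis=1, keepdims=True) + EPS)
            acc = s if acc is None else acc + s
        return acc / len(self.members)

    def score_bundles(self, feats: np.ndarray) -> list[ScoreBundle]:
        per_member = [m.score_bundles(feats) for m in self.members]
        merged = []
        n = len(self.members)
        for bundles in zip(*per_member):
            first = bundles[0]
            merged.append(ScoreBundle(*[
                sum(getattr(b, f) for b in bundles) / n
                for f in ("y_det", "y_cls", "y_mil", "y_cls1", "y_cls2",
                          "image_score", "image_score_star", "critic")]))
        return merged

    def state_arrays(self) -> list[np.ndarray]:
        return [a for m in self.members for a in m.state_arrays()]

    def load_state_arrays(self, arrays) -> None:
        sizes = [len(m.parameters()) for m in self.members]
        if len(arrays) != sum(sizes):
            raise ValueError("state size mismatch")
        k = 0
        for m, n in zip(self.members, sizes):
            m.load_state_arrays(arrays[k:k + n])
            k += n


def fit_ensemble(d_in: int, config: WSMIALConfig, feats: np.ndarray,
                 labels: np.ndarray, epochs: int, n_members: int,
                 seed: int, name: str) -> EnsembleModel:
    """Train `n_members` fresh detectors on the same data and ensemble them."""
    members = []
    for k in range(n_members):
        m = WSMILModel(d_in, config, seed_stream(seed, f"{name}-init-{k}"))
        m.train_supervised(feats, labels, epochs,
                           seed_stream(seed, f"{name}-train-{k}"))
        members.append(m)
    return EnsembleModel(members)


def uncertainty_record(bundle: ScoreBundle, r_n: int,
                       reweight: str = "max") -> UncertaintyRecord:
    """Build the per-instance uncertainty record and the image scalar.

    The per-instance discrepancy ``u_r`` is reweighted by ``w_r`` drawn
    from the MIL-suppressed class scores (see
    `WSMILModel.instance_weights`); the image scalar is computed by
    `wsmial.active.image_informativeness`.
    """
    from .active import image_informativeness  # cycle-free at call time

    u_r = np.abs(bundle.y_cls1 - bundle.y_cls2).sum(axis=1)
    if reweight == "l2":
        w_r = np.linalg.norm(bundle.y_mil, axis=1)
    else:
        w_r = bundle.y_mil.max(axis=1)
    rec = UncertaintyRecord(u_r=u_r, w_r=w_r, informativeness=0.0)
    rec.informativeness = image_informativeness(bundle, rec, r_n)
    return rec
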