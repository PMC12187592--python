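"""Sample and pool containers for the active-learning loop.

An :class:`ImageSample` carries the pixels, the *observed* label (hidden
while the sample sits in the unlabeled pool), and optional ground-truth
boxes that only evaluation code may read. :class:`DataPools` keeps the
four disjoint pools — labeled ``D_l``, unlabeled ``D_u``, pseudo-labeled
``D_pl`` and the held-out test set ``D_t`` — and a private label vault
that stands in for the human expert: the true labels of unlabeled samples
are stored there and are only ever read by the query oracle, never by the
training path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABELED = "labeled"
UNLABELED = "unlabeled"
PSEUDO = "pseudo"


@dataclass
class ImageSample:
    """One image with its label state.

    ``y`` is the label visible to training: the true label when labeled,
    the model-assigned label when pseudo-labeled, ``None`` while unlabeled.
    ``gt_boxes`` are half-open pixel boxes ``(x0, y0, x1, y1)`` used only
    for evaluation overlays and localization checks.
    """

    id: str
    pixels: np.ndarray
    label_state: str = LABELED
    y: int | None = None
    pseudo_round: int | None = None
    gt_boxes: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.label_state not in (LABELED, UNLABELED, PSEUDO):
            raise ValueError(f"invalid label_state {self.label_state!r}")
        if self.label_state == UNLABELED and self.y is not None:
            raise ValueError("unlabeled samples must not expose a label")
        if self.label_state == LABELED and self.y is None:
            raise ValueError("labeled samples need a label")


class PoolError(ValueError):
    pass


@dataclass
class DataPools:
    """The four disjoint sample pools plus the hidden-label vault."""

    labeled: dict[str, ImageSample] = field(default_factory=dict)
    unlabeled: dict[str, ImageSample] = field(default_factory=dict)
    pseudo: dict[str, ImageSample] = field(default_factory=dict)
    test: dict[str, ImageSample] = field(default_factory=dict)
    # true labels of samples whose label is currently hidden (D_u and D_pl);
    # read exclusively by the expert-query oracle
    _vault: dict[str, int] = field(default_factory=dict, repr=False)

    # -- bookkeeping ---------------------------------------------------------
    def sizes(self) -> dict[str, int]:
        return {
            "labeled": len(self.labeled),
            "unlabeled": len(self.unlabeled),
            "pseudo": len(self.pseudo),
            "test": len(self.test),
        }

    @property
    def total(self) -> int:
        return sum(self.sizes().values())

    def check_invariants(self) -> None:
        ids = [list(self.labeled), list(self.unlabeled), list(self.pseudo),
               list(self.test)]
        flat = [i for pool in ids for i in pool]
        if len(flat) != len(set(flat)):
            raise PoolError("pools are not disjoint")
        for sid in self.unlabeled:
            if sid not in self._vault:
                raise PoolError(f"unlabeled sample {sid} missing from label vault")

    # -- oracle access -------------------------------------------------------
    def reveal_true_label(self, sample_id: str) -> int:
        """Expert-oracle read of a hidden true label.

        Only the query step calls this; it is the simulated annotator.
        """
        if sample_id not in self._vault:
            raise PoolError(
                f"no hidden label for {sample_id!r}: the manifest provided no "
                "ground truth for this sample, so only interactive annotation "
                "could label it")
        return self._vault[sample_id]

    def has_hidden_label(self, sample_id: str) -> bool:
        return sample_id in self._vault

    # -- transitions ---------------------------------------------------------
    def move_to_labeled(self, sample_id: str) -> None:
        """Reveal an unlabeled sample's true label and move it to D_l."""
        sample = self.unlabeled.pop(sample_id)
        sample.y = self.reveal_true_label(sample_id)
        sample.label_state = LABELED
        sample.pseudo_round = None
        del self._vault[sample_id]
        self.labeled[sample_id] = sample

    def move_to_pseudo(self, sample_id: str, label: int, round_a: int) -> None:
        sample = self.unlabeled.pop(sample_id)
        sample.y = int(label)
        sample.label_state = PSEUDO
        sample.pseudo_round = round_a
        self.pseudo[sample_id] = sample

    def return_pseudo_to_unlabeled(self, sample_id: str) -> None:
        sample = self.pseudo.pop(sample_id)
        sample.y = None
        sample.label_state = UNLABELED
        sample.pseudo_round = None
        self.unlabeled[sample_id] = sample
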