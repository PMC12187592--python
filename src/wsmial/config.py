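"""Configuration with the published hyperparameter defaults.

The headline knobs default to the printed settings of the method:
K=100 expert queries per round, A=10 rounds, epoch=20 fine-tuning epochs,
initial pseudo-label threshold delta0=0.01 with decay rate dr=0.001,
critic clip Q=0.01, R_n=6 selected instances per image, C=2 classes and
T=2 classification branches. The remaining fields (optimizer, tiny
backbone sizes, synthetic image geometry) are artifact-scale choices
documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


class ConfigError(ValueError):
    pass


@dataclass
class WSMIALConfig:
    # published settings
    K: int = 100                 # expert-query budget per round
    A: int = 10                  # max active-learning rounds
    epoch: int = 20              # fine-tune epochs per round
    delta0: float = 0.01         # initial pseudo-label threshold
    dr: float = 0.001            # threshold decay rate
    Q: float = 0.01              # critic parameter clip bound
    R_n: int = 6                 # selected instances per image
    C: int = 2                   # classes (non-tooth / tooth-marked)
    T: int = 2                   # classification branches
    # discrepancy weight (not printed in the source); chosen so the
    # adversarial game stays in the informative regime at test scale
    beta: float = 0.1
    # reweighting mode for instance uncertainty: max | true_class | l2
    reweight: str = "max"
    # reproducibility
    seed: int = 0
    # geometry
    image_size: int = 64
    downsample: int = 8
    anchors: str = "tiny64"      # anchor preset name
    # tiny backbone + optimizer (test scale)
    feature_dim: int = 32
    hidden_dim: int = 32
    critic_hidden: int = 16
    lr: float = 5e-3
    # small critic step keeps the clipped critic smooth (WGAN practice)
    critic_lr: float = 1e-4
    weight_decay: float = 1e-3
    batch_size: int = 32
    # detection softmax temperature; < 1 sharpens region attention
    det_temp: float = 0.1
    # horizontal-flip augmentation of supervised training images
    flip_augment: bool = True
    # pre-training epochs (Algorithm line 1); defaults to `epoch`
    pretrain_epochs: int | None = None
    # closing fit after the last round; defaults to 3 * epoch
    final_epochs: int | None = None
    # independently initialized detectors averaged per round / closing fit
    n_restarts: int = 2
    final_restarts: int = 3

    def __post_init__(self):
        if self.K < 1 or self.A < 0 or self.epoch < 1:
            raise ConfigError("K, epoch must be >= 1 and A >= 0")
        if self.delta0 < 0 or self.dr < 0 or self.Q <= 0:
            raise ConfigError("delta0, dr must be >= 0 and Q > 0")
        if self.R_n < 1 or self.C < 2 or self.T < 1:
            raise ConfigError("R_n >= 1, C >= 2, T >= 1 required")
        if self.reweight not in ("max", "true_class", "l2"):
            raise ConfigError("reweight must be one of max | true_class | l2")
        if self.image_size % self.downsample != 0:
            raise ConfigError("image_size must be divisible by downsample")

    @property
    def effective_pretrain_epochs(self) -> int:
        return self.epoch if self.pretrain_epochs is None else self.pretrain_epochs

    @property
    def effective_final_epochs(self) -> int:
        return 3 * self.epoch if self.final_epochs is None else self.final_epochs

    @classmethod
    def from_dict(cls, values: dict) -> "WSMIALConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigError(
                f"unknown configuration keys: {sorted(unknown)}")
        return cls(**values)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
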