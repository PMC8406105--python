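"""The stroke-volume regression network.

A 1-D CNN maps a 20-s, 100-Hz arterial pressure segment (length 2000) plus
a 4-element demographic vector to one stroke-volume value (mL). The
feature extractor is a stem of two conv + batch-norm pairs followed by 15
inception modules (4 paths x 32 filters -> 128 channels), with average
pooling after each odd-numbered module shrinking the temporal axis from
2000 to 15 and a global-attention (nonlocal) block placed immediately
before each of the last two inception modules. Global average pooling
yields 128 features, concatenated with the 4 normalised demographics into
a 132-wide vector; the regressor is fully connected 132 -> 64 (batch-norm
after it) -> 1, with 0.5 dropout on the dense layers during training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .layers import (
    AvgPool1d,
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    GlobalAvgPool1d,
    InceptionModule,
    Module,
    NonlocalModule,
    ReLU,
    Sequential,
)
from .types import SEGMENT_LENGTH

__all__ = ["ModelConfig", "SVNet", "build_model", "DemographicNormalizer",
           "save_model", "load_model"]

#: default inception paths: 6 convolutions + 1 pooling layer across 4 paths
DEFAULT_PATHS: list[list[tuple]] = [
    [("pw",)],
    [("conv", 3, 1), ("conv", 3, 1)],
    [("conv", 3, 2), ("conv", 3, 4)],
    [("pool", 2), ("pw",)],
]


@dataclass
class ModelConfig:
    """Architecture parameterisation; the defaults are the full network."""

    input_length: int = SEGMENT_LENGTH
    stem: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(32, 5, 1), (32, 3, 1)]
    )  # (out_channels, kernel, stride)
    n_inception: int = 15
    filters_per_path: int = 32
    inception_paths: list[list[tuple]] = field(
        default_factory=lambda: [list(p) for p in DEFAULT_PATHS]
    )
    pool_after: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13)  # 1-based module index
    pool_rate: int = 2
    nonlocal_before: tuple[int, ...] = (14, 15)
    nonlocal_pool_rate: int = 2
    demo_dim: int = 4
    head_hidden: int = 64
    dropout: float = 0.5

    @property
    def gap_dim(self) -> int:
        return 4 * self.filters_per_path

    @property
    def head_in(self) -> int:
        return self.gap_dim + self.demo_dim

    def validate(self) -> None:
        if len(self.inception_paths) != 4:
            raise ValueError(
                f"configuration error: 4 inception paths required, "
                f"got {len(self.inception_paths)}"
            )
        if self.demo_dim != 4:
            raise ValueError("configuration error: demographic vector has size 4")
        if self.head_in != self.gap_dim + self.demo_dim:
            raise ValueError("configuration error: head input != gap_dim + demo_dim")
        for i in self.pool_after:
            if not 1 <= i <= self.n_inception:
                raise ValueError(f"configuration error: pool position {i} out of range")
        for i in self.nonlocal_before:
            if not 1 <= i <= self.n_inception:
                raise ValueError(
                    f"configuration error: nonlocal position {i} out of range"
                )

    @classmethod
    def reduced(cls) -> "ModelConfig":
        """A small configuration (~9k parameters) for CPU-scale training.

        Dropout is lowered to 0.1: the default 0.5 regularises a
        645k-parameter network with abundant data, and at this scale it
        starves the model instead.
        """
        return cls(
            stem=[(8, 5, 4), (8, 3, 2)],
            n_inception=3,
            filters_per_path=8,
            pool_after=(1, 2, 3),
            pool_rate=2,
            nonlocal_before=(3,),
            nonlocal_pool_rate=2,
            head_hidden=16,
            dropout=0.1,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pool_after"] = list(self.pool_after)
        d["nonlocal_before"] = list(self.nonlocal_before)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["stem"] = [tuple(s) for s in d["stem"]]
        d["inception_paths"] = [
            [tuple(op) for op in path] for path in d["inception_paths"]
        ]
        d["pool_after"] = tuple(d["pool_after"])
        d["nonlocal_before"] = tuple(d["nonlocal_before"])
        return cls(**d)


@dataclass
class DemographicNormalizer:
    """Z-scores age/height/weight; sex stays coded male=1, female=0.

    Constants come from the training corpus and are stored with the model
    so inference is self-contained.
    """

    mean: np.ndarray = field(default_factory=lambda: np.array([60.0, 0.0, 165.0, 65.0]))
    std: np.ndarray = field(default_factory=lambda: np.array([15.0, 1.0, 10.0, 15.0]))

    @classmethod
    def fit(cls, demo: np.ndarray) -> "DemographicNormalizer":
        mean = demo.mean(axis=0)
        std = demo.std(axis=0)
        mean[1], std[1] = 0.0, 1.0  # sex code passes through
        std[std < 1e-8] = 1.0
        return cls(mean=mean, std=std)

    def __call__(self, demo: np.ndarray) -> np.ndarray:
        return (np.asarray(demo, float) - self.mean) / self.std


class SVNet(Module):
    """Feature extractor + demographic-conditioned regressor."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)

        stem_layers: list[Module] = []
        c = 1
        for out_c, k, stride in cfg.stem:
            stem_layers += [
                Conv1d(c, out_c, k, rng, stride=stride,
                       padding="same" if stride == 1 else 0),
                BatchNorm1d(out_c),
                ReLU(),
            ]
            c = out_c
        stem_layers.append(Dropout(cfg.dropout))
        self.stem = Sequential(*stem_layers)

        self.blocks: list[Module] = []
        for i in range(1, cfg.n_inception + 1):
            if i in cfg.nonlocal_before:
                self.blocks.append(
                    NonlocalModule(c, rng, pool_rate=cfg.nonlocal_pool_rate)
                )
            mod = InceptionModule(c, cfg.filters_per_path, cfg.inception_paths, rng)
            self.blocks.append(mod)
            c = mod.out_channels
            if i in cfg.pool_after:
                self.blocks.append(AvgPool1d(cfg.pool_rate))
        assert c == cfg.gap_dim

        self.gap = GlobalAvgPool1d()
        self.head_dropout1 = Dropout(cfg.dropout)
        self.fc1 = Dense(cfg.head_in, cfg.head_hidden, rng)
        self.head_bn = BatchNorm1d(cfg.head_hidden)
        self.head_relu = ReLU()
        self.head_dropout2 = Dropout(cfg.dropout)
        self.fc2 = Dense(cfg.head_hidden, 1, rng)
        self.normalizer = DemographicNormalizer()
        # output affine: the head regresses in target-standardised units and
        # this maps back to mL; constants are fitted from the training split
        self.target_mean = 0.0
        self.target_std = 1.0

    # -- structure ---------------------------------------------------------
    def head_modules(self) -> list[Module]:
        """The regressor part (re-initialised before tuning)."""
        return [self.fc1, self.head_bn, self.fc2]

    def head_parameters(self) -> list[Tensor]:
        out = []
        for m in self.head_modules():
            out.extend(m.parameters())
        return out

    def reinit_head(self, seed: int) -> None:
        """Xavier re-initialisation of the regressor; extractor untouched."""
        rng = np.random.default_rng(seed)
        self.fc1.reinitialize(rng)
        self.fc2.reinitialize(rng)
        self.head_bn.gamma.data[...] = 1.0
        self.head_bn.beta.data[...] = 0.0
        self.head_bn.running_mean[...] = 0.0
        self.head_bn.running_var[...] = 1.0

    def reseed_dropout(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for m in self.modules():
            if isinstance(m, Dropout):
                m.reseed(np.random.default_rng(rng.integers(0, 2**31 - 1)))

    # -- forward -----------------------------------------------------------
    def features(self, segments: Tensor) -> Tensor:
        x = self.stem(segments)
        for block in self.blocks:
            x = block(x)
        return x

    def forward(
        self,
        segments: np.ndarray | Tensor,
        demo: np.ndarray,
        probe: dict | None = None,
    ) -> Tensor:
        """Predict stroke volume (mL) for a batch.

        ``segments`` is [batch, input_length] raw pressure (mmHg), ``demo``
        [batch, 4] raw demographics (normalised internally). When ``probe``
        is a dict it receives the widths of the architecture checkpoints:
        inception output channels, the pre-head concatenation width and the
        head layer widths.
        """
        seg = segments if isinstance(segments, Tensor) else Tensor(segments)
        if seg.ndim != 2 or seg.shape[1] != self.cfg.input_length:
            raise ValueError(
                f"expected segments [batch, {self.cfg.input_length}], got {seg.shape}"
            )
        n = seg.shape[0]
        x = seg.reshape(n, 1, self.cfg.input_length)
        x = self.features(x)
        if probe is not None:
            probe["inception_out_channels"] = x.shape[1]
        feats = self.gap(x)  # [N, gap_dim]
        d = Tensor(self.normalizer(demo))
        z = concat([feats, d], axis=1)
        if probe is not None:
            probe["concat_width"] = z.shape[1]
            probe["head_hidden_width"] = self.fc1.d_out
            probe["output_width"] = self.fc2.d_out
        z = self.head_dropout1(z)
        h = self.head_relu(self.head_bn(self.fc1(z)))
        h = self.head_dropout2(h)
        return self.fc2(h) * self.target_std + self.target_mean

    def predict(self, segments: np.ndarray, demo: np.ndarray) -> np.ndarray:
        """Deterministic inference (dropout off, running batch-norm stats)."""
        was_training = self.training
        self.eval()
        out = self.forward(segments, demo).data[:, 0]
        self.train(was_training)
        return out


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> SVNet:
    """Instantiate the network; weights are reproducible given ``seed``."""
    return SVNet(cfg or ModelConfig(), seed=seed)


# ---------------------------------------------------------------------------
# model bundles: weights + config + normalisation constants


def save_model(model: SVNet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.get_state()
    np.savez_compressed(
        path,
        *state,
        _config=json.dumps(model.cfg.to_dict()),
        _norm_mean=model.normalizer.mean,
        _norm_std=model.normalizer.std,
        _target_affine=np.array([model.target_mean, model.target_std]),
    )


def load_model(path: str | Path) -> SVNet:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig.from_dict(json.loads(str(data["_config"])))
        model = SVNet(cfg, seed=0)
        n = len(model.state_arrays())
        state = [data[f"arr_{i}"] for i in range(n)]
        model.set_state(state)
        model.normalizer = DemographicNormalizer(
            mean=data["_norm_mean"], std=data["_norm_std"]
        )
        model.target_mean, model.target_std = (float(v) for v in data["_target_affine"])
    return model
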