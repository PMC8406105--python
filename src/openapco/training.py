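"""Two-phase transfer-learning harness.

Pretraining fits the network on abundant APCO-device-labelled samples;
tuning then Xavier-re-initialises the regressor head and retrains (all
parameters, extractor included) on scarce PAC-labelled samples. The loss
is root-mean-squared error; optimisation is RAdam wrapped in Lookahead;
validation runs every ``validate_every`` steps on a per-case 30% split,
and when the validation error has not improved for ``patience``
consecutive validations the best weights are restored and training
restarts with the learning rate halved, up to ``max_restarts`` times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .model import DemographicNormalizer, ModelConfig, SVNet, build_model
from .optim import Lookahead, RAdam
from .types import Device, Sample, samples_to_arrays

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "EarlyStopping",
    "rmse_loss",
    "split_validation",
    "fit",
    "pretrain",
    "tune",
]

logger = logging.getLogger(__name__)


def rmse_loss(pred: Tensor | np.ndarray, target: Tensor | np.ndarray) -> Tensor:
    """Root-mean-squared error, sqrt(sum((pred-target)^2)/N)."""
    pred_t = pred if isinstance(pred, Tensor) else Tensor(pred)
    target_t = target if isinstance(target, Tensor) else Tensor(target)
    if pred_t.data.size == 0:
        raise ValueError("empty batch")
    if pred_t.data.size != target_t.data.size:
        raise ValueError("prediction and target lengths differ")
    n = pred_t.data.size
    diff = pred_t.reshape(n) - target_t.reshape(n)
    return ((diff**2).sum() * (1.0 / n)).sqrt()


@dataclass
class TrainConfig:
    batch_size: int = 512
    lr0: float = 1e-3
    lr_decay: float = 0.5
    validate_every: int = 200
    patience: int = 50
    val_frac: float = 0.30
    max_restarts: int = 3
    max_steps: int = 100_000
    lookahead_sync: int = 5
    lookahead_alpha: float = 0.5
    freeze_extractor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_frac < 1:
            raise ValueError("validation fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class ValidationRecord:
    step: int
    train_rmse: float
    val_rmse: float
    lr: float


@dataclass
class TrainHistory:
    records: list[ValidationRecord] = field(default_factory=list)
    best_step: int = 0
    best_val_rmse: float = float("inf")
    restarts: int = 0
    stopped_at_step: int = 0


class EarlyStopping:
    """Patience-with-restarts controller.

    ``update(val)`` returns one of ``"improved"``, ``"continue"``,
    ``"restart"`` (patience exhausted, a restart budget remains: the caller
    restores the best weights and halves the learning rate) or ``"stop"``
    (patience exhausted with no restarts left).
    """

    def __init__(self, patience: int, max_restarts: int):
        self.patience = patience
        self.max_restarts = max_restarts
        self.best = float("inf")
        self.bad = 0
        self.restarts = 0

    def update(self, val_err: float) -> str:
        if val_err < self.best:
            self.best = val_err
            self.bad = 0
            return "improved"
        self.bad += 1
        if self.bad < self.patience:
            return "continue"
        self.bad = 0
        if self.restarts < self.max_restarts:
            self.restarts += 1
            return "restart"
        return "stop"


def split_validation(
    samples: list[Sample], val_frac: float = 0.30, seed: int = 0
) -> tuple[list[Sample], list[Sample]]:
    """Disjoint, exhaustive train/validation split grouped by case.

    All samples of one case land on the same side, so overlapping
    intraoperative segments of a patient can never leak across the split.
    Cases are shuffled by ``seed`` and assigned to validation until its
    share reaches ``val_frac`` (within one case).
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to split")
    by_case: dict[str, list[Sample]] = {}
    for s in samples:
        by_case.setdefault(s.case_id, []).append(s)
    case_ids = sorted(by_case)
    if len(case_ids) < 2:
        raise ValueError("cannot group-split a single case")
    rng = np.random.default_rng(seed)
    rng.shuffle(case_ids)
    target = val_frac * len(samples)
    val_cases: set[str] = set()
    count = 0
    for cid in case_ids:
        if count >= target or len(val_cases) == len(case_ids) - 1:
            break
        val_cases.add(cid)
        count += len(by_case[cid])
    train = [s for s in samples if s.case_id not in val_cases]
    val = [s for s in samples if s.case_id in val_cases]
    return train, val


def _as_batch(arrays: dict, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        arrays["segments"][idx],
        arrays["demographics"][idx],
        arrays["target_sv"][idx],
    )


def fit(
    model: SVNet,
    samples: list[Sample],
    cfg: TrainConfig,
    param_subset: list[Tensor] | None = None,
) -> tuple[SVNet, TrainHistory]:
    """Train ``model`` in place; returns it at its best validation state."""
    if not samples:
        raise ValueError("no training samples")
    train_set, val_set = split_validation(samples, cfg.val_frac, cfg.seed)
    tr = samples_to_arrays(train_set)
    va = samples_to_arrays(val_set)
    model.normalizer = DemographicNormalizer.fit(tr["demographics"])
    model.target_mean = float(tr["target_sv"].mean())
    model.target_std = float(tr["target_sv"].std()) or 1.0

    params = param_subset if param_subset is not None else model.parameters()
    opt = Lookahead(
        RAdam(params, lr=cfg.lr0),
        sync_period=cfg.lookahead_sync,
        alpha=cfg.lookahead_alpha,
    )
    stopper = EarlyStopping(cfg.patience, cfg.max_restarts)
    history = TrainHistory()
    rng = np.random.default_rng(cfg.seed)
    model.reseed_dropout(cfg.seed + 1)
    best_state = model.get_state()

    n = len(train_set)
    batch = min(cfg.batch_size, n)
    model.train()
    step = 0
    while step < cfg.max_steps:
        step += 1
        idx = rng.choice(n, size=batch, replace=False)
        seg, demo, y = _as_batch(tr, idx)
        pred = model.forward(seg, demo)
        loss = rmse_loss(pred, y)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(
                f"non-finite training loss at step {step}; lr={opt.lr:g}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()

        if step % cfg.validate_every == 0:
            val_rmse = _eval_rmse(model, va)
            history.records.append(
                ValidationRecord(step, float(loss.item()), val_rmse, opt.lr)
            )
            action = stopper.update(val_rmse)
            if action == "improved":
                history.best_step = step
                history.best_val_rmse = val_rmse
                best_state = model.get_state()
            elif action == "restart":
                model.set_state(best_state)
                opt.lr = opt.lr * cfg.lr_decay
                opt.sync_state()
                history.restarts += 1
                logger.info("restart %d at step %d, lr -> %g",
                            history.restarts, step, opt.lr)
            elif action == "stop":
                break
            model.train()
    if step > 0 and step % cfg.validate_every != 0:
        # final validation so progress since the last checkpoint can count
        val_rmse = _eval_rmse(model, va)
        history.records.append(
            ValidationRecord(step, float(loss.item()), val_rmse, opt.lr)
        )
        if stopper.update(val_rmse) == "improved":
            history.best_step = step
            history.best_val_rmse = val_rmse
            best_state = model.get_state()
    model.set_state(best_state)
    model.eval()
    history.stopped_at_step = step
    if not history.records:  # zero-step fit: report the untouched model
        history.best_val_rmse = _eval_rmse(model, va)
    return model, history


def _eval_rmse(model: SVNet, arrays: dict, chunk: int = 256) -> float:
    model.eval()
    n = len(arrays["target_sv"])
    preds = np.empty(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        preds[lo:hi] = model.predict(
            arrays["segments"][lo:hi], arrays["demographics"][lo:hi]
        )
    return float(np.sqrt(np.mean((preds - arrays["target_sv"]) ** 2)))


def pretrain(
    cfg_model: ModelConfig,
    apco_samples: list[Sample],
    cfg_train: TrainConfig,
) -> tuple[SVNet, TrainHistory]:
    """Build a fresh model and fit it on APCO-device-labelled samples."""
    if not apco_samples:
        raise ValueError("empty pretraining corpus")
    if any(s.source is not Device.APCO for s in apco_samples):
        raise ValueError("pretraining expects APCO-labelled samples only")
    model = build_model(cfg_model, seed=cfg_train.seed)
    return fit(model, apco_samples, cfg_train)


def tune(
    model: SVNet,
    pac_samples: list[Sample],
    cfg_train: TrainConfig,
) -> tuple[SVNet, TrainHistory]:
    """Transfer step: Xavier-re-init the regressor, retrain on PAC samples.

    The extractor stays trainable unless ``cfg_train.freeze_extractor``.
    """
    if not pac_samples:
        raise ValueError("empty tuning corpus")
    if any(s.source is not Device.PAC for s in pac_samples):
        raise ValueError("tuning expects PAC-labelled samples only")
    model.reinit_head(cfg_train.seed + 17)
    params = None
    if cfg_train.freeze_extractor:
        params = model.head_parameters()
    return fit(model, pac_samples, cfg_train, param_subset=params)
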