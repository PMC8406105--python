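"""Training harness: loss, splits, early-stopping protocol, optimizers."""

import numpy as np
import pytest

import openapco.training as training
from openapco.autodiff import Tensor
from openapco.model import ModelConfig, build_model
from openapco.optim import Lookahead, RAdam
from openapco.training import (
    EarlyStopping,
    TrainConfig,
    fit,
    pretrain,
    rmse_loss,
    split_validation,
    tune,
)
from openapco.types import Demographics, Device, Sample, Sex


def micro_config():
    """A few-thousand-parameter network for protocol tests."""
    return ModelConfig(
        stem=[(4, 5, 8), (4, 3, 2)],
        n_inception=1,
        filters_per_path=4,
        pool_after=(1,),
        pool_rate=4,
        nonlocal_before=(),
        head_hidden=8,
    )


def toy_samples(n_cases=6, per_case=10, source=Device.APCO, seed=0):
    """Segments whose pulse-pressure-like amplitude linearly encodes SV."""
    rng = np.random.default_rng(seed)
    demo = Demographics(60, Sex.MALE, 165, 65)
    out = []
    t = np.arange(2000) / 100.0
    for c in range(n_cases):
        for i in range(per_case):
            sv = rng.uniform(50, 100)
            seg = 80 + 0.5 * sv * 0.5 * (1 + np.cos(2 * np.pi * 1.25 * t))
            seg = seg + rng.normal(0, 0.5, 2000)
            out.append(
                Sample(seg, sv, demo, source, t_start=20.0 * i, case_id=f"c{c}")
            )
    return out


class TestRmseLoss:
    def test_zero_for_perfect_prediction(self):
        y = np.array([60.0, 70.0, 80.0])
        assert rmse_loss(y, y).item() == 0.0

    def test_closed_form(self):
        assert rmse_loss(np.array([3.0, 4.0]), np.zeros(2)).item() == pytest.approx(
            np.sqrt(12.5), rel=1e-6
        )

    def test_single_element_absolute(self):
        assert rmse_loss(np.array([-7.0]), np.array([0.0])).item() == pytest.approx(7.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            rmse_loss(np.array([]), np.array([]))

    def test_gradient_flows(self):
        p = Tensor(np.array([1.0, 2.0]), requires_grad=True)
        loss = rmse_loss(p, np.array([0.0, 0.0]))
        loss.backward()
        assert p.grad is not None and np.all(np.isfinite(p.grad))


class TestSplitValidation:
    def test_group_proportions(self):
        samples = toy_samples(n_cases=10, per_case=30)
        train, val = split_validation(samples, 0.30, seed=1)
        val_cases = {s.case_id for s in val}
        assert len(val_cases) == 3
        assert val_cases.isdisjoint({s.case_id for s in train})
        assert len(train) + len(val) == len(samples)

    def test_reproducible(self):
        samples = toy_samples()
        a = split_validation(samples, 0.3, seed=5)
        b = split_validation(samples, 0.3, seed=5)
        assert [s.case_id for s in a[1]] == [s.case_id for s in b[1]]

    def test_single_case_rejected(self):
        samples = toy_samples(n_cases=1)
        with pytest.raises(ValueError):
            split_validation(samples, 0.3, seed=0)


class TestEarlyStopping:
    @pytest.mark.parametrize("patience", [1, 2, 3])
    def test_restart_fires_exactly_at_patience(self, patience):
        ctl = EarlyStopping(patience=patience, max_restarts=2)
        assert ctl.update(10.0) == "improved"
        actions = [ctl.update(11.0) for _ in range(patience)]
        assert actions[:-1] == ["continue"] * (patience - 1)
        assert actions[-1] == "restart"

    def test_stop_after_budget_exhausted(self):
        ctl = EarlyStopping(patience=1, max_restarts=1)
        ctl.update(10.0)
        assert ctl.update(11.0) == "restart"
        assert ctl.update(12.0) == "stop"

    def test_improvement_resets_patience(self):
        ctl = EarlyStopping(patience=2, max_restarts=0)
        ctl.update(10.0)
        assert ctl.update(11.0) == "continue"
        assert ctl.update(9.0) == "improved"
        assert ctl.update(9.5) == "continue"


class TestFitProtocol:
    def test_worsening_stream_triggers_restart_and_halves_lr(self, monkeypatch):
        stream = iter([10.0, 11.0, 12.0, 13.0, 14.0, 15.0])
        monkeypatch.setattr(training, "_eval_rmse", lambda m, a, chunk=256: next(stream))
        samples = toy_samples(n_cases=4, per_case=5)
        cfg = TrainConfig(batch_size=8, lr0=1e-3, validate_every=5, patience=1,
                          max_restarts=1, max_steps=40, seed=0)
        model = build_model(micro_config(), seed=0)
        model, hist = fit(model, samples, cfg)
        # validation 1 improves, validation 2 triggers the restart
        assert hist.restarts == 1
        assert hist.records[1].lr == pytest.approx(1e-3)
        assert hist.records[2].lr == pytest.approx(5e-4)
        assert hist.best_val_rmse == 10.0

    def test_best_model_never_worse_than_minimum_recorded(self):
        samples = toy_samples(n_cases=4, per_case=8)
        cfg = TrainConfig(batch_size=16, lr0=1e-3, validate_every=10, patience=2,
                          max_restarts=1, max_steps=80, seed=1)
        model, hist = fit(build_model(micro_config(), seed=1), samples, cfg)
        recorded = [r.val_rmse for r in hist.records]
        assert hist.best_val_rmse == min(recorded)

    def test_same_seed_identical_history(self):
        samples = toy_samples(n_cases=4, per_case=8)
        cfg = TrainConfig(batch_size=16, lr0=1e-3, validate_every=10, patience=5,
                          max_restarts=0, max_steps=30, seed=3)
        _, h1 = fit(build_model(micro_config(), seed=2), samples, cfg)
        _, h2 = fit(build_model(micro_config(), seed=2), samples, cfg)
        assert [(r.step, r.train_rmse, r.val_rmse) for r in h1.records] == [
            (r.step, r.train_rmse, r.val_rmse) for r in h2.records
        ]

    def test_loss_decreases_on_fixed_batch(self):
        # median over seeds: short training reduces training loss
        samples = toy_samples(n_cases=4, per_case=8)
        deltas = []
        for seed in range(3):
            cfg = TrainConfig(batch_size=32, lr0=1e-3, validate_every=20,
                              patience=5, max_restarts=0, max_steps=40, seed=seed)
            model, hist = fit(build_model(micro_config(), seed=seed), samples, cfg)
            deltas.append(hist.records[-1].train_rmse - hist.records[0].train_rmse)
        assert np.median(deltas) < 0


class TestTransferContracts:
    def test_pretrain_rejects_mixed_sources(self):
        samples = toy_samples(n_cases=2, source=Device.APCO) + toy_samples(
            n_cases=2, source=Device.PAC, seed=1
        )
        with pytest.raises(ValueError, match="APCO"):
            pretrain(micro_config(), samples, TrainConfig(max_steps=1))

    def test_pretrain_rejects_empty(self):
        with pytest.raises(ValueError):
            pretrain(micro_config(), [], TrainConfig(max_steps=1))

    def test_tune_reinitializes_head_before_any_step(self):
        model = build_model(micro_config(), seed=4)
        before = model.fc1.weight.data.copy()
        samples = toy_samples(n_cases=3, source=Device.PAC)
        cfg = TrainConfig(batch_size=8, validate_every=10, max_steps=0, seed=0)
        model, _ = tune(model, samples, cfg)
        assert not np.allclose(model.fc1.weight.data, before)

    def test_tune_trains_extractor_unless_frozen(self):
        samples = toy_samples(n_cases=3, source=Device.PAC)
        for freeze in (False, True):
            model = build_model(micro_config(), seed=5)
            stem_before = model.stem.layers[0].weight.data.copy()
            cfg = TrainConfig(batch_size=8, validate_every=50, patience=5,
                              max_steps=30, seed=0, freeze_extractor=freeze)
            model, _ = tune(model, samples, cfg)
            changed = not np.allclose(model.stem.layers[0].weight.data, stem_before)
            assert changed != freeze

    def test_tune_rejects_apco_samples(self):
        model = build_model(micro_config(), seed=6)
        with pytest.raises(ValueError, match="PAC"):
            tune(model, toy_samples(n_cases=2, source=Device.APCO),
                 TrainConfig(max_steps=1))


class TestOptimizers:
    def test_radam_lookahead_minimize_quadratic(self):
        # the rectification warmup keeps early effective steps small, so
        # give the optimizer a realistic budget
        x = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Lookahead(RAdam([x], lr=0.2))
        for _ in range(600):
            loss = (x**2).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.all(np.abs(x.data) < 0.1)

    def test_lookahead_sync_pulls_fast_toward_slow(self):
        # constant unit gradient; RAdam warmup steps move x by exactly lr,
        # so after 2 inner steps x = 0 and the sync interpolates to
        # slow + alpha * (fast - slow) = 1 + 0.5 * (0 - 1) = 0.5
        x = Tensor(np.array([1.0]), requires_grad=True)
        opt = Lookahead(RAdam([x], lr=0.5), sync_period=2, alpha=0.5)
        for _ in range(2):
            loss = (x * 1.0).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert float(x.data[0]) == pytest.approx(0.5, abs=1e-9)
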