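"""Split bookkeeping, LR schedules, and the two-phase training protocol."""

import numpy as np
import pytest

from connfusion.dataio import SubjectRecord, labels_to_indices
from connfusion.errors import DivergenceError, ValidationError
from connfusion.models import (MLPConfig, ResNetConfig, build_mlp,
                               build_resnet3d)
from connfusion.training import (PHASE1_MLP, PHASE1_RESNET, PHASE2_MULTIMODAL,
                                 SplitPlan, TrainConfig, lr_at_epoch,
                                 split_dataset, train_phase1_mlp,
                                 train_phase1_resnet,
                                 train_phase2_multimodal)


def _records(n):
    return [SubjectRecord(f"s{i:04d}", f"v{i}.nii.gz",
                          "ASD" if i % 2 else "control") for i in range(n)]


class TestSplit:
    def test_partition_property(self):
        plan = split_dataset(_records(10), n_train=8, seed=5)
        assert len(plan.train_ids) == 8 and len(plan.test_ids) == 2
        assert set(plan.train_ids).isdisjoint(plan.test_ids)
        assert set(plan.train_ids) | set(plan.test_ids) == {
            f"s{i:04d}" for i in range(10)}

    def test_seeded_determinism(self):
        a = split_dataset(_records(30), n_train=20, seed=9)
        b = split_dataset(_records(30), n_train=20, seed=9)
        assert a == b
        c = split_dataset(_records(30), n_train=20, seed=10)
        assert a != c

    def test_persistence_roundtrip(self, tmp_path):
        plan = split_dataset(_records(12), n_train=9, seed=1)
        plan.to_json(tmp_path / "split.json")
        assert SplitPlan.from_json(tmp_path / "split.json") == plan

    def test_stratified_option_balances_classes(self):
        plan = split_dataset(_records(40), n_train=30, seed=2, stratified=True)
        train_labels = [int(s[1:]) % 2 for s in plan.train_ids]
        assert abs(sum(train_labels) - 15) <= 1

    def test_rejects_degenerate_sizes(self):
        with pytest.raises(ValidationError):
            split_dataset(_records(10), n_train=10, seed=0)
        with pytest.raises(ValidationError):
            split_dataset(_records(10), n_train=0, seed=0)


class TestLRSchedule:
    @pytest.mark.parametrize("epoch, expected", [
        (0, 1e-2), (5, 1e-2), (6, 1e-3), (11, 1e-3), (12, 1e-4), (29, 1e-6),
    ])
    def test_resnet_schedule(self, epoch, expected):
        assert lr_at_epoch(1e-2, epoch, 6, 0.1) == pytest.approx(expected)

    def test_closed_form_over_full_horizons(self):
        for base, step, epochs in ((1e-2, 6, 30), (1e-2, 5, 50), (1e-5, 8, 30)):
            for epoch in range(epochs):
                assert lr_at_epoch(base, epoch, step, 0.1) == pytest.approx(
                    base * 0.1 ** (epoch // step))

    def test_phase_defaults_match_protocol(self):
        assert (PHASE1_RESNET.base_lr, PHASE1_RESNET.epochs,
                PHASE1_RESNET.lr_step) == (1e-2, 30, 6)
        assert (PHASE1_MLP.base_lr, PHASE1_MLP.epochs,
                PHASE1_MLP.lr_step) == (1e-2, 50, 5)
        assert (PHASE2_MULTIMODAL.base_lr, PHASE2_MULTIMODAL.epochs,
                PHASE2_MULTIMODAL.lr_step) == (1e-5, 30, 8)


def _separable_vectors(n=24, dim=12, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    x = rng.normal(scale=0.3, size=(n, dim)).astype(np.float32)
    x[:, 0] += np.where(y == 1, 2.0, -2.0)
    return x, y.astype(np.int64)


class TestPhase1:
    def test_mlp_fits_separable_data(self):
        x, y = _separable_vectors()
        mlp = build_mlp(MLPConfig(in_features=x.shape[1]), seed=0)
        mlp, hist = train_phase1_mlp(
            mlp, x, y, TrainConfig(base_lr=1e-2, epochs=15, lr_step=5, seed=0))
        assert len(hist.loss_history) == 15
        assert hist.accuracy_history[-1] >= 0.95
        # loss should broadly decrease on this easy problem
        assert hist.loss_history[-1] < hist.loss_history[0]
        drops = sum(b <= a + 1e-9 for a, b in zip(hist.loss_history,
                                                  hist.loss_history[1:]))
        assert drops >= 0.7 * (len(hist.loss_history) - 1)

    def test_resnet_fits_separable_fingerprints(self, tiny_cohort, tiny_features):
        fps, _, labels = tiny_features
        y = labels_to_indices(labels)
        net = build_resnet3d(
            ResNetConfig(in_channels=tiny_cohort.atlas.n_regions), seed=0)
        net, hist = train_phase1_resnet(
            net, fps, y, TrainConfig(base_lr=1e-2, epochs=6, lr_step=6, seed=0))
        assert len(hist.loss_history) == 6
        assert hist.accuracy_history[-1] >= 0.9

    def test_zero_lr_leaves_weights_unchanged(self):
        x, y = _separable_vectors()
        mlp = build_mlp(MLPConfig(in_features=x.shape[1]), seed=1)
        before = {k: v.copy() for k, v in mlp.state_dict().items()}
        train_phase1_mlp(mlp, x, y,
                         TrainConfig(base_lr=0.0, epochs=3, lr_step=5, seed=0))
        after = mlp.state_dict()
        for key in before:
            if key.endswith("running_mean") or key.endswith("running_var"):
                continue
            np.testing.assert_array_equal(after[key], before[key], err_msg=key)

    def test_empty_training_set_rejected(self):
        mlp = build_mlp(MLPConfig(in_features=4), seed=0)
        with pytest.raises(ValidationError):
            train_phase1_mlp(mlp, np.zeros((0, 4), dtype=np.float32),
                             np.zeros(0, dtype=np.int64))

    def test_divergence_reports_epoch(self):
        x, y = _separable_vectors()
        mlp = build_mlp(MLPConfig(in_features=x.shape[1]), seed=0)
        with pytest.raises(DivergenceError) as err:
            train_phase1_mlp(mlp, x * 1e4, y,
                             TrainConfig(base_lr=1e12, epochs=5, lr_step=5,
                                         seed=0))
        assert err.value.epoch < 5

    def test_fixed_seed_reproduces_final_weights(self):
        x, y = _separable_vectors()
        results = []
        for _ in range(2):
            mlp = build_mlp(MLPConfig(in_features=x.shape[1]), seed=3)
            mlp, _ = train_phase1_mlp(
                mlp, x, y, TrainConfig(base_lr=1e-2, epochs=5, lr_step=5,
                                       seed=3))
            results.append(mlp.state_dict())
        for key in results[0]:
            np.testing.assert_array_equal(results[0][key], results[1][key],
                                          err_msg=key)


class TestPhase2:
    def test_encoders_initialised_from_phase1_bit_exactly(self, tiny_cohort,
                                                          tiny_features):
        fps, vecs, labels = tiny_features
        y = labels_to_indices(labels)
        n = tiny_cohort.atlas.n_regions
        resnet = build_resnet3d(ResNetConfig(in_channels=n), seed=0)
        mlp = build_mlp(MLPConfig(in_features=vecs.shape[1]), seed=1)
        resnet, _ = train_phase1_resnet(
            resnet, fps, y, TrainConfig(base_lr=1e-2, epochs=2, lr_step=6,
                                        seed=2))
        mlp, _ = train_phase1_mlp(
            mlp, vecs, y, TrainConfig(base_lr=1e-2, epochs=2, lr_step=5,
                                      seed=3))
        phase1_resnet = {k: v.copy() for k, v in resnet.state_dict().items()}
        phase1_mlp = {k: v.copy() for k, v in mlp.state_dict().items()}
        # zero LR so the fused weights stay at their initial values: this
        # exposes the initialisation, which must equal the Phase-I weights
        fused, hist = train_phase2_multimodal(
            resnet, mlp, None, fps, vecs, y,
            TrainConfig(base_lr=0.0, epochs=1, lr_step=8, seed=4))
        for key, arr in phase1_resnet.items():
            if "running" in key:
                continue
            np.testing.assert_array_equal(fused.resnet.state_dict()[key], arr,
                                          err_msg=key)
        for key, arr in phase1_mlp.items():
            if "running" in key:
                continue
            np.testing.assert_array_equal(fused.mlp.state_dict()[key], arr,
                                          err_msg=key)
        # and the Phase-I networks themselves are untouched by fusion
        for key, arr in resnet.state_dict().items():
            np.testing.assert_array_equal(phase1_resnet[key], arr)
        assert hist.lr_history == [0.0]

    def test_schedule_follows_lr_at_epoch(self, tiny_features):
        fps, vecs, labels = tiny_features
        y = labels_to_indices(labels)
        resnet = build_resnet3d(ResNetConfig(in_channels=fps.shape[1]), seed=0)
        mlp = build_mlp(MLPConfig(in_features=vecs.shape[1]), seed=1)
        cfg = TrainConfig(base_lr=1e-3, epochs=10, lr_step=4, seed=0)
        _, hist = train_phase2_multimodal(resnet, mlp, None, fps, vecs, y, cfg)
        expected = [lr_at_epoch(1e-3, e, 4, 0.1) for e in range(10)]
        assert hist.lr_history == pytest.approx(expected)
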