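"""Loss oracles, augmentation, leakage audit, and training-loop mechanics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from scprofile.autodiff import Tensor
from scprofile.sequence import one_hot, rc_one_hot
from scprofile.training import (
    LossConfig,
    TrainConfig,
    audit_leakage,
    augment,
    exclude_leaky_features,
    filter_rare_features,
    poisson_multinomial_loss,
    train,
    window_targets,
)


class TestLoss:
    def test_zero_target_reduces_to_scaled_poisson(self):
        # target all-zero: multinomial term vanishes, Poisson term is the
        # predicted total divided by the bin count (times the weight)
        pred = np.full((2, 8, 1), 0.5)
        cfg = LossConfig(poisson_weight=1.0, epsilon=0.0)
        loss = float(poisson_multinomial_loss(pred, np.zeros((2, 8, 1)), cfg).data)
        expected = (pred.sum(axis=1) / 8).mean()
        assert loss == pytest.approx(expected, rel=1e-6)

    def test_closed_form_small_example(self):
        # hand-computed NLL with log-gamma terms on a 5-bin example
        r = np.random.default_rng(0)
        pred = r.uniform(0.5, 3.0, (1, 5, 1))
        target = r.poisson(2.0, (1, 5, 1)).astype(float)
        cfg = LossConfig(poisson_weight=0.7, epsilon=0.0)
        got = float(poisson_multinomial_loss(pred, target, cfg).data)
        P, T = pred.sum(), target.sum()
        poisson = P - T * np.log(P) + gammaln(T + 1)
        p = pred[0, :, 0] / P
        multinomial = -(target[0, :, 0] * np.log(p)).sum() - (
            gammaln(T + 1) - gammaln(target + 1).sum()
        )
        expected = 0.7 * poisson / 5 + multinomial
        assert got == pytest.approx(float(expected), rel=1e-4)

    def test_gradient_near_zero_at_match(self):
        # at pred == target both terms are stationary (up to epsilon)
        r = np.random.default_rng(1)
        target = r.uniform(1.0, 5.0, (2, 6, 2))
        pred = Tensor(target.copy(), requires_grad=True)
        loss = poisson_multinomial_loss(pred, target, LossConfig(1.0, 1e-12))
        loss.backward()
        assert np.max(np.abs(pred.grad)) < 1e-4

    def test_differentiable_and_matches_finite_differences(self):
        r = np.random.default_rng(2)
        target = r.poisson(3.0, (1, 4, 1)).astype(float)
        base = r.uniform(1.0, 2.0, (1, 4, 1))
        cfg = LossConfig(0.5, 1e-9)
        pred = Tensor(base.copy(), requires_grad=True)
        poisson_multinomial_loss(pred, target, cfg).backward()
        eps = 1e-4
        for i in range(4):
            up, down = base.copy(), base.copy()
            up[0, i, 0] += eps
            down[0, i, 0] -= eps
            fd = (float(poisson_multinomial_loss(up, target, cfg).data)
                  - float(poisson_multinomial_loss(down, target, cfg).data)) / (2 * eps)
            # float32 engine: finite differences agree to a few percent
            assert pred.grad[0, i, 0] == pytest.approx(fd, rel=8e-2, abs=2e-3)

    def test_negative_prediction_rejected(self):
        with pytest.raises(ValueError):
            poisson_multinomial_loss(-np.ones((1, 2, 1)), np.ones((1, 2, 1)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            poisson_multinomial_loss(np.ones((1, 2, 1)), np.ones((1, 3, 1)))


class TestAugment:
    def setup_method(self):
        r = np.random.default_rng(0)
        self.seq = one_hot("".join(r.choice(list("ACGT"), 128)))
        self.targets = {
            "rna": r.poisson(2, (3, 4, 2)).astype(float),
            "atac": r.poisson(2, (3, 4, 1)).astype(float),
        }

    def test_identity_without_shift_or_rc(self):
        class NoRC:
            def integers(self, *a, **k):
                return 0

            def random(self):
                return 1.0  # never below the RC probability

        seq, tg = augment(self.seq, self.targets, NoRC())
        np.testing.assert_array_equal(seq, self.seq)
        for k in tg:
            np.testing.assert_array_equal(tg[k], self.targets[k])

    def test_rc_twice_is_involution(self):
        class AlwaysRC:
            def integers(self, *a, **k):
                return 0

            def random(self):
                return 0.0

        seq1, tg1 = augment(self.seq, self.targets, AlwaysRC())
        seq2, tg2 = augment(seq1, tg1, AlwaysRC())
        np.testing.assert_array_equal(seq2, self.seq)
        for k in tg2:
            np.testing.assert_array_equal(tg2[k], self.targets[k])

    def test_rc_swaps_rna_strands_and_flips_bins(self):
        class AlwaysRC:
            def integers(self, *a, **k):
                return 0

            def random(self):
                return 0.0

        seq, tg = augment(self.seq, self.targets, AlwaysRC())
        np.testing.assert_array_equal(seq, rc_one_hot(self.seq))
        np.testing.assert_array_equal(
            tg["rna"], self.targets["rna"][:, ::-1, ::-1]
        )
        np.testing.assert_array_equal(
            tg["atac"], self.targets["atac"][:, ::-1, :]
        )

    def test_strand_symmetric_profile_invariant_under_rc(self):
        # palindromic profile with mirrored strands is an RC fixed point
        base = np.arange(8.0).reshape(1, 4, 2)
        sym = base.copy()
        sym[..., 1] = base[::, ::-1, 0]  # minus strand mirrors plus
        targets = {"rna": sym}

        class AlwaysRC:
            def integers(self, *a, **k):
                return 0

            def random(self):
                return 0.0

        _, tg = augment(self.seq, targets, AlwaysRC())
        np.testing.assert_array_equal(tg["rna"], sym)

    def test_shift_refetches_through_callback(self):
        calls = []

        def refetch(shift):
            calls.append(shift)
            return self.seq, self.targets

        class Shift2:
            def integers(self, lo, hi):
                return 2

            def random(self):
                return 1.0

        augment(self.seq, self.targets, Shift2(), shift_max=3, refetch=refetch)
        assert calls == [2]


class TestLeakage:
    REGIONS = [("chr1", 0, 100, "r1", "train"),
               ("chr1", 200, 300, "r2", "valid"),
               ("chr2", 0, 100, "r3", "test")]

    def test_audit_finds_overlaps(self):
        features = [("chr1", 250, 260, "peakA"),  # in valid
                    ("chr1", 50, 60, "peakB"),  # train only
                    ("chr2", 90, 150, "peakC")]  # straddles test
        leaky = audit_leakage(features, self.REGIONS)
        assert {f[3] for f in leaky} == {"peakA", "peakC"}

    def test_exclusion_removes_only_leaky(self):
        features = [("chr1", 250, 260, "peakA"), ("chr1", 50, 60, "peakB")]
        kept = exclude_leaky_features(features, self.REGIONS)
        assert [f[3] for f in kept] == ["peakB"]

    def test_rare_feature_filter(self):
        m = pd.DataFrame(np.zeros((200, 3)), columns=["a", "b", "c"])
        m.loc[:3, "a"] = 1.0  # 2% of cells
        m.loc[0, "b"] = 1.0  # 0.5%
        m["c"] = 1.0
        out = filter_rare_features(m, min_cell_fraction=0.01)
        assert list(out.columns) == ["a", "c"]


@pytest.fixture(scope="module")
def tiny_training_setup():
    from scprofile.backbone import EncoderConfig
    from scprofile.model import ModelConfig, ProfileModel
    from scprofile.simulate import (SimConfig, generate_world,
                                    simulate_atac_fragments,
                                    simulate_rna_fragments)

    world = generate_world(SimConfig(
        seed=21, n_chroms=3, chrom_length=32_768, n_genes=9, n_cells=40,
        n_variant_genes=0,
    ))
    stores = {
        "rna": simulate_rna_fragments(world, 60, seed=1),
        "atac": simulate_atac_fragments(world, 120, seed=2),
    }
    model = ProfileModel(ModelConfig(
        encoder=EncoderConfig(input_length=8192, channels=16,
                              n_transformer_layers=1, seed=0),
        embedding_dim=world.config.embedding_dim,
        seed=0,
    ))
    return world, stores, model


class TestTrainLoop:
    def test_zero_lr_leaves_parameters_bitwise_unchanged(self, tiny_training_setup):
        world, stores, model = tiny_training_setup
        before = {k: v.copy() for k, v in model.state_dict().items()}
        cfg = TrainConfig(batch_sequences=2, cells_per_sequence=4, epochs=1,
                          lr_decoder=0.0, lr_lora_and_head=0.0,
                          warmup_steps=0, seed=0)
        train(model, world.genome, world.genes, stores,
              world.cells.embedding, world.splits, cfg,
              labels=world.cells.labels)
        after = model.state_dict()
        for k in before:
            assert np.array_equal(before[k], after[k]), k

    def test_loss_decreases_on_toy_fixture(self, tiny_training_setup):
        world, stores, model = tiny_training_setup
        cfg = TrainConfig(batch_sequences=2, cells_per_sequence=8, epochs=14,
                          warmup_steps=10, lr_decoder=4e-3,
                          lr_lora_and_head=2e-3, seed=0,
                          shift_max=0, rc_augment=False)
        res = train(model, world.genome, world.genes, stores,
                    world.cells.embedding, world.splits, cfg,
                    labels=None)
        losses = np.array([r["loss"] for r in res.log])
        w = 10
        windows = [losses[i:i + w].mean() for i in range(0, len(losses) - w, w)]
        drops = sum(b < a for a, b in zip(windows[:-1], windows[1:]))
        assert drops / (len(windows) - 1) >= 0.6
        assert windows[-1] < windows[0] * 0.8

    def test_checkpoint_selection_is_argmax_of_validation(self, tiny_training_setup):
        world, stores, model = tiny_training_setup
        cfg = TrainConfig(batch_sequences=2, cells_per_sequence=4, epochs=3,
                          warmup_steps=2, seed=1)
        res = train(model, world.genome, world.genes, stores,
                    world.cells.embedding, world.splits, cfg,
                    labels=world.cells.labels)
        metrics = np.array([v["metric"] for v in res.val_log])
        if np.isfinite(metrics).any():
            assert res.best_epoch == int(np.nanargmax(metrics))
            assert res.best_metric == pytest.approx(np.nanmax(metrics))
        else:
            assert res.best_epoch == -1

    def test_empty_split_rejected(self, tiny_training_setup):
        world, stores, model = tiny_training_setup
        cfg = TrainConfig(epochs=1, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, world.genome, world.genes, stores,
                  world.cells.embedding, {g.name: "test" for g in world.genes},
                  cfg)

    def test_gradients_reach_only_adapters_head_and_hypernets(self):
        from scprofile.backbone import EncoderConfig
        from scprofile.model import ModelConfig, ProfileModel
        from scprofile.lora import lora_parameters

        model = ProfileModel(ModelConfig(
            encoder=EncoderConfig(input_length=2048, channels=16,
                                  n_transformer_layers=1, seed=0),
            embedding_dim=4, seed=0,
        ))
        model.add_adapters()
        r = np.random.default_rng(0)
        x = one_hot("".join(r.choice(list("ACGT"), 2048)))
        out = model.forward_cells(x, r.normal(size=(2, 4)))
        loss = poisson_multinomial_loss(
            out["rna"], np.abs(r.normal(size=out["rna"].shape))
        )
        loss.backward()
        allowed = {id(p) for p in lora_parameters(model.encoder)}
        allowed |= {id(p) for p in model.head.parameters()}
        allowed |= {id(p) for p in model.hypernet_rna.parameters()}
        allowed |= {id(p) for p in model.hypernet_atac.parameters()}
        for name, p in model.encoder.named_parameters():
            if id(p) not in allowed:
                assert p.grad is None, name

    def test_fixed_seed_reproducible_loss_trajectory(self, tiny_training_setup):
        world, stores, _ = tiny_training_setup
        from scprofile.backbone import EncoderConfig
        from scprofile.model import ModelConfig, ProfileModel

        losses = []
        for _ in range(2):
            model = ProfileModel(ModelConfig(
                encoder=EncoderConfig(input_length=8192, channels=16,
                                      n_transformer_layers=1, seed=5),
                embedding_dim=world.config.embedding_dim, seed=5,
            ))
            cfg = TrainConfig(batch_sequences=2, cells_per_sequence=4,
                              epochs=2, warmup_steps=2, seed=3)
            res = train(model, world.genome, world.genes, stores,
                        world.cells.embedding, world.splits, cfg)
            losses.append([r["loss"] for r in res.log])
        assert losses[0] == losses[1]
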