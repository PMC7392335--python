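import numpy as np
import pytest
from scipy import stats as sps

from dualgenome.model import build_model, toy_config
from dualgenome.prep import TrainingExample, encode_sequence
from dualgenome.training import (TrainConfig, augment_example, augmentation_cycle,
                                 crop_center, evaluate, fine_tune, pearson,
                                 poisson_loss, poisson_loss_grad,
                                 sample_genome_batches, train)


class TestPoissonLoss:
    def test_target_zero_pred_one(self):
        assert poisson_loss(np.array([1.0]), np.array([0.0])) == pytest.approx(1.0)

    def test_pred_equals_target_closed_form(self):
        y = np.array([2.0, 5.0, 0.5])
        expected = np.mean(y - y * np.log(y))
        assert poisson_loss(y, y) == pytest.approx(expected)

    def test_minimized_at_target(self):
        y = np.array([3.0, 7.0])
        base = poisson_loss(y, y)
        for eps in (0.01, -0.01):
            assert poisson_loss(y + eps, y) > base

    def test_nonpositive_pred_raises(self):
        with pytest.raises(ValueError, match="positive"):
            poisson_loss(np.array([0.0]), np.array([1.0]))

    def test_grad_matches_finite_difference(self, rng):
        pred = rng.gamma(2.0, 1.0, size=(3, 4)) + 0.1
        target = rng.gamma(2.0, 1.0, size=(3, 4))
        g = poisson_loss_grad(pred, target)
        eps = 1e-5
        for idx in [(0, 0), (2, 3)]:
            p = pred.copy()
            p[idx] += eps
            up = poisson_loss(p, target)
            p[idx] -= 2 * eps
            down = poisson_loss(p, target)
            assert g[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-3)


class TestCropCenter:
    def test_full_scale_arithmetic(self):
        x = np.zeros((1024, 3))
        out = crop_center(x, 896)
        assert out.shape == (896, 3)

    def test_identity(self, rng):
        x = rng.random((64, 2))
        np.testing.assert_array_equal(crop_center(x, 64), x)

    def test_matches_slice_oracle(self, rng):
        x = rng.random((2, 32, 3))
        np.testing.assert_array_equal(crop_center(x, 24), x[:, 4:28, :])

    def test_odd_remainder_raises(self):
        with pytest.raises(ValueError):
            crop_center(np.zeros((10, 1)), 7)


def _make_example(rng, L=64, n_bins=16, n_tasks=2, genome_id="A"):
    seq = "".join(rng.choice(list("ACGT"), size=L))
    return TrainingExample(
        sequence=encode_sequence(seq),
        targets=rng.random((n_bins, n_tasks)).astype(np.float32),
        genome_id=genome_id, split="train", chrom="chr1", start=100, end=100 + L,
    )


class TestAugment:
    def test_rc_twice_is_identity(self, rng):
        ex = _make_example(rng)
        back = augment_example(augment_example(ex, True, 0), True, 0)
        np.testing.assert_array_equal(back.sequence, ex.sequence)
        np.testing.assert_array_equal(back.targets, ex.targets)

    def test_identity_augment(self, rng):
        ex = _make_example(rng)
        out = augment_example(ex, False, 0)
        np.testing.assert_array_equal(out.sequence, ex.sequence)

    def test_rc_reverses_targets(self, rng):
        ex = _make_example(rng)
        out = augment_example(ex, True, 0)
        np.testing.assert_array_equal(out.targets, ex.targets[::-1])

    def test_shift_moves_window_with_uniform_fill(self, rng):
        ex = _make_example(rng)
        out = augment_example(ex, False, 2)
        np.testing.assert_array_equal(out.sequence[:, :-2], ex.sequence[:, 2:])
        np.testing.assert_array_equal(out.sequence[:, -2:], 0.25)
        np.testing.assert_array_equal(out.targets, ex.targets)

    def test_shift_with_genome_fetches_flank(self, rng, tmp_path):
        from dualgenome import io

        seq = "".join(rng.choice(list("ACGT"), size=300))
        io.write_fasta(str(tmp_path / "g.fa"), {"chr1": seq})
        fa = io.read_fasta(str(tmp_path / "g.fa"))
        ex = TrainingExample(encode_sequence(seq[100:164]),
                             rng.random((16, 1)).astype(np.float32),
                             "A", "train", "chr1", 100, 164)
        out = augment_example(ex, False, 3, genome=fa)
        np.testing.assert_array_equal(out.sequence, encode_sequence(seq[103:167]))

    def test_shift_off_contig_raises(self, rng, tmp_path):
        from dualgenome import io

        seq = "".join(rng.choice(list("ACGT"), size=64))
        io.write_fasta(str(tmp_path / "g.fa"), {"chr1": seq})
        fa = io.read_fasta(str(tmp_path / "g.fa"))
        ex = TrainingExample(encode_sequence(seq), rng.random((16, 1)).astype(np.float32),
                             "A", "train", "chr1", 0, 64)
        with pytest.raises(ValueError, match="off contig"):
            augment_example(ex, False, -1, genome=fa)

    def test_cycle_covers_all_combinations(self):
        combos = augmentation_cycle(3, True)
        assert len(combos) == 14
        assert set(combos) == {(rc, s) for rc in (False, True) for s in range(-3, 4)}


class TestGenomeBatches:
    def test_printed_proportions(self):
        # 38.2k human / 33.5k mouse -> P(A) = 0.533
        counts = {"A": 38_200, "B": 33_500}
        gen = sample_genome_batches(counts, seed=0)
        draws = [next(gen) for _ in range(100_000)]
        frac_a = draws.count("A") / len(draws)
        p = 38_200 / 71_700
        sigma = np.sqrt(p * (1 - p) / len(draws))
        assert abs(frac_a - p) < 3 * sigma

    def test_zero_count_genome_never_drawn(self):
        gen = sample_genome_batches({"A": 10, "B": 0}, seed=1)
        assert {next(gen) for _ in range(100)} == {"A"}

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            next(sample_genome_batches({"A": 0, "B": 0}, seed=0))


@pytest.fixture()
def tiny_setup(rng):
    cfg = toy_config(seq_len=256, tower_blocks=2, dilated_blocks=2, filters=6,
                     heads={"A": 2, "B": 2}, seed=0)
    model = build_model(cfg)
    n_bins = cfg.n_bins
    examples = {
        g: [_make_example(rng, L=256, n_bins=n_bins, n_tasks=2, genome_id=g)
            for _ in range(6)]
        for g in "AB"
    }
    valid = {
        g: [_make_example(rng, L=256, n_bins=n_bins, n_tasks=2, genome_id=g)
            for _ in range(2)]
        for g in "AB"
    }
    return model, examples, valid


class TestTrain:
    def test_patience_zero_stops_after_first_non_improvement(self, tiny_setup):
        model, examples, valid = tiny_setup
        cfg = TrainConfig(seed=0, lr=1e-4, max_epochs=50, shift_max=1)
        history = train(model, examples, valid, cfg, patience=0)
        frame = history.to_frame()
        mixed = frame[(frame.split == "valid") & (frame.genome == "mixed")]
        best = frame[frame.split == "best"].iloc[0]
        # stopped exactly one epoch after the last improvement
        assert mixed.epoch.max() == best.epoch + 1 or mixed.epoch.max() == 49

    def test_identical_seeds_identical_history(self, rng):
        histories = []
        for _ in range(2):
            cfg_m = toy_config(seq_len=256, tower_blocks=2, dilated_blocks=2,
                               filters=6, heads={"A": 2}, seed=3)
            model = build_model(cfg_m)
            local = np.random.default_rng(42)
            examples = {"A": [_make_example(local, 256, 64, 2) for _ in range(4)]}
            valid = {"A": [_make_example(local, 256, 64, 2) for _ in range(2)]}
            cfg = TrainConfig(seed=9, lr=1e-3, max_epochs=3, shift_max=1)
            histories.append(train(model, examples, valid, cfg, patience=5).to_frame())
        assert histories[0].equals(histories[1])

    def test_convergence_to_constant_target(self, rng):
        # single constant-target dataset: predictions approach the Poisson
        # optimum (the constant itself)
        cfg_m = toy_config(seq_len=256, tower_blocks=2, dilated_blocks=2,
                           filters=6, heads={"A": 1}, seed=1,
                           residual_dropout=0.0, final_dropout=0.0)
        model = build_model(cfg_m)
        target_value = 3.0
        examples = []
        for _ in range(4):
            ex = _make_example(rng, 256, 64, 1)
            ex.targets[...] = target_value
            examples.append(ex)
        cfg = TrainConfig(seed=0, lr=0.02, momentum=0.9, max_epochs=30,
                          shift_max=0, rc_augment=False, crop_keep=64)
        train(model, {"A": examples}, {"A": examples[:1]}, cfg, patience=30)
        pred = model.forward(examples[0].sequence[None], "A")
        assert pred.mean() == pytest.approx(target_value, rel=0.2)

    def test_loss_monotone_at_small_lr_on_fixed_batch(self, rng):
        from dualgenome.model import build_model, toy_config
        from dualgenome.nn import SGD
        from dualgenome.training import poisson_loss, poisson_loss_grad

        cfg = toy_config(seq_len=256, tower_blocks=2, dilated_blocks=2,
                         filters=6, heads={"A": 2}, seed=2,
                         residual_dropout=0.0, final_dropout=0.0)
        model = build_model(cfg)
        x = np.stack([_make_example(rng, 256, 64, 2).sequence for _ in range(4)])
        t = np.stack([rng.gamma(2.0, 1.0, (64, 2)).astype(np.float32)
                      for _ in range(4)])
        opt = SGD(lr=1e-4, momentum=0.0)
        losses = []
        for _ in range(6):
            pred = model.forward(x, "A", train=True)
            losses.append(poisson_loss(pred, t))
            model.zero_grad()
            model.backward(poisson_loss_grad(pred, t), "A")
            opt.step(model.step_params("A"))
        assert all(b <= a + 1e-7 for a, b in zip(losses, losses[1:]))

    def test_divergence_aborts(self, tiny_setup):
        model, examples, valid = tiny_setup
        for ex in examples["A"]:
            ex.targets[...] = 1e30  # force immediate non-finite loss
        cfg = TrainConfig(seed=0, lr=10.0, max_epochs=3, clip_norm=None)
        with pytest.raises(FloatingPointError):
            train(model, {"A": examples["A"]}, {"A": valid["A"]}, cfg)


class TestFineTune:
    def test_other_head_bitwise_unchanged_and_patience(self, tiny_setup):
        model, examples, valid = tiny_setup
        joint_cfg = TrainConfig(seed=0, lr=1e-3, max_epochs=2, shift_max=1)
        train(model, examples, valid, joint_cfg, patience=2)
        before_b = [p.copy() for _n, p, _g in model.head_params("B")]
        ft_cfg = TrainConfig(seed=1, lr=1e-3, max_epochs=8, finetune_patience=2,
                             shift_max=1)
        history = fine_tune(model, "A", examples, valid, ft_cfg)
        for b0, (_n, b1, _g) in zip(before_b, model.head_params("B")):
            np.testing.assert_array_equal(b0, b1)
        frame = history.to_frame()
        mixed = frame[(frame.split == "valid") & (frame.genome == "mixed")]
        best_epoch = frame[frame.split == "best"].iloc[0].epoch
        assert mixed.epoch.max() <= best_epoch + ft_cfg.finetune_patience + 1

    def test_returns_best_validation_weights(self, tiny_setup):
        model, examples, valid = tiny_setup
        cfg = TrainConfig(seed=0, lr=1e-3, max_epochs=4, shift_max=1)
        history = fine_tune(model, "A", examples, valid, cfg)
        frame = history.to_frame()
        mixed = frame[(frame.split == "valid") & (frame.genome == "mixed")]
        best = frame[frame.split == "best"].iloc[0].loss
        assert best == pytest.approx(mixed.loss.min())

    def test_unknown_genome_raises(self, tiny_setup):
        model, examples, valid = tiny_setup
        with pytest.raises(KeyError):
            fine_tune(model, "Z", examples, valid, TrainConfig())


class TestEvaluate:
    def test_predictions_equal_targets_r_one(self, tiny_setup, rng):
        model, examples, _ = tiny_setup
        exs = examples["A"][:2]
        for ex in exs:
            pred = model.forward(ex.sequence[None], "A")[0]
            ex.targets = pred.astype(np.float32)
        corr = evaluate(model, exs, crop_keep=64)
        np.testing.assert_allclose(corr["A"], 1.0, atol=1e-5)

    def test_negated_centered_targets_r_minus_one(self, tiny_setup):
        model, examples, _ = tiny_setup
        exs = examples["A"][:1]
        for ex in exs:
            pred = model.forward(ex.sequence[None], "A")[0]
            ex.targets = (-(pred - pred.mean(axis=0))).astype(np.float32)
        corr = evaluate(model, exs, crop_keep=64)
        np.testing.assert_allclose(corr["A"], -1.0, atol=1e-4)

    def test_zero_variance_dataset_nan(self, tiny_setup):
        model, examples, _ = tiny_setup
        exs = examples["A"][:1]
        exs[0].targets[...] = 5.0
        corr = evaluate(model, exs, crop_keep=64)
        assert np.isnan(corr["A"]).all()

    def test_empty_raises(self, tiny_setup):
        model, _, _ = tiny_setup
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, [])


def test_pearson_matches_scipy(rng):
    for _ in range(5):
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert pearson(a, b) == pytest.approx(sps.pearsonr(a, b).statistic, rel=1e-9)
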