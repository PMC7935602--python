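import numpy as np
import pytest

from advseg.config import RunConfig
from advseg.nn.discnet import DiscNet, DiscNetSpec
from advseg.training import (
    TrainState,
    init_state,
    leave_one_out,
    load_checkpoint,
    sample_batch,
    save_checkpoint,
    summarize_folds,
    train,
    train_step_discriminator,
    train_step_segmenter,
    _prepared,
)
from advseg.nn.adam import Adam
from advseg.types import one_hot


def _snapshot(obj):
    return {k: v.copy() for k, v in obj.state_arrays().items()}


def _assert_identical(a, b):
    assert a.keys() == b.keys()
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


@pytest.fixture
def adv_state_and_batch(tiny_adv_config, small_phantoms):
    state = init_state(tiny_adv_config)
    pairs = _prepared(small_phantoms[:2], tiny_adv_config)
    batch = sample_batch(pairs, tiny_adv_config, state.rng)
    return state, batch


class TestStepContracts:
    def test_discriminator_step_freezes_segmenter(self, adv_state_and_batch):
        state, batch = adv_state_and_batch
        before = _snapshot(state.seg)
        d_loss = train_step_discriminator(state, batch)
        _assert_identical(before, _snapshot(state.seg))
        assert np.isfinite(d_loss)

    def test_segmenter_step_freezes_discriminator(self, adv_state_and_batch):
        state, batch = adv_state_and_batch
        before = _snapshot(state.disc)
        breakdown = train_step_segmenter(state, batch)
        _assert_identical(before, _snapshot(state.disc))
        assert breakdown.j_total == pytest.approx(
            breakdown.j_ce + 0.15 * breakdown.j_adv_gen
        )

    def test_segmenter_step_changes_segmenter(self, adv_state_and_batch):
        state, batch = adv_state_and_batch
        before = _snapshot(state.seg)
        train_step_segmenter(state, batch)
        changed = any(
            not np.array_equal(before[k], v) for k, v in state.seg.state_arrays().items()
        )
        assert changed

    def test_alpha_zero_never_builds_discriminator(self, tiny_config):
        state = init_state(tiny_config)
        assert state.disc is None
        assert state.opt_disc is None

    def test_alpha_zero_step_is_pure_cross_entropy(self, tiny_config, small_phantoms):
        state = init_state(tiny_config)
        pairs = _prepared(small_phantoms[:2], tiny_config)
        batch = sample_batch(pairs, tiny_config, state.rng)
        breakdown = train_step_segmenter(state, batch)
        assert breakdown.j_adv_gen == 0.0
        assert breakdown.j_total == breakdown.j_ce

    def test_empty_batch_rejected(self, tiny_config):
        state = init_state(tiny_config)
        empty = (np.zeros((0, 1, 16, 16, 16)), np.zeros((0, 3, 16, 16, 16)))
        with pytest.raises(ValueError, match="empty"):
            train_step_segmenter(state, empty)

    def test_cross_entropy_decreases_on_fixed_batch(self, tiny_config, small_phantoms):
        state = init_state(tiny_config)
        pairs = _prepared(small_phantoms[:1], tiny_config)
        batch = sample_batch(pairs, tiny_config, state.rng)
        first = train_step_segmenter(state, batch).j_ce
        last = first
        for _ in range(49):
            last = train_step_segmenter(state, batch).j_ce
        assert last < first


class _TruthSegmenter:
    """Stand-in segmenter whose output is exactly the manual annotation."""

    def forward(self, x, train=False):
        raise NotImplementedError  # replaced per-batch below


class TestDiscriminatorEquilibrium:
    def test_scores_drift_to_half_when_fake_equals_real(self, tiny_adv_config, small_phantoms):
        # with a perfect segmenter the two roles are indistinguishable;
        # BCE then drives the discriminator toward D = 0.5 on both
        cfg = tiny_adv_config
        state = init_state(cfg)
        pairs = _prepared(small_phantoms[:2], cfg)
        rng = np.random.default_rng(0)

        truth_seg = _TruthSegmenter()
        state = TrainState(
            seg=truth_seg, disc=state.disc, opt_seg=None,
            opt_disc=state.opt_disc, rng=state.rng, config=cfg,
        )
        batch = sample_batch(pairs, cfg, state.rng)
        truth_seg.forward = lambda x, train=False: batch[1]

        d0 = state.disc.forward(batch[0], batch[1], train=False)
        for _ in range(60):
            train_step_discriminator(state, batch)
        d1 = state.disc.forward(batch[0], batch[1], train=False)
        assert np.abs(d1 - 0.5).mean() < np.abs(d0 - 0.5).mean() + 1e-6
        assert np.abs(d1 - 0.5).mean() < 0.2


class TestTrainLoop:
    def test_identical_seeds_identical_traces(self, tiny_config, small_phantoms):
        s1 = train(small_phantoms[:2], tiny_config)
        s2 = train(small_phantoms[:2], tiny_config)
        assert s1.history == s2.history
        _assert_identical(_snapshot(s1.seg), _snapshot(s2.seg))

    def test_adversarial_loop_logs_all_components(self, tiny_adv_config, small_phantoms, tmp_path):
        log = tmp_path / "train.tsv"
        state = train(small_phantoms[:2], tiny_adv_config, log_path=log)
        assert state.step == tiny_adv_config.steps
        rows = log.read_text().strip().split("\n")
        assert len(rows) == tiny_adv_config.steps
        for rec in state.history:
            assert np.isfinite(rec["d_loss"])
            assert rec["j_total"] == pytest.approx(
                rec["j_ce"] + tiny_adv_config.alpha * rec["j_adv_gen"]
            )

    def test_checkpoint_restore_reproduces_trajectory(self, tiny_config, small_phantoms, tmp_path):
        cfg3 = RunConfig(**{**tiny_config.to_dict(), "steps": 3})
        cfg6 = RunConfig(**{**tiny_config.to_dict(), "steps": 6})
        # uninterrupted 6-step run
        full = train(small_phantoms[:2], cfg6)
        # 3 steps, checkpoint, restore, 3 more
        half = train(small_phantoms[:2], cfg3)
        ckpt = tmp_path / "mid.npz"
        save_checkpoint(half, ckpt)
        resumed = load_checkpoint(ckpt)
        resumed.config = cfg6
        resumed = train(small_phantoms[:2], cfg6, state=resumed)
        assert resumed.history == full.history
        _assert_identical(_snapshot(resumed.seg), _snapshot(full.seg))

    def test_checkpoint_roundtrip_adversarial(self, tiny_adv_config, small_phantoms, tmp_path):
        state = train(small_phantoms[:2], tiny_adv_config)
        ckpt = tmp_path / "adv.npz"
        save_checkpoint(state, ckpt)
        back = load_checkpoint(ckpt)
        _assert_identical(_snapshot(state.seg), _snapshot(back.seg))
        _assert_identical(_snapshot(state.disc), _snapshot(back.disc))
        _assert_identical(state.opt_seg.state_arrays(), back.opt_seg.state_arrays())
        assert back.step == state.step

    def test_empty_dataset_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            train([], tiny_config)


class TestLeaveOneOut:
    def test_partition_and_summary(self, tiny_config, small_phantoms):
        cfg = RunConfig(**{**tiny_config.to_dict(), "steps": 2})
        reports = leave_one_out(small_phantoms, cfg)
        assert [r.case_id for r in reports] == [0, 1, 2]
        for r in reports:
            assert 0.0 <= r.dice_myocardium <= 1.0
            assert 0.0 <= r.dice_blood_pool <= 1.0
        summary = summarize_folds(reports)
        assert summary["dice_myocardium"] == pytest.approx(
            np.mean([r.dice_myocardium for r in reports])
        )
        assert summary["n_folds"] == 3

    def test_reproducible_fold_seeds(self, tiny_config, small_phantoms):
        cfg = RunConfig(**{**tiny_config.to_dict(), "steps": 2})
        a = leave_one_out(small_phantoms[:2], cfg)
        b = leave_one_out(small_phantoms[:2], cfg)
        for ra, rb in zip(a, b):
            assert ra == rb

    def test_requires_two_cases(self, tiny_config, small_phantoms):
        with pytest.raises(ValueError):
            leave_one_out(small_phantoms[:1], tiny_config)


class TestPriorBiasInit:
    def test_initial_prediction_matches_class_prior(self, tiny_config, small_phantoms):
        from advseg.training import _set_prior_bias

        state = init_state(tiny_config)
        pairs = _prepared(small_phantoms[:2], tiny_config)
        _set_prior_bias(state.seg, pairs)
        counts = np.zeros(3)
        for _, lab in pairs:
            counts += np.bincount(lab.ravel(), minlength=3)
        priors = counts / counts.sum()
        x = pairs[0][0][:16, :16, :16][None, None]
        probs = state.seg.forward(x, train=False).mean(axis=(0, 2, 3, 4))
        # untrained conv logits are near zero, so the bias dominates
        np.testing.assert_allclose(probs, priors, atol=0.06)
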