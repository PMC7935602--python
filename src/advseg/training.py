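"""Alternating adversarial optimisation, checkpointing, and the
cross-validation / ablation harnesses.

One training iteration samples a batch of augmented random blocks,
takes one discriminator step (skipped entirely when ``alpha = 0``) and
one segmenter step.  The discriminator sees the frozen segmenter's
output as "fake" and the one-hot manual annotation as "real"; the
segmenter's update combines cross-entropy with the alpha-weighted
generator term.  Each step touches exactly one network's parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import losses
from .config import RunConfig
from .nn.adam import Adam
from .nn.discnet import DiscNet, DiscNetSpec
from .nn.segnet import SegNet, SegNetSpec
from .phantom import PhantomCase
from .preprocess import apply_augment, random_augment, sample_random_patch, standardize
from .types import LabelMap, Volume, one_hot


@dataclass
class TrainState:
    """Everything needed to continue (or exactly reproduce) a run."""

    seg: SegNet
    disc: DiscNet | None
    opt_seg: Adam
    opt_disc: Adam | None
    rng: np.random.Generator
    config: RunConfig
    step: int = 0
    history: list = field(default_factory=list)


@dataclass(frozen=True)
class FoldReport:
    """Held-out evaluation of one cross-validation fold."""

    case_id: int
    dice_myocardium: float
    dice_blood_pool: float
    config: dict


def _as_pairs(dataset) -> list[tuple[np.ndarray, np.ndarray]]:
    pairs = []
    for item in dataset:
        if isinstance(item, PhantomCase):
            vol, lab = item.volume, item.labels
        else:
            vol, lab = item
        v = vol.data if isinstance(vol, Volume) else np.asarray(vol)
        l = lab.data if isinstance(lab, LabelMap) else np.asarray(lab)
        if v.shape != l.shape:
            raise ValueError(f"volume {v.shape} / label {l.shape} shape mismatch")
        pairs.append((np.asarray(v, dtype=np.float32), np.asarray(l)))
    return pairs


def _prepared(dataset, config: RunConfig):
    pairs = _as_pairs(dataset)
    if config.standardize:
        pairs = [
            (standardize(Volume(v)).data, l) for v, l in pairs
        ]
    return pairs


def _set_prior_bias(seg: SegNet, pairs, n_classes: int = 3) -> None:
    """Initialise the output layer's bias to the log class frequencies.

    The initial prediction then matches the empirical class prior
    instead of the uniform distribution, the standard remedy for
    extreme class imbalance: the dominant background stops flooding
    the early gradients and the rare classes' voxels carry strong
    per-voxel signal from step one.
    """
    counts = np.zeros(n_classes, dtype=np.float64)
    for _, lab in pairs:
        counts += np.bincount(np.asarray(lab).ravel(), minlength=n_classes)[:n_classes]
    freqs = np.clip(counts / counts.sum(), 1e-6, None)
    seg.final.params["b"][...] = np.log(freqs).astype(np.float32)


def init_state(config: RunConfig) -> TrainState:
    """Build networks, optimisers and the sampling generator from one seed."""
    ss = np.random.SeedSequence(config.seed)
    seg_ss, disc_ss, sample_ss = ss.spawn(3)
    seg = SegNet(
        SegNetSpec(scales=config.scales, base_channels=config.base_channels),
        np.random.default_rng(seg_ss),
    )
    seg.spec.check_patch(config.patch_size)
    opt_seg = Adam(seg.layers, lr=config.learning_rate)
    disc = opt_disc = None
    if config.alpha > 0:
        disc = DiscNet(DiscNetSpec(channels=config.disc_channels), np.random.default_rng(disc_ss))
        opt_disc = Adam(disc.layers, lr=config.learning_rate)
    return TrainState(
        seg=seg, disc=disc, opt_seg=opt_seg, opt_disc=opt_disc,
        rng=np.random.default_rng(sample_ss), config=config,
    )


def sample_batch(pairs, config: RunConfig, rng: np.random.Generator):
    """Draw ``batch_size`` augmented random blocks across the volumes."""
    xs, ys = [], []
    for _ in range(config.batch_size):
        v, l = pairs[int(rng.integers(0, len(pairs)))]
        pair = sample_random_patch(v, l, config.patch_size, rng)
        pair = apply_augment(pair, random_augment(rng))
        xs.append(pair.image[None])
        ys.append(one_hot(pair.labels))
    return np.stack(xs), np.stack(ys)


def train_step_discriminator(state: TrainState, batch) -> float:
    """One Adam step on the discriminator only; the segmenter is frozen
    (evaluated in inference mode, gradients never applied to it)."""
    x, y = batch
    if x.shape[0] == 0:
        raise ValueError("empty batch")
    if state.disc is None:
        raise ValueError("no discriminator in an alpha = 0 run")
    probs = state.seg.forward(x, train=False)  # detached generator output
    state.disc.zero_grads()
    d_real = state.disc.forward(x, y, train=True)
    g_real, _ = losses.discriminator_loss_grads(d_real, np.zeros_like(d_real))
    state.disc.backward(g_real)
    d_fake = state.disc.forward(x, probs, train=True)
    _, g_fake = losses.discriminator_loss_grads(np.full_like(d_fake, 0.5), d_fake)
    state.disc.backward(g_fake)
    state.opt_disc.step()
    return losses.discriminator_loss(d_real, d_fake)


def train_step_segmenter(state: TrainState, batch) -> losses.LossBreakdown:
    """One Adam step on the segmenter only, driven by
    ``J_CE + alpha * J_adv``; the discriminator is frozen."""
    x, y = batch
    if x.shape[0] == 0:
        raise ValueError("empty batch")
    cfg = state.config
    state.seg.zero_grads()
    probs = state.seg.forward(x, train=True)
    j_ce = losses.cross_entropy(probs, y)
    glogits = losses.cross_entropy_logit_grad(probs, y)  # fused softmax/CE form
    gprobs = None
    j_adv = 0.0
    if cfg.alpha > 0:
        d_fake = state.disc.forward(x, probs, train=False)
        j_adv = losses.generator_adversarial_loss(d_fake)
        state.disc.zero_grads()  # discard any stale accumulation
        _, g_seg_in = state.disc.backward(losses.generator_adversarial_loss_grad(d_fake))
        state.disc.zero_grads()  # freeze: this pass must not leak into a D update
        gprobs = cfg.alpha * g_seg_in
    state.seg.backward(gprobs, glogits=glogits)
    state.opt_seg.step()
    state.step += 1
    return losses.total_loss(j_ce, j_adv, cfg.alpha)


def train(dataset, config: RunConfig, state: TrainState | None = None,
          log_path: str | Path | None = None,
          checkpoint_path: str | Path | None = None) -> TrainState:
    """Run the alternating loop for ``config.steps`` iterations.

    Passing an existing ``state`` continues it (used after checkpoint
    restore); the loop runs until ``state.step`` reaches ``config.steps``.
    """
    if len(dataset) < 1:
        raise ValueError("need at least one training volume")
    pairs = _prepared(dataset, config)
    for v, _ in pairs:
        if any(d < config.patch_size for d in v.shape):
            raise ValueError(f"volume shape {v.shape} smaller than patch {config.patch_size}")
    if state is None:
        state = init_state(config)
        _set_prior_bias(state.seg, pairs)
    log_file = open(log_path, "a") if log_path else None
    try:
        while state.step < config.steps:
            batch = sample_batch(pairs, config, state.rng)
            d_loss = None  # no discriminator in the alpha = 0 baseline
            if config.alpha > 0:
                d_loss = train_step_discriminator(state, batch)
            breakdown = train_step_segmenter(state, batch)
            rec = {
                "step": state.step,
                "j_ce": breakdown.j_ce,
                "j_adv_gen": breakdown.j_adv_gen,
                "d_loss": d_loss,
                "j_total": breakdown.j_total,
            }
            state.history.append(rec)
            if log_file:
                d_txt = "na" if d_loss is None else f"{d_loss:.6f}"
                log_file.write(
                    f"{rec['step']}\t{rec['j_ce']:.6f}\t{rec['j_adv_gen']:.6f}"
                    f"\t{d_txt}\t{rec['j_total']:.6f}\n"
                )
            if (
                checkpoint_path
                and config.checkpoint_every
                and state.step % config.checkpoint_every == 0
            ):
                save_checkpoint(state, checkpoint_path)
    finally:
        if log_file:
            log_file.close()
    return state


# ----------------------------------------------------------------------
# checkpointing

CHECKPOINT_VERSION = 1


def save_checkpoint(state: TrainState, path: str | Path) -> None:
    """Serialise networks, optimisers, step counter and sampling RNG."""
    arrays: dict[str, np.ndarray] = {}
    for prefix, obj in (
        ("seg", state.seg), ("opt_seg", state.opt_seg),
        ("disc", state.disc), ("opt_disc", state.opt_disc),
    ):
        if obj is None:
            continue
        for k, v in obj.state_arrays().items():
            arrays[f"{prefix}/{k}"] = v
    meta = {
        "version": CHECKPOINT_VERSION,
        "step": state.step,
        "config": state.config.to_dict(),
        "rng_state": state.rng.bit_generator.state,
        "history": state.history,
    }
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> TrainState:
    """Rebuild a :class:`TrainState` that continues exactly where the
    saved run left off (given the same data order)."""
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["__meta__"]))
        arrays = {k: f[k] for k in f.files if k != "__meta__"}
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    config = RunConfig(**meta["config"])
    state = init_state(config)
    state.step = meta["step"]
    state.history = list(meta.get("history", []))
    state.rng.bit_generator.state = meta["rng_state"]
    for prefix, obj in (
        ("seg", state.seg), ("opt_seg", state.opt_seg),
        ("disc", state.disc), ("opt_disc", state.opt_disc),
    ):
        if obj is None:
            continue
        obj.load_state_arrays(
            {k.split("/", 1)[1]: v for k, v in arrays.items() if k.startswith(prefix + "/")}
        )
    return state


# ----------------------------------------------------------------------
# experiment harnesses

def _evaluate_case(state: TrainState, case, config: RunConfig):
    from .inference import dice_report, predict_volume

    if isinstance(case, PhantomCase):
        vol, lab = case.volume, case.labels
    else:
        vol, lab = case
    _, pred = predict_volume(state.seg, vol, config)
    truth = lab if isinstance(lab, LabelMap) else LabelMap(np.asarray(lab))
    return dice_report(pred, truth)


def leave_one_out(cases, config: RunConfig) -> list[FoldReport]:
    """n folds over n cases: each case held out once, the model trained
    from scratch on the rest with a fold-derived seed."""
    if len(cases) < 2:
        raise ValueError("leave-one-out requires at least 2 cases")
    reports = []
    for i in range(len(cases)):
        fold_seed = int(
            np.random.default_rng(np.random.SeedSequence((config.seed, i))).integers(0, 2**31 - 1)
        )
        fold_cfg = RunConfig(**{**config.to_dict(), "seed": fold_seed})
        train_cases = [c for j, c in enumerate(cases) if j != i]
        state = train(train_cases, fold_cfg)
        rep = _evaluate_case(state, cases[i], fold_cfg)
        reports.append(
            FoldReport(
                case_id=i,
                dice_myocardium=rep.dice(1),
                dice_blood_pool=rep.dice(2),
                config=fold_cfg.to_dict(),
            )
        )
    return reports


def summarize_folds(reports: list[FoldReport]) -> dict:
    return {
        "dice_myocardium": float(np.mean([r.dice_myocardium for r in reports])),
        "dice_blood_pool": float(np.mean([r.dice_blood_pool for r in reports])),
        "n_folds": len(reports),
    }


ARM_LABELS = {0: "baseline", 1: "adversarial"}


def ablation(cases, config: RunConfig, alphas=(0.0, 0.15), n_holdout: int = 2,
             out_tsv: str | Path | None = None) -> list[dict]:
    """Train one arm per alpha on the same split and tabulate held-out Dice.

    The last ``n_holdout`` cases are held out for every arm, so the arms
    differ only through the adversarial term.  Returns one record per
    arm and optionally writes a tab-separated table
    (arm, alpha, myocardium Dice, blood-pool Dice).
    """
    if not (0 < n_holdout < len(cases)):
        raise ValueError("n_holdout must leave at least one training case")
    train_cases, held = cases[:-n_holdout], cases[-n_holdout:]
    rows = []
    for alpha in alphas:
        cfg = RunConfig(**{**config.to_dict(), "alpha": float(alpha)})
        state = train(train_cases, cfg)
        per_case = [_evaluate_case(state, c, cfg) for c in held]
        rows.append(
            {
                "arm": "baseline" if alpha == 0 else "adversarial",
                "alpha": float(alpha),
                "dice_myocardium": float(np.mean([r.dice(1) for r in per_case])),
                "dice_blood_pool": float(np.mean([r.dice(2) for r in per_case])),
                "per_case_myocardium": [r.dice(1) for r in per_case],
                "per_case_blood_pool": [r.dice(2) for r in per_case],
            }
        )
    if out_tsv:
        with open(out_tsv, "w") as f:
            f.write("arm\talpha\tdice_myocardium\tdice_blood_pool\n")
            for row in rows:
                f.write(
                    f"{row['arm']}\t{row['alpha']:g}"
                    f"\t{row['dice_myocardium']:.4f}\t{row['dice_blood_pool']:.4f}\n"
                )
    return rows
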