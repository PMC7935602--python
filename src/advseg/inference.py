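"""Whole-volume tiled prediction and Dice-coefficient evaluation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import RunConfig
from .nn.segnet import SegNet
from .preprocess import assemble, extract_blocks, make_grid, standardize
from .types import CLASS_NAMES, LabelMap, Volume


def predict_volume(
    seg: SegNet,
    volume: Volume | np.ndarray,
    config: RunConfig | None = None,
    patch_size: int | None = None,
    stride: int | None = None,
    do_standardize: bool | None = None,
    batch_blocks: int = 4,
    postprocess=None,
) -> tuple[np.ndarray, LabelMap]:
    """Predict a full volume by gridded block inference.

    Blocks are taken on the clamped regular grid, passed through the
    segmenter in inference mode, and overlap-averaged into one
    probability map; labels are its per-voxel argmax (lowest class id
    wins ties).  ``postprocess``, if given, is called on the label array
    after argmax and must return an array of the same shape — the
    package itself applies none.

    Returns ``(probability_map, label_map)`` where the probability map
    has shape ``(3, D, H, W)``.
    """
    cfg = config or RunConfig()
    patch = patch_size or cfg.patch_size
    step = stride or cfg.stride
    std = cfg.standardize if do_standardize is None else do_standardize
    vol = volume if isinstance(volume, Volume) else Volume(np.asarray(volume))
    if any(d < patch for d in vol.shape):
        raise ValueError(f"volume shape {vol.shape} smaller than patch size {patch}")
    if std:
        vol = standardize(vol)
    grid = make_grid(vol.shape, patch, step)
    blocks = extract_blocks(vol.data.astype(np.float32), grid)
    probs = []
    for i in range(0, len(blocks), batch_blocks):
        chunk = np.stack(blocks[i : i + batch_blocks])[:, None]
        out = seg.forward(chunk, train=False)
        probs.extend(out[j] for j in range(out.shape[0]))
    prob_map = assemble(probs, grid, vol.shape)
    labels = np.argmax(prob_map, axis=0).astype(np.int16)
    if postprocess is not None:
        labels = np.asarray(postprocess(labels)).astype(np.int16)
        if labels.shape != vol.shape:
            raise ValueError("postprocess must preserve the label array shape")
    return prob_map, LabelMap(data=labels, spacing=vol.spacing)


@dataclass(frozen=True)
class DiceEntry:
    """Voxel counts and the Dice coefficient for one class."""

    class_id: int
    n_pred: int
    n_truth: int
    n_intersection: int

    @property
    def dsc(self) -> float:
        denom = self.n_pred + self.n_truth
        if denom == 0:
            return 1.0  # both sets empty: perfect (vacuous) agreement
        return 2.0 * self.n_intersection / denom


def dice(pred: LabelMap | np.ndarray, truth: LabelMap | np.ndarray, class_id: int) -> DiceEntry:
    """DSC = 2|X∩Y| / (|X| + |Y|) for one class's voxel sets."""
    p = pred.data if isinstance(pred, LabelMap) else np.asarray(pred)
    t = truth.data if isinstance(truth, LabelMap) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    x = p == class_id
    y = t == class_id
    return DiceEntry(
        class_id=class_id,
        n_pred=int(x.sum()),
        n_truth=int(y.sum()),
        n_intersection=int((x & y).sum()),
    )


@dataclass(frozen=True)
class DiceReport:
    """Per-class Dice entries for the two foreground classes."""

    entries: tuple[DiceEntry, ...]

    def entry(self, class_id: int) -> DiceEntry:
        for e in self.entries:
            if e.class_id == class_id:
                return e
        raise KeyError(class_id)

    def dice(self, class_id: int) -> float:
        return self.entry(class_id).dsc

    def to_tsv(self, case: str = "case") -> str:
        lines = ["case\tclass\tn_pred\tn_truth\tn_intersection\tdice"]
        for e in self.entries:
            lines.append(
                f"{case}\t{CLASS_NAMES[e.class_id]}\t{e.n_pred}\t{e.n_truth}"
                f"\t{e.n_intersection}\t{e.dsc:.4f}"
            )
        return "\n".join(lines) + "\n"


def dice_report(pred: LabelMap | np.ndarray, truth: LabelMap | np.ndarray,
                class_ids=(1, 2)) -> DiceReport:
    """Dice for the myocardium and blood-pool classes (by default)."""
    return DiceReport(entries=tuple(dice(pred, truth, c) for c in class_ids))
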