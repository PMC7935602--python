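"""scikit-learn-style estimator wrapping the adversarial training loop.

``AdversarialVolumeSegmenter(alpha=0).fit(X, y)`` is the pure
cross-entropy 3D U-Net baseline; a positive ``alpha`` adds the
discriminator and the adversarial term.  ``X`` is a sequence of 3D
volumes (``Volume`` or arrays) and ``y`` the aligned 3-class label maps.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .config import RunConfig
from .inference import dice_report, predict_volume
from .training import train
from .types import LabelMap, Volume


class AdversarialVolumeSegmenter(BaseEstimator):
    """3D encoder-decoder segmenter trained against a convolutional
    discriminator with loss ``J = J_CE + alpha * J_adv``.

    Parameters
    ----------
    alpha : float, default 0.15
        Weight of the adversarial generator term; 0 disables the
        discriminator entirely (the baseline arm).
    scales, base_channels : int
        Encoder depth and first-scale channel count of the segmenter.
    patch_size, stride : int
        Training block edge length and inference grid stride (voxels).
    learning_rate, batch_size, steps : Adam step size, blocks per batch,
        and total alternating iterations.
    disc_channels : tuple of 4 ints
        Channel schedule of the discriminator's basic modules.
    standardize : bool
        Z-score each volume before blocking (training and inference).
    random_state : int
        Seed fanned out to network init and patch sampling.

    Attributes
    ----------
    segmenter_ : SegNet
        The trained segmentation network.
    discriminator_ : DiscNet or None
        The trained discriminator (None when ``alpha = 0``).
    history_ : list of dict
        Per-step loss components (step, j_ce, j_adv_gen, d_loss, j_total).
    config_ : RunConfig
        The resolved run configuration.
    """

    def __init__(self, alpha: float = 0.15, scales: int = 4, base_channels: int = 16,
                 patch_size: int = 64, stride: int = 32, learning_rate: float = 0.001,
                 batch_size: int = 16, steps: int = 300,
                 disc_channels: tuple = (16, 32, 64, 128),
                 standardize: bool = True, random_state: int = 0):
        self.alpha = alpha
        self.scales = scales
        self.base_channels = base_channels
        self.patch_size = patch_size
        self.stride = stride
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.steps = steps
        self.disc_channels = disc_channels
        self.standardize = standardize
        self.random_state = random_state

    def _config(self) -> RunConfig:
        return RunConfig(
            patch_size=self.patch_size, stride=self.stride, alpha=self.alpha,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            steps=self.steps, seed=self.random_state, scales=self.scales,
            base_channels=self.base_channels, disc_channels=self.disc_channels,
            standardize=self.standardize,
        )

    def fit(self, X, y, log_path=None, checkpoint_path=None):
        """Train on aligned sequences of volumes and label maps."""
        if len(X) != len(y):
            raise ValueError(f"got {len(X)} volumes but {len(y)} label maps")
        if len(X) == 0:
            raise ValueError("need at least one training volume")
        config = self._config()
        state = train(list(zip(X, y)), config, log_path=log_path,
                      checkpoint_path=checkpoint_path)
        self.state_ = state
        self.segmenter_ = state.seg
        self.discriminator_ = state.disc
        self.history_ = state.history
        self.config_ = config
        return self

    def _check_fitted(self):
        if not hasattr(self, "segmenter_"):
            raise RuntimeError("this AdversarialVolumeSegmenter instance is not fitted yet")

    def predict(self, X) -> list[LabelMap]:
        """Tiled whole-volume prediction; returns one LabelMap per input."""
        self._check_fitted()
        return [predict_volume(self.segmenter_, v, self.config_)[1] for v in self._iter(X)]

    def predict_proba(self, X) -> list[np.ndarray]:
        """Overlap-averaged (3, D, H, W) probability map per input."""
        self._check_fitted()
        return [predict_volume(self.segmenter_, v, self.config_)[0] for v in self._iter(X)]

    def score(self, X, y) -> float:
        """Mean foreground Dice (myocardium and blood pool averaged)
        across the given cases."""
        self._check_fitted()
        scores = []
        for pred, truth in zip(self.predict(X), y):
            rep = dice_report(pred, truth if isinstance(truth, LabelMap) else LabelMap(np.asarray(truth)))
            scores.append(0.5 * (rep.dice(1) + rep.dice(2)))
        return float(np.mean(scores))

    @staticmethod
    def _iter(X):
        if isinstance(X, (Volume, np.ndarray)):
            raise TypeError("X must be a sequence of volumes (wrap a single volume in a list)")
        return X
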