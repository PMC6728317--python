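"""Step 1: the sinogram-inpainting conditional GAN.

The generator fills the zero-padded missing-wedge rows of a normalized
sinogram; at inference the acquired rows are copied verbatim from the
measurement and only the missing rows are taken from the network
(compositing), so measured data are never altered.  The discriminator is
conditional: it scores the candidate sinogram stacked with the masked input.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .nn import DTYPE, LossBreakdown
from .nn.losses import GAN_LOSSES, mse_loss
from .nn.models import DualPathDiscriminator, RRDBGenerator
from .projection import (AngleGrid, Sinogram, WedgeSpec, apply_missing_wedge,
                         forward_project, normalize_sinogram)
from .train import CheckpointSet, TrainConfig, train_gan

__all__ = ["SinogramInpainter", "build_sinogram_dataset", "composite_inpaint",
           "inpaint_losses", "train_inpainting"]


def build_sinogram_dataset(phantoms, grid: AngleGrid | None = None,
                           wedge: WedgeSpec = WedgeSpec(45.0)):
    """Paired (masked, complete) normalized sinograms from a phantom suite.

    Returns ``(X_masked, Y_complete, mask)`` with arrays of shape
    (N, angles, bins) in [0,1] and the shared per-row acquired mask.  Values
    are clipped to [0,1] here — the projector's cubic interpolation can ring
    a fraction of a percent below zero, and the networks expect a bounded
    nonnegative range — while :func:`~wedgenet.projection.normalize_sinogram`
    itself stays exactly linear and invertible.
    """
    Xs, Ys, mask = [], [], None
    for ph in phantoms:
        complete = normalize_sinogram(forward_project(ph, grid))
        masked = apply_missing_wedge(complete, wedge, pad_zeros=True)
        Xs.append(np.clip(masked.values, 0.0, 1.0))
        Ys.append(np.clip(complete.values, 0.0, 1.0))
        mask = masked.mask
    return np.asarray(Xs), np.asarray(Ys), mask


def composite_sinogram_arrays(pred: np.ndarray, masked: np.ndarray,
                              mask: np.ndarray) -> np.ndarray:
    """Acquired rows from the measurement, missing rows from the prediction."""
    out = np.where(mask[None, :, None], masked, pred)
    return out


def composite_inpaint(model, masked: Sinogram) -> Sinogram:
    """Inpaint one masked sinogram and composite the acquired rows back in.

    ``masked`` must be normalized with its missing rows zero-padded.  The
    output has an all-acquired mask.
    """
    if masked.mask.all():
        raise ValueError("sinogram has no missing rows to inpaint")
    if masked.values[~masked.mask].any():
        raise ValueError("missing rows must be zero-padded before inpainting")
    gen = model.generator_ if isinstance(model, SinogramInpainter) else model
    pred = gen.predict(masked.values[None, None].astype(DTYPE))[0, 0]
    vals = np.where(masked.mask[:, None], masked.values, pred.astype(np.float64))
    return Sinogram(vals, masked.angle_grid,
                    np.ones_like(masked.mask), masked.scale)


def inpaint_losses(fake: np.ndarray, real: np.ndarray, masked_input: np.ndarray,
                   discriminator, lambda_adv: float = 5e-3,
                   gan_loss: str = "ralsgan"):
    """Joint generator loss breakdown and the discriminator loss for a batch.

    ``fake``, ``real`` and ``masked_input`` are (N, angles, bins) batches; the
    discriminator consumes conditional (candidate, masked input) pairs.  MSE
    is computed over the full sinogram.
    """
    fake = np.asarray(fake, dtype=DTYPE)
    real = np.asarray(real, dtype=DTYPE)
    cond = np.asarray(masked_input, dtype=DTYPE)
    if not (fake.shape == real.shape == cond.shape):
        raise ValueError("all three sinogram batches must share a shape")
    d_loss_fn, g_loss_fn = GAN_LOSSES[gan_loss]
    sr, _ = discriminator.forward(np.stack([real, cond], axis=1), train=False)
    sf, _ = discriminator.forward(np.stack([fake, cond], axis=1), train=False)
    mse, _ = mse_loss(fake, real)
    adv, _, _ = g_loss_fn(sr, sf)
    d_loss, _, _ = d_loss_fn(sr, sf)
    return LossBreakdown(mse=mse, adversarial=adv, lambda_adv=lambda_adv), d_loss


class SinogramInpainter(BaseEstimator, TransformerMixin):
    """RRDB-GAN sinogram inpainter with an sklearn fit/transform surface.

    Parameters mirror the generator (``n_blocks``, ``feature_depth``,
    ``growth_channels``, ``dilation``) and the dual-path discriminator
    (``d_*`` and ``input_kernel``); ``train_config`` carries the optimization
    schedule.  Fitted attributes: ``generator_``, ``discriminator_``,
    ``history_``, ``checkpoints_``, ``mask_``.
    """

    def __init__(self, n_blocks=8, feature_depth=64, growth_channels=32,
                 dilation=2, d_feature_depth=64, d_groups=4, slow_path_depth=5,
                 fast_path_depth=3, d_dilation=2, input_kernel=(5, 3),
                 train_config: TrainConfig | None = None,
                 checkpoint_epochs=None, out_dir=None):
        self.n_blocks = n_blocks
        self.feature_depth = feature_depth
        self.growth_channels = growth_channels
        self.dilation = dilation
        self.d_feature_depth = d_feature_depth
        self.d_groups = d_groups
        self.slow_path_depth = slow_path_depth
        self.fast_path_depth = fast_path_depth
        self.d_dilation = d_dilation
        self.input_kernel = input_kernel
        self.train_config = train_config
        self.checkpoint_epochs = checkpoint_epochs
        self.out_dir = out_dir

    def build_models(self, seed: int = 0):
        g = RRDBGenerator(n_blocks=self.n_blocks, feature_depth=self.feature_depth,
                          growth_channels=self.growth_channels,
                          dilation=self.dilation, seed=seed)
        d = DualPathDiscriminator(feature_depth=self.d_feature_depth,
                                  group_norm_groups=self.d_groups,
                                  slow_path_depth=self.slow_path_depth,
                                  fast_path_depth=self.fast_path_depth,
                                  dilation=self.d_dilation,
                                  input_kernel=self.input_kernel, seed=seed + 1)
        return g, d

    def fit(self, X, y, mask=None, val=None):
        """Train on masked (X) vs complete (y) normalized sinogram arrays.

        ``mask`` is the shared per-row acquired flag; validation pairs may be
        passed as ``val=(Xv, Yv)``.
        """
        X = np.asarray(X)
        y = np.asarray(y)
        if mask is None:
            # rows that are zero across the whole corpus are the missing ones
            mask = ~np.all(X == 0, axis=(0, 2))
        self.mask_ = np.asarray(mask, dtype=bool)
        cfg = self.train_config or TrainConfig()
        g, d = self.build_models(seed=cfg.seed)

        def postprocess(pred, inputs):
            return composite_sinogram_arrays(pred, inputs, self.mask_)

        self.history_, self.checkpoints_ = train_gan(
            g, d, X, y, cfg, val=val, checkpoint_epochs=self.checkpoint_epochs,
            out_dir=self.out_dir, postprocess=postprocess)
        self.generator_ = g
        self.discriminator_ = d
        return self

    def transform(self, X):
        """Inpaint a batch of masked normalized sinogram arrays (N, A, B).

        Acquired rows are returned bit-identical to the input (the network
        runs in float32 but compositing copies the original measurements).
        """
        from .train import _batched_predict
        X = np.asarray(X, dtype=np.float64)
        pred = _batched_predict(self.generator_, X.astype(DTYPE))
        return composite_sinogram_arrays(pred.astype(np.float64), X, self.mask_)


def train_inpainting(train_data, val_data, tcfg: TrainConfig,
                     checkpoint_epochs=None, out_dir=None,
                     model_params: dict | None = None) -> CheckpointSet:
    """Functional wrapper: train an inpainter and return its checkpoint set."""
    X, y, mask = train_data
    est = SinogramInpainter(train_config=tcfg, checkpoint_epochs=checkpoint_epochs,
                            out_dir=out_dir, **(model_params or {}))
    est.fit(X, y, mask=mask, val=val_data)
    return est.checkpoints_
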