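"""Joint GAN losses: pixel MSE plus a relativistic-average least-squares term.

The adversarial formulation follows the relativistic-average scheme: each
real score is judged against the batch mean of the fake scores (and vice
versa) with least-squares targets of +/-1.  A plain least-squares GAN variant
is available as a switch.  All functions return the scalar loss together with
analytic gradients with respect to the discriminator scores, so the trainer
can backpropagate them through the score network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LossBreakdown:
    """Generator-side loss components; ``total = mse + lambda_adv * adversarial``."""

    mse: float
    adversarial: float
    lambda_adv: float

    @property
    def total(self) -> float:
        return self.mse + self.lambda_adv * self.adversarial


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(pred.dtype)


def _check_batch(sr, sf):
    sr = np.asarray(sr, dtype=np.float64).ravel()
    sf = np.asarray(sf, dtype=np.float64).ravel()
    if sr.size < 2 or sf.size < 2:
        raise ValueError("relativistic-average losses need at least 2 samples per class")
    return sr, sf


def ralsgan_d_loss(scores_real, scores_fake):
    """Discriminator loss: real above the fake mean (+1), fake below the real mean (-1)."""
    sr, sf = _check_batch(scores_real, scores_fake)
    b_r, b_f = sr.size, sf.size
    mr, mf = sr.mean(), sf.mean()
    tr = sr - mf - 1.0
    tf = sf - mr + 1.0
    loss = 0.5 * (np.mean(tr ** 2) + np.mean(tf ** 2))
    dsr = tr / b_r - np.mean(tf) / b_r
    dsf = tf / b_f - np.mean(tr) / b_f
    return float(loss), dsr, dsf


def ralsgan_g_loss(scores_real, scores_fake):
    """Generator adversarial loss: the reversed-target counterpart of the D loss."""
    sr, sf = _check_batch(scores_real, scores_fake)
    b_r, b_f = sr.size, sf.size
    mr, mf = sr.mean(), sf.mean()
    tr = sr - mf + 1.0
    tf = sf - mr - 1.0
    loss = 0.5 * (np.mean(tr ** 2) + np.mean(tf ** 2))
    dsr = tr / b_r - np.mean(tf) / b_r
    dsf = tf / b_f - np.mean(tr) / b_f
    return float(loss), dsr, dsf


def lsgan_d_loss(scores_real, scores_fake):
    """Plain least-squares GAN discriminator loss (targets 1 for real, 0 for fake)."""
    sr = np.asarray(scores_real, dtype=np.float64).ravel()
    sf = np.asarray(scores_fake, dtype=np.float64).ravel()
    loss = 0.5 * (np.mean((sr - 1.0) ** 2) + np.mean(sf ** 2))
    return float(loss), (sr - 1.0) / sr.size, sf / sf.size


def lsgan_g_loss(scores_real, scores_fake):
    """Plain least-squares GAN generator loss (fake pushed toward the real target)."""
    sf = np.asarray(scores_fake, dtype=np.float64).ravel()
    loss = 0.5 * np.mean((sf - 1.0) ** 2)
    return float(loss), np.zeros_like(np.asarray(scores_real, dtype=np.float64).ravel()), (sf - 1.0) / sf.size


GAN_LOSSES = {
    "ralsgan": (ralsgan_d_loss, ralsgan_g_loss),
    "lsgan": (lsgan_d_loss, lsgan_g_loss),
}
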