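"""Step 2: the tomogram de-artifact conditional GAN and its training recipe.

The training corpus mixes four tomogram subsets so the U-net learns to
remove streak/ghost-tail artifacts without inventing corrections on clean
inputs: missing-wedge WBP, missing-wedge SART, complete-sinogram WBP (the
over-de-artifacting guard) and inpainted-then-WBP tomograms produced by
several inpainting checkpoints of increasing restoration strength.  Default
proportions are 10,000 : 7,500 : 7,500 : 20,000 scaled to the requested
corpus size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .inpaint import composite_inpaint
from .nn import DTYPE
from .nn.models import TomoDiscriminator, UNetGenerator
from .projection import (AngleGrid, WedgeSpec, apply_missing_wedge,
                         denormalize_sinogram, forward_project,
                         normalize_sinogram)
from .recon import (IterativeConfig, SARTReconstructor, Tomogram,
                    WBPReconstructor)
from .train import TrainConfig, train_gan

__all__ = ["DeartifactRecipe", "assemble_deartifact_dataset", "ArtifactRemover",
           "remove_artifacts"]

SUBSETS = ("missing_wbp", "missing_sart", "complete_wbp", "inpainted_wbp")


@dataclass
class DeartifactRecipe:
    """Subset fractions (missing-WBP, missing-SART, complete-WBP, inpainted-WBP)."""

    fractions: tuple = (2 / 9, 1 / 6, 1 / 6, 4 / 9)

    def __post_init__(self):
        if len(self.fractions) != len(SUBSETS):
            raise ValueError(f"need {len(SUBSETS)} fractions")
        if any(f < 0 for f in self.fractions) or not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("fractions must be nonnegative and sum to 1")

    def apportion(self, total: int) -> tuple[int, ...]:
        """Largest-remainder apportionment of ``total`` across the subsets."""
        if total < sum(1 for f in self.fractions if f > 0):
            raise ValueError("total too small to honor every nonempty subset")
        quotas = np.asarray(self.fractions) * total
        counts = np.floor(quotas).astype(int)
        rem = quotas - counts
        for i in np.argsort(-rem)[: total - counts.sum()]:
            counts[i] += 1
        return tuple(int(c) for c in counts)


def assemble_deartifact_dataset(phantoms, checkpoints, recipe: DeartifactRecipe,
                                total: int, seed: int = 0,
                                grid: AngleGrid | None = None,
                                wedge: WedgeSpec = WedgeSpec(45.0),
                                sart_cfg: IterativeConfig | None = None):
    """Paired (input tomogram, target phantom) training data per the recipe.

    ``checkpoints`` is a list of inpainting generator models (or a
    :class:`~wedgenet.train.CheckpointSet`); the inpainted subset is split
    evenly (round-robin) across them.  Targets are the source phantoms,
    bit-exact.  Returns a dict with ``inputs``, ``targets`` and per-sample
    ``labels`` for stratified evaluation.
    """
    from .train import CheckpointSet

    if isinstance(checkpoints, CheckpointSet):
        checkpoints = [checkpoints.load_generator(i) for i in range(len(checkpoints))]
    if not checkpoints:
        raise ValueError("need at least one inpainting checkpoint")
    phantoms = list(phantoms)
    counts = recipe.apportion(total)
    rng = np.random.default_rng(seed)
    wbp = WBPReconstructor()
    sart = SARTReconstructor(sart_cfg)

    inputs, targets, labels, ckpt_idx = [], [], [], []
    for subset, n in zip(SUBSETS, counts):
        picks = rng.integers(0, len(phantoms), size=n)
        for j, pick in enumerate(picks):
            ckpt_idx.append(j % len(checkpoints) if subset == "inpainted_wbp" else -1)
            ph = phantoms[int(pick)]
            complete = normalize_sinogram(forward_project(ph, grid))
            if subset == "complete_wbp":
                tomo = wbp.transform_one(denormalize_sinogram(complete))
            else:
                masked = apply_missing_wedge(complete, wedge, pad_zeros=True)
                if subset == "missing_wbp":
                    tomo = wbp.transform_one(denormalize_sinogram(masked))
                elif subset == "missing_sart":
                    tomo = sart.transform_one(denormalize_sinogram(masked))
                else:  # inpainted_wbp: round-robin over the checkpoints
                    gen = checkpoints[j % len(checkpoints)]
                    filled = composite_inpaint(gen, masked)
                    tomo = wbp.transform_one(denormalize_sinogram(filled))
            inputs.append(tomo.pixels)
            targets.append(ph.pixels)
            labels.append(subset)
    return {"inputs": np.asarray(inputs), "targets": np.asarray(targets),
            "labels": np.asarray(labels),
            "checkpoint_idx": np.asarray(ckpt_idx)}


def _standardize(batch: np.ndarray):
    mu = batch.mean(axis=(-2, -1), keepdims=True)
    sd = batch.std(axis=(-2, -1), keepdims=True)
    sd = np.where(sd < 1e-8, 1.0, sd)
    return (batch - mu) / sd, mu, sd


class ArtifactRemover(BaseEstimator, TransformerMixin):
    """U-net GAN that removes residual reconstruction artifacts from tomograms.

    Inputs are standardized to zero mean / unit variance per image before the
    network (WBP output is unbounded) and de-standardized on the way out; the
    U-net predicts a residual correction, so an untrained model is close to
    the identity.  Fitted attributes: ``generator_``, ``discriminator_``,
    ``history_``, ``checkpoints_``.
    """

    def __init__(self, depth=4, base_channels=64, norm=True,
                 d_feature_depth=64, d_layers=4, d_dilation=2,
                 train_config: TrainConfig | None = None,
                 checkpoint_epochs=None, out_dir=None):
        self.depth = depth
        self.base_channels = base_channels
        self.norm = norm
        self.d_feature_depth = d_feature_depth
        self.d_layers = d_layers
        self.d_dilation = d_dilation
        self.train_config = train_config
        self.checkpoint_epochs = checkpoint_epochs
        self.out_dir = out_dir

    def build_models(self, seed: int = 0):
        g = UNetGenerator(depth=self.depth, base_channels=self.base_channels,
                          norm=self.norm, seed=seed)
        d = TomoDiscriminator(feature_depth=self.d_feature_depth,
                              n_layers=self.d_layers, dilation=self.d_dilation,
                              seed=seed + 1)
        return g, d

    def fit(self, X, y, val=None):
        """Train on (input tomogram, target phantom) array pairs (N, S, S)."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        Xs, mu, sd = _standardize(X)
        ys = (y - mu) / sd
        val_s = None
        if val is not None:
            Xv, yv = np.asarray(val[0]), np.asarray(val[1])
            Xvs, muv, sdv = _standardize(Xv)
            val_s = (Xvs, (yv - muv) / sdv)
        cfg = self.train_config or TrainConfig(batch_size=32)
        g, d = self.build_models(seed=cfg.seed)
        self.history_, self.checkpoints_ = train_gan(
            g, d, Xs, ys, cfg, val=val_s, checkpoint_epochs=self.checkpoint_epochs,
            out_dir=self.out_dir)
        self.generator_ = g
        self.discriminator_ = d
        return self

    def transform_one(self, tomo: Tomogram) -> Tomogram:
        px = self.transform(tomo.pixels[None])[0]
        prov = dict(tomo.provenance)
        prov["deartifact"] = {"model": "unet-gan",
                              "depth": self.depth,
                              "base_channels": self.base_channels}
        return Tomogram(px, prov)

    def transform(self, X):
        """Clean a batch of tomogram arrays (N, S, S); deterministic inference."""
        X = np.asarray(X, dtype=np.float64)
        Xs, mu, sd = _standardize(X)
        out = []
        for i in range(len(Xs)):
            pred = self.generator_.predict(Xs[i][None, None].astype(DTYPE))[0, 0]
            out.append(pred.astype(np.float64) * sd[i] + mu[i])
        return np.asarray(out)


def remove_artifacts(model: ArtifactRemover, tomo: Tomogram) -> Tomogram:
    """Functional wrapper over :meth:`ArtifactRemover.transform_one`."""
    size = tomo.pixels.shape[0]
    if size % 2 ** model.depth:
        raise ValueError(f"tomogram size {size} does not match the trained "
                         f"geometry (needs a multiple of {2 ** model.depth})")
    return model.transform_one(tomo)
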