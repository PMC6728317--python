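"""Shared adversarial training loop for the inpainting and de-artifact GANs.

One discriminator update and one generator update per batch (1:1 frequency).
The generator trains on a joint loss, pixel MSE plus a weighted
relativistic-average least-squares adversarial term; the discriminator sees
conditional pairs (candidate stacked with the generator input).  Optimizers
and schedule: Adam for the generator, RMSprop for the discriminator, both at
a base rate of 4e-4 with 1e-4 weight decay, warmed up over the first three
epochs (1e-4, 2e-4, 4e-4) and decayed tenfold at epochs 20 and 28 of a
30-epoch run.  Everything is seeded and deterministic on a fixed platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (DTYPE, GAN_LOSSES, Adam, RMSprop, lr_for_epoch, mse_loss)
from .nn.models import Model, RRDBGenerator, UNetGenerator

__all__ = ["TrainConfig", "CheckpointSet", "train_gan", "save_checkpoint",
           "load_checkpoint"]


@dataclass
class TrainConfig:
    """Hyper-parameters of one GAN training run."""

    epochs: int = 30
    batch_size: int = 8
    lambda_adv: float = 5e-3
    gan_loss: str = "ralsgan"
    base_lr: float = 4e-4
    warmup_lrs: tuple = (1e-4, 2e-4, 4e-4)
    decay_epochs: tuple = (20, 28)
    decay_factor: float = 0.1
    weight_decay: float = 1e-4
    adam_betas: tuple = (0.9, 0.999)
    rmsprop_alpha: float = 0.99
    rmsprop_momentum: float = 0.0
    seed: int = 0
    max_steps: int | None = None   # cap on generator updates (smoke runs)
    lr_override: float | None = None  # constant LR replacing the schedule

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if any(d >= self.epochs for d in self.decay_epochs) and self.epochs >= 30:
            raise ValueError("decay epochs must precede the final epoch")
        if self.gan_loss not in GAN_LOSSES:
            raise ValueError(f"unknown gan_loss {self.gan_loss!r}")

    def lr_at(self, epoch: int) -> float:
        if self.lr_override is not None:
            return self.lr_override
        return lr_for_epoch(epoch, self.base_lr, self.warmup_lrs,
                            self.decay_epochs, self.decay_factor)


@dataclass
class CheckpointSet:
    """Ordered generator snapshots with their validation scores."""

    entries: list[dict] = field(default_factory=list)

    def add(self, epoch: int, path: str, val_mse: float, val_psnr: float,
            val_ssim: float):
        if self.entries and epoch <= self.entries[-1]["epoch"]:
            raise ValueError("checkpoint epochs must be strictly increasing")
        self.entries.append(dict(epoch=epoch, path=str(path), val_mse=val_mse,
                                 val_psnr=val_psnr, val_ssim=val_ssim))

    def __len__(self):
        return len(self.entries)

    def load_generator(self, i: int) -> Model:
        return load_checkpoint(self.entries[i]["path"])


_GEN_CLASSES = {"RRDBGenerator": RRDBGenerator, "UNetGenerator": UNetGenerator}


def save_checkpoint(model: Model, path: str | Path) -> None:
    """Single-file generator snapshot embedding its architecture config."""
    arrays = {f"a{i}": a for i, a in enumerate(model.state_arrays())}
    meta = json.dumps({"class": type(model).__name__, "config": model.config})
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path: str | Path) -> Model:
    with np.load(path) as z:
        meta = json.loads(str(z["__meta__"]))
        cls = _GEN_CLASSES[meta["class"]]
        model = cls(**meta["config"])
        model.load_state_arrays([z[f"a{i}"] for i in range(len(z.files) - 1)])
    return model


def _batched_predict(model: Model, X: np.ndarray, batch: int = 8) -> np.ndarray:
    outs = [model.predict(X[i:i + batch, None]) for i in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0)[:, 0]


def _validate(g: Model, Xv, Yv, postprocess=None) -> dict:
    from .metrics import fidelity_metrics
    pred = _batched_predict(g, Xv)
    if postprocess is not None:
        pred = postprocess(pred, Xv)
    mse = float(np.mean((pred.astype(np.float64) - Yv) ** 2))
    reps = [fidelity_metrics(y, p) for y, p in zip(Yv, pred)]
    finite = [r.psnr for r in reps if np.isfinite(r.psnr)]
    return {"val_mse": mse,
            "val_psnr": float(np.mean(finite)) if finite else float("inf"),
            "val_ssim": float(np.mean([r.ssim for r in reps]))}


def train_gan(g: Model, d: Model, X: np.ndarray, Y: np.ndarray,
              cfg: TrainConfig, val: tuple | None = None,
              checkpoint_epochs: list[int] | None = None,
              out_dir: str | Path | None = None,
              postprocess=None):
    """Train ``g`` against ``d`` on paired arrays ``(X, Y)`` of shape (N, H, W).

    ``postprocess(pred, inputs)`` is applied before validation metrics (the
    inpainting model composites acquired rows there).  Returns
    ``(history, CheckpointSet)``; checkpoints are written to ``out_dir`` at
    the requested epochs (the final epoch is always included).
    """
    X = np.ascontiguousarray(X, dtype=DTYPE)
    Y = np.ascontiguousarray(Y, dtype=DTYPE)
    if X.shape != Y.shape or X.ndim != 3 or len(X) == 0:
        raise ValueError("X and Y must be matching nonempty (N, H, W) arrays")
    d_loss_fn, g_loss_fn = GAN_LOSSES[cfg.gan_loss]
    rng = np.random.default_rng(cfg.seed)
    opt_g = Adam(g.parameters(), lr=cfg.lr_at(1), betas=cfg.adam_betas,
                 weight_decay=cfg.weight_decay)
    opt_d = RMSprop(d.parameters(), lr=cfg.lr_at(1), alpha=cfg.rmsprop_alpha,
                    weight_decay=cfg.weight_decay, momentum=cfg.rmsprop_momentum)
    checkpoint_epochs = sorted(set(checkpoint_epochs or []))
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    ckpts = CheckpointSet()
    history = []
    n = len(X)
    step = 0
    done = False
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.lr_at(epoch)
        opt_g.lr = opt_d.lr = lr
        order = rng.permutation(n)
        ep_mse, ep_adv, ep_dloss, nb = 0.0, 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if idx.size < 2:
                continue  # relativistic means need >= 2 samples
            x = X[idx][:, None]
            y = Y[idx][:, None]
            fake, gcache = g.forward(x, train=True)
            real_pair = np.concatenate([y, x], axis=1)
            fake_pair = np.concatenate([fake, x], axis=1)

            # --- discriminator update ---
            opt_d.zero_grad()
            sr, cr = d.forward(real_pair, train=True)
            sf, cf = d.forward(fake_pair, train=True)
            dl, dsr, dsf = d_loss_fn(sr, sf)
            d.backward(dsr.astype(DTYPE), cr)
            d.backward(dsf.astype(DTYPE), cf)
            opt_d.step()

            # --- generator update (joint MSE + adversarial) ---
            mse, dmse = mse_loss(fake, y)
            dfake = dmse
            adv = 0.0
            if cfg.lambda_adv > 0:
                sr2, _ = d.forward(real_pair, train=True)
                sf2, cf2 = d.forward(fake_pair, train=True)
                adv, _, dsf2 = g_loss_fn(sr2, sf2)
                opt_d.zero_grad()  # discard D grads from the G pass
                dpair = d.backward(dsf2.astype(DTYPE), cf2)
                opt_d.zero_grad()
                dfake = dmse + DTYPE(cfg.lambda_adv) * dpair[:, :1]
            opt_g.zero_grad()
            g.backward(dfake.astype(DTYPE), gcache)
            opt_g.step()

            if not np.isfinite(mse):
                raise RuntimeError(f"non-finite loss at epoch {epoch} step {step}")
            ep_mse += mse
            ep_adv += adv
            ep_dloss += dl
            nb += 1
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
        rec = {"epoch": epoch, "lr": lr, "mse": ep_mse / max(nb, 1),
               "adv": ep_adv / max(nb, 1), "d_loss": ep_dloss / max(nb, 1),
               "g_steps": step}
        if val is not None:
            rec.update(_validate(g, val[0].astype(DTYPE), val[1], postprocess))
        history.append(rec)
        want_ckpt = epoch in checkpoint_epochs or epoch == cfg.epochs or done
        if want_ckpt and out_dir is not None:
            path = out_dir / f"gen_epoch{epoch:03d}.npz"
            save_checkpoint(g, path)
            ckpts.add(epoch, path, rec.get("val_mse", float("nan")),
                      rec.get("val_psnr", float("nan")),
                      rec.get("val_ssim", float("nan")))
        if done:
            break
    if out_dir is not None:
        (out_dir / "history.jsonl").write_text(
            "\n".join(json.dumps(h) for h in history) + "\n")
    return history, ckpts
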