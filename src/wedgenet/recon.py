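"""Classical reference reconstructions: WBP, SART and TV-regularized SART.

All three operate on the acquired rows only — zero-padded missing rows would
act as false constraints in the algebraic methods, and contribute nothing to
filtered back projection.  Outputs are deliberately not clipped to [0,1]:
overshoot is informative for the artifact-removal network, and clipping is
applied only at metric/export time.

Reconstructors are stateless sklearn-style transformers (``fit`` is a no-op)
so they compose with pipelines; ``reconstruct_wbp`` / ``reconstruct_sart`` /
``reconstruct_tvm`` are the equivalent functional entry points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon, iradon_sart
from sklearn.base import BaseEstimator, TransformerMixin

from .projection import Sinogram

__all__ = ["Tomogram", "IterativeConfig", "WBPReconstructor", "SARTReconstructor",
           "TVMReconstructor", "reconstruct_wbp", "reconstruct_sart",
           "reconstruct_tvm", "total_variation"]


@dataclass
class Tomogram:
    """A reconstructed 2-D slice on the phantom grid, with provenance."""

    pixels: np.ndarray
    provenance: dict

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.isfinite(self.pixels).all():
            raise ValueError("tomogram contains non-finite values")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class IterativeConfig:
    """Iteration controls shared by SART and TVM."""

    n_iterations: int = 20
    relaxation: float = 0.15
    tv_weight: float = 0.1
    tv_inner_steps: int = 10

    def __post_init__(self):
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if not (0 < self.relaxation < 2):
            raise ValueError("relaxation must lie in (0, 2)")
        if self.tv_weight < 0 or self.tv_inner_steps < 0:
            raise ValueError("tv_weight and tv_inner_steps must be >= 0")


def _acquired(sino: Sinogram):
    if not sino.mask.any():
        raise ValueError("sinogram has no acquired rows")
    raw = sino.raw[sino.mask]
    theta = sino.angle_grid.angles[sino.mask]
    return raw.T.astype(np.float64), theta  # (bins, n_acquired) for skimage


class WBPReconstructor(BaseEstimator, TransformerMixin):
    """Weighted back projection: ramp filtering then back projection.

    ``filter_name`` is the frequency-domain apodization: "ramp" (Ram-Lak,
    default, no window) or "hann".
    """

    def __init__(self, filter_name: str = "ramp"):
        self.filter_name = filter_name

    def fit(self, X=None, y=None):
        return self

    def transform_one(self, sino: Sinogram) -> Tomogram:
        vals, theta = _acquired(sino)
        px = iradon(vals, theta=theta, filter_name=self.filter_name,
                    circle=True, output_size=sino.n_bins)
        prov = {"method": "wbp", "filter": self.filter_name,
                "n_angles": int(sino.mask.sum())}
        return Tomogram(px, prov)

    def transform(self, X):
        return [self.transform_one(s) for s in X]


class SARTReconstructor(BaseEstimator, TransformerMixin):
    """Simultaneous algebraic reconstruction over the acquired rows only.

    Starts from a zero image and back-distributes relaxed projection
    residuals; missing rows exert no constraint.
    """

    def __init__(self, config: IterativeConfig | None = None):
        self.config = config

    def _cfg(self) -> IterativeConfig:
        return self.config or IterativeConfig()

    def fit(self, X=None, y=None):
        return self

    def transform_one(self, sino: Sinogram) -> Tomogram:
        cfg = self._cfg()
        vals, theta = _acquired(sino)
        est = np.zeros((sino.n_bins, sino.n_bins), dtype=np.float64)
        for it in range(cfg.n_iterations):
            est = iradon_sart(vals, theta=theta, image=est,
                              relaxation=cfg.relaxation)
            if not np.isfinite(est).all():
                raise FloatingPointError(f"SART diverged at iteration {it + 1}")
        prov = {"method": "sart", "n_iterations": cfg.n_iterations,
                "relaxation": cfg.relaxation, "n_angles": int(sino.mask.sum())}
        return Tomogram(est, prov)

    def transform(self, X):
        return [self.transform_one(s) for s in X]


def total_variation(px: np.ndarray, eps: float = 1e-8) -> float:
    """Isotropic total variation with forward differences."""
    gx = np.diff(px, axis=1, append=px[:, -1:])
    gy = np.diff(px, axis=0, append=px[-1:, :])
    return float(np.sum(np.sqrt(gx ** 2 + gy ** 2 + eps)))


def _tv_gradient(px: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    gx = np.diff(px, axis=1, append=px[:, -1:])
    gy = np.diff(px, axis=0, append=px[-1:, :])
    mag = np.sqrt(gx ** 2 + gy ** 2 + eps)
    nx, ny = gx / mag, gy / mag
    grad = np.zeros_like(px)
    grad -= nx
    grad[:, 1:] += nx[:, :-1]
    grad -= ny
    grad[1:, :] += ny[:-1, :]
    return grad  # d TV / d px  (negative divergence of the normalized gradient)


class TVMReconstructor(BaseEstimator, TransformerMixin):
    """SART alternated with total-variation gradient descent.

    After each SART sweep the estimate moves ``tv_inner_steps`` small steps
    down the TV gradient; the step length is ``tv_weight`` times the size of
    the last data update (so the regularizer never overwhelms the data term,
    and ``tv_weight = 0`` reduces exactly to SART).
    """

    def __init__(self, config: IterativeConfig | None = None):
        self.config = config

    def _cfg(self) -> IterativeConfig:
        return self.config or IterativeConfig(n_iterations=30)

    def fit(self, X=None, y=None):
        return self

    def transform_one(self, sino: Sinogram) -> Tomogram:
        cfg = self._cfg()
        vals, theta = _acquired(sino)
        est = np.zeros((sino.n_bins, sino.n_bins), dtype=np.float64)
        for it in range(cfg.n_iterations):
            prev = est.copy()  # iradon_sart may update its argument in place
            est = iradon_sart(vals, theta=theta, image=est,
                              relaxation=cfg.relaxation)
            if not np.isfinite(est).all():
                raise FloatingPointError(f"TVM diverged at iteration {it + 1}")
            if cfg.tv_weight > 0 and cfg.tv_inner_steps > 0:
                dp = float(np.linalg.norm(est - prev))
                step = cfg.tv_weight * dp / max(cfg.tv_inner_steps, 1)
                for _ in range(cfg.tv_inner_steps):
                    g = _tv_gradient(est)
                    gn = np.linalg.norm(g)
                    if gn < 1e-12:
                        break
                    # backtracking keeps every inner step TV non-increasing
                    tv0, s = total_variation(est), step
                    for _ in range(20):
                        cand = est - s * g / gn
                        if total_variation(cand) <= tv0:
                            est = cand
                            break
                        s *= 0.5
        prov = {"method": "tvm", "n_iterations": cfg.n_iterations,
                "relaxation": cfg.relaxation, "tv_weight": cfg.tv_weight,
                "tv_inner_steps": cfg.tv_inner_steps,
                "n_angles": int(sino.mask.sum())}
        return Tomogram(est, prov)

    def transform(self, X):
        return [self.transform_one(s) for s in X]


def reconstruct_wbp(sino: Sinogram, filter_name: str = "ramp") -> Tomogram:
    return WBPReconstructor(filter_name).transform_one(sino)


def reconstruct_sart(sino: Sinogram, cfg: IterativeConfig | None = None) -> Tomogram:
    return SARTReconstructor(cfg).transform_one(sino)


def reconstruct_tvm(sino: Sinogram, cfg: IterativeConfig | None = None) -> Tomogram:
    return TVMReconstructor(cfg).transform_one(sino)
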