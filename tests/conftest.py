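"""Shared fixtures.

The expensive fixtures (the smoke-trained inpainting and de-artifact GANs and
the tiny end-to-end pipeline runs) are session-scoped and shared between the
module tests and the acceptance tests, so each GAN is trained exactly once
per test session.  Smoke scale: 64x64 phantoms, a 3-degree tilt grid (60
projections), a 45-degree missing wedge, a 2-block RRDB generator and a
depth-3 U-net.
"""

from __future__ import annotations

import numpy as np
import pytest

from wedgenet import (AngleGrid, ArtifactRemover, IterativeConfig,
                      SinogramInpainter, TrainConfig, WedgeSpec,
                      apply_missing_wedge, build_sinogram_dataset,
                      denormalize_sinogram, fidelity_metrics, forward_project,
                      generate_suite, joint_reconstruct, normalize_sinogram,
                      reconstruct_sart, reconstruct_wbp)
from wedgenet.deartifact import DeartifactRecipe, assemble_deartifact_dataset

SMOKE_SIZE = 64
SMOKE_STEP = 3.0


@pytest.fixture(scope="session")
def grid3():
    return AngleGrid.uniform(SMOKE_STEP)


@pytest.fixture(scope="session")
def wedge45():
    return WedgeSpec(45.0)


@pytest.fixture(scope="session")
def train_phantoms():
    return generate_suite(36, SMOKE_SIZE, seed=0)


@pytest.fixture(scope="session")
def holdout_phantoms():
    return generate_suite(20, SMOKE_SIZE, seed=1)


@pytest.fixture(scope="session")
def sino_data(train_phantoms, grid3, wedge45):
    X, Y, mask = build_sinogram_dataset(train_phantoms, grid3, wedge45)
    return X, Y, mask


@pytest.fixture(scope="session")
def trained_inpainter(sino_data, tmp_path_factory):
    """2-block RRDB inpainter, 200 generator steps at constant LR 1e-3."""
    X, Y, mask = sino_data
    out = tmp_path_factory.mktemp("inpaint_ckpt")
    cfg = TrainConfig(epochs=50, batch_size=4, lr_override=1e-3, seed=0,
                      max_steps=200)
    est = SinogramInpainter(n_blocks=2, feature_depth=16, growth_channels=8,
                            d_feature_depth=16, slow_path_depth=4,
                            fast_path_depth=2, train_config=cfg,
                            checkpoint_epochs=[8], out_dir=str(out))
    est.fit(X, Y, mask=mask)
    return est


@pytest.fixture(scope="session")
def deartifact_data(train_phantoms, trained_inpainter, grid3, wedge45):
    gens = [trained_inpainter.checkpoints_.load_generator(i)
            for i in range(len(trained_inpainter.checkpoints_))]
    return assemble_deartifact_dataset(
        train_phantoms, gens, DeartifactRecipe(), total=72, seed=3,
        grid=grid3, wedge=wedge45,
        sart_cfg=IterativeConfig(n_iterations=10))


@pytest.fixture(scope="session")
def trained_remover(deartifact_data):
    """Depth-3 U-net de-artifacter, 400 generator steps."""
    cfg = TrainConfig(epochs=50, batch_size=8, lr_override=1e-3, seed=7,
                      max_steps=400)
    est = ArtifactRemover(depth=3, base_channels=16, d_feature_depth=16,
                          d_layers=3, train_config=cfg)
    est.fit(deartifact_data["inputs"], deartifact_data["targets"])
    return est


@pytest.fixture(scope="session")
def holdout_eval(holdout_phantoms, trained_inpainter, trained_remover, grid3,
                 wedge45):
    """Per-phantom held-out scores for the joint model and the baselines."""
    out = {"ssim_joint": [], "ssim_wbp": [], "ssim_sart": [],
           "guard_mse_in": [], "guard_mse_out": []}
    for ph in holdout_phantoms:
        complete = normalize_sinogram(forward_project(ph, grid3))
        masked = apply_missing_wedge(complete, wedge45, pad_zeros=True)
        raw = denormalize_sinogram(masked)
        out["ssim_wbp"].append(fidelity_metrics(ph.pixels,
                                                reconstruct_wbp(raw).pixels).ssim)
        out["ssim_sart"].append(fidelity_metrics(
            ph.pixels, reconstruct_sart(raw).pixels).ssim)
        joint = joint_reconstruct(masked, trained_inpainter, trained_remover)
        out["ssim_joint"].append(fidelity_metrics(ph.pixels, joint.pixels).ssim)
        cwbp = reconstruct_wbp(denormalize_sinogram(complete))
        cleaned = trained_remover.transform(cwbp.pixels[None])[0]
        out["guard_mse_in"].append(float(np.mean((cwbp.pixels - ph.pixels) ** 2)))
        out["guard_mse_out"].append(float(np.mean((cleaned - ph.pixels) ** 2)))
    return {k: np.asarray(v) for k, v in out.items()}


TINY_CFG = dict(
    n_train=12, n_holdout=4, size=64, angle_step=6.0,
    inpaint_train=dict(epochs=20, batch_size=4, lr_override=1e-3, max_steps=30),
    deartifact_total=18,
    deartifact_train=dict(epochs=20, batch_size=6, lr_override=1e-3, max_steps=40),
    methods=("wbp",), sart_iterations=5)


@pytest.fixture(scope="session")
def tiny_pipeline_runs(tmp_path_factory):
    """Two independent tiny end-to-end runs plus cached/invalidation reruns."""
    import shutil

    from wedgenet.pipeline import ExperimentConfig, run_experiment

    root = tmp_path_factory.mktemp("pipeline")
    cfg_a = ExperimentConfig(seed=5, out_root=str(root / "a"), **TINY_CFG)
    cfg_b = ExperimentConfig(seed=5, out_root=str(root / "b"), **TINY_CFG)
    rep_a = run_experiment(cfg_a)
    rep_b = run_experiment(cfg_b)
    rep_a_cached = run_experiment(cfg_a)
    shutil.rmtree(root / "a" / "deartifact")
    rep_a_invalidated = run_experiment(cfg_a)
    return dict(a=rep_a, b=rep_b, cached=rep_a_cached,
                invalidated=rep_a_invalidated)
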