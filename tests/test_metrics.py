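"""Fidelity metrics, the perceptual index and the NIQE model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wedgenet.metrics import (evaluate_methods, fidelity_metrics,
                              perceptual_index)
from wedgenet.niqe import fit_niqe_model, niqe_score
from wedgenet.phantoms import generate_suite
from wedgenet.projection import (AngleGrid, WedgeSpec, apply_missing_wedge,
                                 forward_project)
from wedgenet.recon import reconstruct_wbp


class TestFidelityMetrics:
    def test_identical_images(self):
        x = generate_suite(1, 64, seed=0)[0].pixels
        rep = fidelity_metrics(x, x)
        assert rep.ssim == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert rep.psnr == float("inf")

    def test_closed_form_constant_images(self):
        ref = np.full((32, 32), 255.0)
        test = np.full((32, 32), 127.5)
        rep = fidelity_metrics(ref, test, ref_range=(0.0, 255.0))
        assert rep.rmse == pytest.approx(127.5)
        assert rep.psnr == pytest.approx(10 * np.log10(255 ** 2 / 127.5 ** 2),
                                         abs=1e-9)

    def test_psnr_rmse_consistency(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.random((32, 32))
            b = rng.random((32, 32))
            rep = fidelity_metrics(a, b)
            assert rep.psnr == pytest.approx(20 * np.log10(255.0 / rep.rmse),
                                             abs=1e-9)

    def test_ssim_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        assert (fidelity_metrics(a, b).ssim
                == pytest.approx(fidelity_metrics(b, a).ssim, abs=1e-12))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fidelity_metrics(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPerceptualIndex:
    @pytest.mark.parametrize("ma,niqe,expected", [(10.0, 0.0, 0.0),
                                                  (0.0, 10.0, 10.0),
                                                  (5.0, 5.0, 5.0)])
    def test_formula(self, ma, niqe, expected):
        assert perceptual_index(ma, niqe) == expected

    @given(ma=st.floats(0, 10), niqe=st.floats(0, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_formula_exact(self, ma, niqe):
        assert perceptual_index(ma, niqe) == ((10.0 - ma) + niqe) / 2.0

    def test_out_of_range_ma_rejected(self):
        with pytest.raises(ValueError):
            perceptual_index(11.0, 5.0)


@pytest.fixture(scope="module")
def niqe_model():
    return fit_niqe_model(generate_suite(50, 128, seed=100))


class TestNiqe:
    def test_fit_is_deterministic_and_psd(self, niqe_model):
        again = fit_niqe_model(generate_suite(50, 128, seed=100))
        np.testing.assert_array_equal(niqe_model.mean, again.mean)
        np.testing.assert_array_equal(niqe_model.cov, again.cov)
        assert np.allclose(niqe_model.cov, niqe_model.cov.T)
        assert np.linalg.eigvalsh(niqe_model.cov).min() >= 0

    def test_small_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_niqe_model(generate_suite(10, 128, seed=0))

    def test_pristine_scores_below_missing_wedge_wbp(self, niqe_model):
        grid = AngleGrid.uniform(3.0)
        pristine, corrupted = [], []
        for ph in generate_suite(5, 128, seed=999):
            masked = apply_missing_wedge(forward_project(ph, grid),
                                         WedgeSpec(45.0))
            pristine.append(niqe_score(ph.pixels, niqe_model))
            corrupted.append(niqe_score(reconstruct_wbp(masked).pixels,
                                        niqe_model))
        assert np.mean(pristine) < np.mean(corrupted)

    def test_streak_corruption_increases_score(self, niqe_model):
        stripes = 0.5 * np.sin(np.arange(128) * 2.0)[None, :]
        for ph in generate_suite(5, 128, seed=50):
            clean = niqe_score(ph.pixels, niqe_model)
            assert niqe_score(ph.pixels + stripes, niqe_model) > clean

    def test_offset_invariance(self, niqe_model):
        px = generate_suite(1, 128, seed=7)[0].pixels
        delta = abs(niqe_score(px + 0.3, niqe_model) - niqe_score(px, niqe_model))
        assert delta < 1e-3

    def test_calibration_on_corpus(self, niqe_model):
        scores = [niqe_score(p.pixels, niqe_model)
                  for p in generate_suite(20, 128, seed=100)]
        bound = np.mean(scores) + 2 * np.std(scores)
        unseen = generate_suite(1, 128, seed=123456)[0]
        assert niqe_score(unseen.pixels, niqe_model) <= bound

    def test_too_small_image_rejected(self, niqe_model):
        with pytest.raises(ValueError):
            niqe_score(np.zeros((8, 8)), niqe_model)


class TestEvaluateMethods:
    def test_single_phantom_wbp_table(self):
        suite = generate_suite(1, 64, seed=0)
        table = evaluate_methods(suite, WedgeSpec(45.0), methods=("wbp",),
                                 grid=AngleGrid.uniform(6.0))
        assert list(table.index) == ["missing_wbp", "complete_wbp"]
        assert np.isfinite(table.to_numpy()).all()

    def test_complete_beats_missing_and_determinism(self):
        suite = generate_suite(4, 64, seed=2)
        grid = AngleGrid.uniform(6.0)
        t1 = evaluate_methods(suite, WedgeSpec(45.0), methods=("wbp",), grid=grid)
        t2 = evaluate_methods(suite, WedgeSpec(45.0), methods=("wbp",), grid=grid)
        assert t1.loc["complete_wbp", "psnr"] > t1.loc["missing_wbp", "psnr"]
        assert t1.equals(t2)

    def test_joint_without_models_rejected(self):
        suite = generate_suite(1, 64, seed=0)
        with pytest.raises(ValueError):
            evaluate_methods(suite, WedgeSpec(45.0), methods=("wbp", "joint"),
                             grid=AngleGrid.uniform(6.0))
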