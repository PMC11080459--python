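import numpy as np
import pytest

from metabarcode.grid import SpectralGrid
from metabarcode.datasets import LabeledDataset
from metabarcode.nn import (ModelSpec, TrainConfig, build_model,
                            integrated_gradients, metapixel_importance,
                            select_top_metapixels, train)
from metabarcode.nn.layers import Flatten, Linear
from metabarcode.nn.model import CNN1D


def linear_model(width=20, seed=0):
    """CNN1D shell around a pure linear map F(x) = W x + b."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec("pruned", n_wavenumbers=width, dropout=0.0)
    lin = Linear(width, 2, rng)
    return CNN1D(spec, [Flatten(), lin], width), lin


class TestIntegratedGradients:
    def test_zero_input_gives_zero_attributions(self):
        m = build_model(ModelSpec("pruned", n_wavenumbers=30), seed=0)
        x = np.zeros((1, 30), dtype=np.float32)
        att = integrated_gradients(m, x, target_class=1, n_steps=8)
        assert np.all(att.per_feature == 0.0)

    @pytest.mark.parametrize("n_steps", [2, 16, 257])
    def test_linear_model_closed_form(self, n_steps):
        """For F(x) = w.x the Riemann sum is exact at any step count:
        IG_i = w_i * x_i."""
        m, lin = linear_model()
        x = np.random.default_rng(1).random((1, 20)).astype(np.float32)
        att = integrated_gradients(m, x, target_class=1, n_steps=n_steps)
        expected = lin.W[1].astype(np.float64) * x[0].astype(np.float64)
        assert np.allclose(att.per_feature.ravel(), expected, rtol=1e-4,
                           atol=1e-7)
        assert att.completeness_residual <= 1e-4 * abs(att.delta) + 1e-6

    def test_attribution_batch_chunking_consistent(self):
        m = build_model(ModelSpec("pruned", n_wavenumbers=30), seed=1)
        x = np.random.default_rng(2).random((1, 30)).astype(np.float32)
        a = integrated_gradients(m, x, target_class=0, n_steps=64,
                                 batch_steps=64)
        b = integrated_gradients(m, x, target_class=0, n_steps=64,
                                 batch_steps=7)
        assert np.allclose(a.per_feature, b.per_feature, rtol=1e-5, atol=1e-9)

    def test_self_convergence_and_completeness(self):
        """On a trained nonlinear model, attributions converge as the
        quadrature refines and the completeness residual shrinks."""
        rng = np.random.default_rng(3)
        width = 40
        X = rng.random((30, 1, width)).astype(np.float32)
        y = np.repeat([0, 1], 15)
        X[y == 1, :, 10:20] += 0.4
        grid = SpectralGrid(1300.0, 1300.0 + 2 * (width - 1), 2.0)
        ds = LabeledDataset(X, y, grid, np.array([1500.0]))
        m = build_model(ModelSpec("pruned", n_wavenumbers=width, dropout=0.2),
                        seed=3)
        train(m, ds, TrainConfig(epochs=40, seed=3))
        x = X[-1]
        coarse = integrated_gradients(m, x, n_steps=512)
        fine = integrated_gradients(m, x, n_steps=4096)
        num = np.abs(coarse.per_feature - fine.per_feature).sum()
        den = np.abs(fine.per_feature).sum()
        assert num / den < 0.01
        # at these step counts the quadrature error sits at the float32
        # accumulation floor, so assert the bound rather than monotonicity
        assert coarse.completeness_residual <= 0.01 * abs(coarse.delta) + 1e-8
        assert fine.completeness_residual <= 0.01 * abs(fine.delta) + 1e-8

    def test_too_few_steps_rejected(self):
        m, _ = linear_model()
        with pytest.raises(ValueError):
            integrated_gradients(m, np.ones((1, 20), dtype=np.float32),
                                 n_steps=1)


class TestMetapixelImportance:
    def test_single_block_support_is_one_hot(self):
        att = np.zeros((5, 10))
        att[2, 3] = 4.0
        imp = metapixel_importance(att)
        assert imp.tolist() == [0, 0, 1, 0, 0]

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        att = rng.normal(size=(5, 10))
        assert np.allclose(metapixel_importance(att),
                           metapixel_importance(10.0 * att))

    def test_flat_layout_needs_block_count(self):
        att = np.zeros(50)
        with pytest.raises(ValueError):
            metapixel_importance(att)
        imp = metapixel_importance(att.reshape(1, 50), n_metapixels=5)
        assert imp.shape == (5,)

    def test_average_over_items(self):
        a = np.zeros((2, 4))
        a[0, 0] = 1.0
        b = np.zeros((2, 4))
        b[1, 0] = 3.0
        imp = metapixel_importance([a, b])
        assert np.allclose(imp, [0.5 / 1.5, 1.0])


class TestSelectTop:
    nus = np.array([1400.0, 1500.0, 1600.0, 1700.0])

    def test_unique_maximum(self):
        imp = np.array([0.1, 0.9, 0.3, 0.2])
        assert select_top_metapixels(imp, self.nus, 1).tolist() == [1]

    def test_k_equals_n_sorted_by_importance(self):
        imp = np.array([0.1, 0.9, 0.3, 0.2])
        assert select_top_metapixels(imp, self.nus, 4).tolist() == [1, 2, 3, 0]

    def test_tie_broken_by_lower_resonance(self):
        imp = np.array([0.5, 0.9, 0.9, 0.1])
        assert select_top_metapixels(imp, self.nus, 2).tolist() == [1, 2]
        imp2 = np.array([0.5, 0.9, 0.9, 0.1])
        nus_swapped = np.array([1400.0, 1600.0, 1500.0, 1700.0])
        assert select_top_metapixels(imp2, nus_swapped, 1).tolist() == [2]

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            select_top_metapixels(np.ones(4), self.nus, 5)
        with pytest.raises(ValueError):
            select_top_metapixels(np.ones(4), self.nus, 0)
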