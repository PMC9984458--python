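"""CMSFL block: conv unit semantics, wiring, initialization."""

import numpy as np
import pytest

from cmsfl import _ops
from cmsfl.block import (
    CMSFLModuleParams,
    ConvUnitParams,
    cmsfl_forward,
    conv_bn_act,
    conv_bn_act_backward,
    init_module,
)


def identity_unit(f, c_in, weights=None):
    """Unit whose BN is the identity in eval mode (gain 1, bias 0, stats 0/1)."""
    w = weights if weights is not None else np.zeros((f, c_in, 3, 3))
    return ConvUnitParams(
        weights=np.asarray(w, dtype=np.float64),
        bn_gain=np.ones(f), bn_bias=np.zeros(f),
        bn_running_mean=np.zeros(f), bn_running_var=np.ones(f),
    )


class TestConvUnit:
    def test_zero_weights_give_zero_output(self, rng):
        unit = identity_unit(1, 2)
        x = rng.random((3, 2, 5, 5))
        out = conv_bn_act(x, unit, mode="eval")
        assert out.shape == (3, 1, 5, 5)
        np.testing.assert_array_equal(out, 0.0)

    @pytest.mark.parametrize("c", [0.3, -0.5])
    def test_all_ones_filter_on_constant_input(self, c):
        """Interior pixels of an all-ones 3x3 filter on constant c see the
        full window: output max(0, 9c) under identity BN."""
        unit = identity_unit(1, 1, np.ones((1, 1, 3, 3)))
        x = np.full((1, 1, 3, 3), c)
        out = conv_bn_act(x, unit, mode="eval")
        # BN's variance epsilon (1e-5) makes identity-BN exact only to ~5e-6
        assert out[0, 0, 1, 1] == pytest.approx(max(0.0, 9 * c), abs=1e-4)

    @pytest.mark.parametrize("shape,f", [
        ((1, 1, 5, 5), 1), ((2, 3, 8, 8), 4), ((2, 2, 6, 7), 3),
    ])
    def test_matches_bruteforce_convolution(self, rng, shape, f):
        """Pre-BN output equals the nested-summation reference everywhere."""
        x = rng.random(shape)
        w = rng.normal(0, 0.4, (f, shape[1], 3, 3))
        fast, _ = _ops.conv3x3_forward(x, w, want_cache=False)
        slow = _ops.conv3x3_bruteforce(x, w)
        np.testing.assert_allclose(fast, slow, atol=1e-5)

    def test_channel_mismatch_names_expected_and_actual(self, rng):
        unit = identity_unit(1, 3)
        with pytest.raises(ValueError, match="expected 3.*got 2"):
            conv_bn_act(rng.random((1, 2, 4, 4)), unit)

    def test_train_mode_batch_normalizes(self, rng):
        unit = identity_unit(2, 1, rng.normal(0, 0.3, (2, 1, 3, 3)))
        out = conv_bn_act(rng.random((4, 1, 8, 8)), unit, mode="train")
        pre_relu_mean = None  # BN output is zero-mean per channel before ReLU
        # running stats must have moved off their (0, 1) initialization
        assert not np.allclose(unit.bn_running_mean, 0.0)

    def test_backward_matches_numeric_gradient(self, rng):
        unit = identity_unit(2, 2, rng.normal(0, 0.4, (2, 2, 3, 3)))
        x = rng.random((2, 2, 4, 4))
        y, cache = conv_bn_act(x, unit, mode="train", want_cache=True)
        dy = rng.random(y.shape)
        dx, dw, dg, db = conv_bn_act_backward(dy, cache)
        eps = 1e-6
        for arr, grad in ((x, dx), (unit.weights, dw), (unit.bn_gain, dg)):
            for _ in range(6):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = (conv_bn_act(x, unit, "train") * dy).sum()
                arr[idx] = orig - eps
                lm = (conv_bn_act(x, unit, "train") * dy).sum()
                arr[idx] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(grad[idx], abs=1e-4)


class TestModule:
    def test_output_shape_doubles_channels(self, rng):
        p = init_module(in_channels=3, filters=32, seed=0)
        x = rng.random((2, 3, 8, 8)).astype(np.float32)
        out = cmsfl_forward(x, p, mode="eval")
        assert out.shape == (2, 64, 8, 8)

    def test_exactly_seven_convolutions(self):
        p = init_module(3, 8, seed=0)
        assert len(p.mb_units) + len(p.sb_units) == 7

    def test_wiring_channel_counts(self):
        p = init_module(3, 32, seed=0)
        assert [u.weights.shape for u in p.mb_units] == [
            (32, 3, 3, 3), (32, 32, 3, 3), (32, 64, 3, 3), (32, 64, 3, 3)
        ]
        assert all(u.weights.shape == (32, 3, 3, 3) for u in p.sb_units)

    def test_zeroed_final_sb_unit_touches_only_last_channels(self, rng):
        """Zeroing the final-stage SB conv leaves the main-branch half of
        the output bit-identical; its own half becomes ReLU(BN(0)) = 0.
        (Earlier SB units feed the later MB convs through the stage
        concatenations, so only the final stage has this isolation.)"""
        p = init_module(2, 4, seed=1)
        x = rng.random((2, 2, 8, 8)).astype(np.float64)
        base = cmsfl_forward(x, p, mode="eval")
        p.sb_units[2].weights = np.zeros_like(p.sb_units[2].weights)
        zeroed = cmsfl_forward(x, p, mode="eval")
        np.testing.assert_array_equal(base[:, :4], zeroed[:, :4])
        np.testing.assert_array_equal(zeroed[:, 4:], 0.0)
        assert not np.array_equal(base[:, 4:], zeroed[:, 4:])

    def test_secondary_branch_is_live(self, rng):
        """Perturbing any SB unit changes the module output."""
        x = rng.random((1, 3, 8, 8))
        for k in range(3):
            p = init_module(3, 4, seed=2)
            base = cmsfl_forward(x, p, mode="eval")
            p.sb_units[k].weights = p.sb_units[k].weights + 0.5
            assert not np.array_equal(cmsfl_forward(x, p, mode="eval"), base)

    def test_spatial_dims_preserved(self, rng):
        p = init_module(1, 4, seed=0)
        for h, w in ((8, 8), (6, 10)):
            out = cmsfl_forward(rng.random((1, 1, h, w)), p, mode="eval")
            assert out.shape[2:] == (h, w)

    def test_module_validates_branch_counts(self):
        p = init_module(3, 4, seed=0)
        with pytest.raises(ValueError, match="4 main and 3 secondary"):
            CMSFLModuleParams(mb_units=p.mb_units[:3], sb_units=p.sb_units,
                              filters=4)


class TestInit:
    def test_deterministic_given_seed(self):
        a, b = init_module(3, 8, seed=5), init_module(3, 8, seed=5)
        for (na, ua), (nb, ub) in zip(a.units(), b.units()):
            assert na == nb
            np.testing.assert_array_equal(ua.weights, ub.weights)

    def test_he_standard_deviation(self):
        """Empirical sd of mb1 weights ~ sqrt(2 / (9 * in_channels))."""
        p = init_module(in_channels=3, filters=1024, seed=0)
        sd = p.mb_units[0].weights.std()
        assert sd == pytest.approx(np.sqrt(2 / 27), rel=0.1)

    def test_bn_state_initialized_to_identity(self):
        p = init_module(3, 8, seed=0)
        for _, u in p.units():
            np.testing.assert_array_equal(u.bn_gain, 1.0)
            np.testing.assert_array_equal(u.bn_bias, 0.0)
            np.testing.assert_array_equal(u.bn_running_mean, 0.0)
            np.testing.assert_array_equal(u.bn_running_var, 1.0)
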