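"""Architecture components against independent oracles.

The dilated convolution is checked elementwise against a brute-force
triple loop over the defining sum y(m) = sum_t x(m + r*t - pad) w(t);
the attention gate against explicit scalar evaluation on a four-position
toy instance; ASPP against the dilated-conv oracle with hand-set
weights.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mciagaspp import autodiff as ad
from mciagaspp import nn
from mciagaspp.architecture import (
    ASPP,
    AttentionGate,
    AttentionGateParams,
    ModelConfig,
    aspp,
    attention_gate,
    build_model,
    dilated_conv,
    effective_kernel_size,
)


# --------------------------------------------------------------------------
# effective kernel size
# --------------------------------------------------------------------------

@pytest.mark.parametrize("k,d,expected", [(3, 2, 5), (3, 3, 7), (3, 1, 3), (5, 1, 5),
                                          (5, 2, 9), (1, 4, 1)])
def test_effective_kernel_size_values(k, d, expected):
    assert effective_kernel_size(k, d) == expected


@given(k=st.sampled_from([3, 5, 7]), d=st.integers(min_value=1, max_value=10))
@settings(deadline=None, max_examples=40)
def test_effective_kernel_size_increasing_in_rate(k, d):
    assert effective_kernel_size(k, d + 1) > effective_kernel_size(k, d)


def test_effective_kernel_size_validation():
    with pytest.raises(ValueError):
        effective_kernel_size(4, 2)
    with pytest.raises(ValueError):
        effective_kernel_size(3, 0)
    with pytest.raises(ValueError):
        effective_kernel_size(-3, 1)


# --------------------------------------------------------------------------
# dilated convolution vs brute force
# --------------------------------------------------------------------------

def brute_force_dilated(x, w, r):
    """Direct evaluation of the dilated-convolution sum with zero padding."""
    B, C, D, H, W = x.shape
    O = w.shape[0]
    ks = w.shape[2:]
    pads = [(k + (k - 1) * (r - 1) - 1) // 2 for k in ks]
    out = np.zeros((B, O, D, H, W))
    for b in range(B):
        for o in range(O):
            for m in range(D):
                for n in range(H):
                    for p in range(W):
                        acc = 0.0
                        for c in range(C):
                            for i in range(ks[0]):
                                for j in range(ks[1]):
                                    for k in range(ks[2]):
                                        z = m + r * i - pads[0]
                                        y = n + r * j - pads[1]
                                        q = p + r * k - pads[2]
                                        if 0 <= z < D and 0 <= y < H and 0 <= q < W:
                                            acc += x[b, c, z, y, q] * w[o, c, i, j, k]
                        out[b, o, m, n, p] = acc
    return out


@pytest.mark.parametrize("shape,ksize,rate", [
    ((1, 1, 7, 7, 7), 3, 1),
    ((1, 1, 7, 7, 7), 3, 2),
    ((1, 1, 9, 8, 9), 3, 3),
    ((2, 2, 6, 7, 6), 3, 2),
    ((1, 2, 5, 5, 5), 1, 3),
])
def test_dilated_conv_matches_brute_force(shape, ksize, rate, rng):
    x = rng.normal(size=shape)
    w = rng.normal(size=(2, shape[1]) + (ksize,) * 3)
    got = dilated_conv(x, w, rate)
    expected = brute_force_dilated(x, w, rate)
    np.testing.assert_allclose(got, expected, atol=1e-5)
    assert got.shape == expected.shape  # 'same' padding preserves dims


def test_dilated_conv_ones_counts_inbounds_taps():
    x = np.ones((1, 1, 7, 7, 7))
    w = np.ones((1, 1, 3, 3, 3))
    got = dilated_conv(x, w, 2)
    # interior voxels see all 27 taps; corners only the in-bounds ones
    assert got[0, 0, 3, 3, 3] == pytest.approx(27.0)
    np.testing.assert_allclose(got, brute_force_dilated(x, w, 2), atol=1e-6)


def test_dilated_conv_impulse_response(rng):
    """A delta input reproduces the kernel taps spaced at the dilation rate."""
    r = 3
    x = np.zeros((1, 1, 13, 13, 13))
    x[0, 0, 6, 6, 6] = 1.0
    w = rng.normal(size=(1, 1, 3, 3, 3))
    got = dilated_conv(x, w, r)
    expected = np.zeros_like(got)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                # y(m) = sum_i x(m + r*i - pad) w(i): tap i lands at 6 - (i-1)*r
                expected[0, 0, 6 - (i - 1) * r, 6 - (j - 1) * r, 6 - (k - 1) * r] = w[0, 0, i, j, k]
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_rate_one_equals_ordinary_convolution(rng):
    from scipy import ndimage

    x = rng.normal(size=(1, 1, 6, 6, 6))
    w = rng.normal(size=(1, 1, 3, 3, 3))
    got = dilated_conv(x, w, 1)
    ref = ndimage.correlate(x[0, 0], w[0, 0], mode="constant", cval=0.0)
    np.testing.assert_allclose(got[0, 0], ref, atol=1e-10)


# --------------------------------------------------------------------------
# attention gate
# --------------------------------------------------------------------------

def _gate_params(F_l, F_g, F_int, seed=0, sigma2="softmax"):
    return AttentionGateParams.init(
        F_l, F_g, F_int, np.random.default_rng(seed), sigma2=sigma2
    )


def test_softmax_alpha_sums_to_one_per_sample(rng):
    params = _gate_params(4, 8, 3, seed=1)
    x_l = ad.Tensor(rng.normal(size=(3, 4, 8, 8, 8)))
    g = ad.Tensor(rng.normal(size=(3, 8, 4, 4, 4)))
    _, alpha = attention_gate(x_l, g, params)
    sums = alpha.data.reshape(3, -1).sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)
    assert (alpha.data >= 0).all()


def test_toy_instance_matches_scalar_evaluation():
    """Hand-set 1-channel gate on a 2x2 plane, evaluated by scalar loops."""
    x = np.array([[0.5, -1.0], [2.0, 0.25]])
    gsig = np.array([[1.0, 0.5], [-3.0, 0.75]])
    params = AttentionGateParams(
        F_l=1, F_g=1, F_int=1,
        W_x=ad.Tensor(np.ones((1, 1))), W_g=ad.Tensor(np.ones((1, 1))),
        psi=ad.Tensor(np.ones(1)), b_xg=ad.Tensor(np.zeros(1)),
        b_psi=ad.Tensor(np.zeros(1)), sigma2="softmax",
    )
    x_l = ad.Tensor(x.reshape(1, 1, 1, 2, 2))
    g = ad.Tensor(gsig.reshape(1, 1, 1, 2, 2))
    gated, alpha = attention_gate(x_l, g, params)

    q = np.maximum(x + gsig, 0.0)
    e = np.exp(q - q.max())
    alpha_expected = e / e.sum()
    np.testing.assert_allclose(alpha.data[0, 0, 0], alpha_expected, rtol=1e-5)
    np.testing.assert_allclose(gated.data[0, 0, 0], alpha_expected * x, rtol=1e-5)


def test_zero_alpha_zeroes_every_channel(rng):
    params = _gate_params(3, 2, 2, seed=2, sigma2="sigmoid")
    # sigmoid(q) -> 0 when psi weights are hugely negative via bias
    params.b_psi.data[:] = -50.0
    params.psi.data[:] = 0.0
    x_l = ad.Tensor(rng.normal(size=(1, 3, 4, 4, 4)))
    g = ad.Tensor(rng.normal(size=(1, 2, 2, 2, 2)))
    gated, alpha = attention_gate(x_l, g, params)
    np.testing.assert_allclose(alpha.data, 0.0, atol=1e-12)
    np.testing.assert_allclose(gated.data, 0.0, atol=1e-10)


def test_attention_gate_channel_mismatch_rejected(rng):
    params = _gate_params(4, 8, 3)
    with pytest.raises(ValueError, match="channels"):
        attention_gate(
            ad.Tensor(rng.normal(size=(1, 5, 4, 4, 4))),
            ad.Tensor(rng.normal(size=(1, 8, 2, 2, 2))),
            params,
        )


# --------------------------------------------------------------------------
# ASPP
# --------------------------------------------------------------------------

def test_aspp_preserves_spatial_dims(rng):
    x = rng.normal(size=(2, 3, 6, 7, 6)).astype(np.float32)
    for rates in ([1], [1, 2], [1, 2, 3]):
        out = aspp(x, rates, out_channels=5, rng=np.random.default_rng(0))
        assert out.shape == (2, 5, 6, 7, 6)


def test_aspp_preprojection_channel_arithmetic(rng):
    module = ASPP(3, [1, 2, 3], out_channels=4, branch_channels=6,
                  rng=np.random.default_rng(0))
    assert module.project.weight.shape[1] == (3 + 1) * 6


def test_aspp_single_rate_reduces_to_plain_convolution(rng):
    """With the pointwise branch zeroed and the projection set to select
    the dilated branch, ASPP equals the dilated-conv oracle at rate 1."""
    c = 2
    module = ASPP(c, [1], out_channels=c, branch_channels=c,
                  rng=np.random.default_rng(3))
    module.point_branch.weight.data[:] = 0.0
    module.point_branch.bias.data[:] = 0.0
    module.branches[0].bias.data[:] = 0.0
    proj = np.zeros_like(module.project.weight.data)
    for i in range(c):
        proj[i, i, 0, 0, 0] = 1.0
    module.project.weight.data = proj
    module.project.bias.data[:] = 0.0

    x = rng.normal(size=(1, c, 6, 6, 6)).astype(np.float32)
    got = module(ad.Tensor(x)).data
    expected = dilated_conv(x, module.branches[0].weight.data, 1)
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_aspp_rejects_empty_rates():
    with pytest.raises(ValueError, match="rates"):
        ASPP(2, [], out_channels=2)


# --------------------------------------------------------------------------
# full model
# --------------------------------------------------------------------------

GRID = (16, 20, 16)


def _config(variant, **kw):
    return ModelConfig(variant=variant, input_grid=GRID, base_channels=4, **kw)


@pytest.mark.parametrize("variant", ["baseline", "ag", "ag_aspp"])
def test_forward_shape_contract(variant, rng):
    model = build_model(_config(variant), seed=0)
    x = rng.normal(size=(2, 1) + GRID).astype(np.float32)
    out = model(ad.Tensor(x))
    assert out.shape == (2, 2)


def test_parameter_counts_strictly_ordered():
    counts = {
        v: build_model(_config(v), seed=0).n_parameters()
        for v in ("baseline", "ag", "ag_aspp")
    }
    assert counts["baseline"] < counts["ag"] < counts["ag_aspp"]


def test_build_determinism(rng):
    a = build_model(_config("ag_aspp"), seed=5)
    b = build_model(_config("ag_aspp"), seed=5)
    sa, sb = a.state_dict(), b.state_dict()
    assert sa.keys() == sb.keys()
    for k in sa:
        np.testing.assert_array_equal(sa[k], sb[k])
    x = rng.normal(size=(1, 1) + GRID).astype(np.float32)
    np.testing.assert_array_equal(a(ad.Tensor(x)).data, b(ad.Tensor(x)).data)
    c = build_model(_config("ag_aspp"), seed=6)
    assert any(
        not np.array_equal(sa[k], v) for k, v in c.state_dict().items()
    )


@pytest.mark.parametrize("variant", ["baseline", "ag", "ag_aspp"])
def test_gradients_reach_every_parameter(variant, rng):
    """One training step sends gradient to every parameter (sigmoid gating:
    under spatial softmax the gate's scalar bias is provably inert, since
    softmax is invariant to constant shifts of its input)."""
    model = build_model(_config(variant, sigma2="sigmoid"), seed=1)
    x = rng.normal(size=(2, 1) + GRID).astype(np.float32)
    loss = ad.cross_entropy(model(ad.Tensor(x)), np.array([0, 1]))
    loss.backward()
    dead = [n for n, p in model.named_parameters() if p.grad is None or not np.any(p.grad)]
    assert dead == []


def test_truncated_normal_initialization_bounds():
    model = build_model(_config("baseline", init_sd=0.1), seed=0)
    w = model.stem_conv.weight.data
    assert np.abs(w).max() <= 0.2 + 1e-6  # resampled outside +/- 2 sd
    assert 0.05 < w.std() < 0.15
    np.testing.assert_array_equal(model.stem_conv.bias.data, 0.0)


def test_small_grid_rejected():
    with pytest.raises(ValueError, match=">= 16"):
        ModelConfig(variant="baseline", input_grid=(8, 20, 16))
    model = build_model(_config("baseline"), seed=0)
    with pytest.raises(ValueError, match=">= 16"):
        model(ad.Tensor(np.zeros((1, 1, 8, 8, 8), dtype=np.float32)))


def test_checkpoint_roundtrip(tmp_path, rng):
    from mciagaspp.architecture import load_checkpoint, save_checkpoint

    model = build_model(_config("ag"), seed=2)
    save_checkpoint(model, tmp_path / "ckpt")
    back = load_checkpoint(tmp_path / "ckpt")
    x = rng.normal(size=(1, 1) + GRID).astype(np.float32)
    np.testing.assert_array_equal(model(ad.Tensor(x)).data, back(ad.Tensor(x)).data)
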