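"""Architecture blocks and model assembly: shapes, toggles, decode."""

import numpy as np
import pytest

from kcc import nd
from kcc.anchors import AnchorSet, PAPER_ANCHORS
from kcc.network import (CBS, ELAN, CoordConv, DetectionModel, MPDown, ModelConfig,
                         RepConv, SPPCSPC, build_model, coordinate_channels, decode,
                         load_checkpoint, save_checkpoint)

RNG = np.random.default_rng(11)


def test_coordinate_channels_convention():
    cc = coordinate_channels(4, 6)       # (2, H, W): x ramp then y ramp
    assert cc[0, 0, 0] == -1 and cc[1, 0, 0] == -1
    assert cc[0, -1, -1] == 1 and cc[1, -1, -1] == 1
    assert np.allclose(coordinate_channels(1, 1), 0.0)   # midpoint convention


def test_coordconv_reduces_to_plain_conv_with_zeroed_coord_weights():
    conv = CoordConv(3, 5, kernel=1, rng=RNG)
    x = RNG.normal(size=(2, 3, 6, 6))
    w = conv.conv.weight.data
    w[:, 3:, :, :] = 0.0        # silence the two coordinate channels
    out = conv(nd.Tensor(x)).numpy()
    ref = (x.transpose(0, 2, 3, 1) @ w[:, :3, 0, 0].T + conv.conv.bias.data)
    assert np.allclose(out, ref.transpose(0, 3, 1, 2), atol=1e-10)


def test_cbs_spatial_dims():
    x = nd.Tensor(RNG.normal(size=(1, 3, 16, 16)))
    assert CBS(3, 8, 3, rng=RNG)(x).shape == (1, 8, 16, 16)
    assert CBS(3, 8, 3, stride=2, rng=RNG)(x).shape == (1, 8, 8, 8)


def test_elan_shapes_and_tap_width():
    elan = ELAN(8, 4, 16, coordconv=False, rng=RNG)
    x = nd.Tensor(RNG.normal(size=(1, 8, 12, 12)))
    assert elan(x).shape == (1, 16, 12, 12)
    assert elan.fuse.conv.weight.shape[1] == 4 * elan.hidden
    coord = ELAN(8, 4, 16, coordconv=True, rng=RNG)
    assert coord(x).shape == (1, 16, 12, 12)
    assert coord.branch1.conv.weight.shape[1] == 8 + 2   # coordinate channels


def test_mp_downsample_shapes_and_odd_error():
    mp = MPDown(6, 12, rng=RNG)
    x = nd.Tensor(RNG.normal(size=(1, 6, 64, 64)))
    assert mp(x).shape == (1, 12, 32, 32)
    with pytest.raises(ValueError):
        mp(nd.Tensor(RNG.normal(size=(1, 6, 7, 8))))


def test_maxpool_branch_commutes_with_channel_permutation():
    from kcc.nd import functional as F
    x = RNG.normal(size=(1, 5, 8, 8))
    perm = RNG.permutation(5)
    a = F.max_pool2d(nd.Tensor(x[:, perm]), 2, 2).numpy()
    b = F.max_pool2d(nd.Tensor(x), 2, 2).numpy()[:, perm]
    assert np.allclose(a, b)


def test_sppcspc_and_repconv_preserve_shape():
    x = nd.Tensor(RNG.normal(size=(1, 8, 16, 16)))
    assert SPPCSPC(8, 8, rng=RNG)(x).shape == (1, 8, 16, 16)
    assert RepConv(8, 8, rng=RNG)(x).shape == (1, 8, 16, 16)


def test_repconv_zero_convs_identity_bn_is_identity():
    rep = RepConv(4, 4, rng=RNG)
    rep.conv3.weight.data[:] = 0
    rep.conv1.weight.data[:] = 0
    rep.eval()      # BN with fresh running stats (mean 0, var 1) is affine-identity
    x = RNG.normal(size=(1, 4, 5, 5))
    out = rep(nd.Tensor(x)).numpy()
    assert np.allclose(out, x, atol=1e-4)


def test_sppcspc_pooling_branches_are_live():
    spp = SPPCSPC(8, 8, rng=RNG)
    x = nd.Tensor(RNG.normal(size=(1, 8, 16, 16)))
    base = spp(x).numpy()
    saved = spp.pool_sizes
    spp.pool_sizes = (5, 9, 1)    # degrade the 13-pool branch
    assert not np.allclose(spp(x).numpy(), base)
    spp.pool_sizes = saved


def tiny_cfg(**kw):
    kw.setdefault("width_scale", 0.125)
    kw.setdefault("input_size", 64)
    kw.setdefault("init_seed", 0)
    return ModelConfig(**kw)


def test_grid_shapes_for_full_input_resolution():
    model = build_model(tiny_cfg(input_size=640))
    model.eval()
    with nd.no_grad():
        grids = model(RNG.random((1, 3, 640, 640)))
    assert [g.shape[2:4] for g in grids] == [(80, 80), (40, 40), (20, 20)]
    assert all(g.shape[1] == 3 and g.shape[4] == 10 for g in grids)


@pytest.mark.parametrize("kmeans,coord,cbam", [
    (False, False, False), (True, False, False), (False, True, False),
    (False, False, True), (True, False, True), (False, True, True),
    (True, True, True)])
def test_all_ablation_variants_build_and_run(kmeans, coord, cbam):
    cfg = tiny_cfg(use_kmeans_anchors=kmeans, use_coordconv=coord, use_cbam=cbam)
    model = build_model(cfg)
    model.eval()
    with nd.no_grad():
        grids = model(RNG.random((1, 3, 64, 64)))
    assert [g.shape[2] for g in grids] == [8, 4, 2]
    from kcc.network import DEFAULT_ANCHORS
    expected = PAPER_ANCHORS if kmeans else DEFAULT_ANCHORS
    assert cfg.effective_anchors.anchors == AnchorSet(expected).anchors


def test_flags_toggle_structure():
    base = build_model(tiny_cfg(use_coordconv=False, use_cbam=False))
    full = build_model(tiny_cfg(use_coordconv=True, use_cbam=True))
    n_base = sum(p.size for p in base.parameters())
    n_full = sum(p.size for p in full.parameters())
    assert n_full > n_base   # coordinate channels + attention add parameters
    assert base.elan1.branch1.conv.weight.shape[1] == base.elan1.branch1.conv.weight.shape[1]


def test_gradient_reaches_every_parameter_group():
    model = build_model(tiny_cfg())
    x = RNG.random((2, 3, 64, 64))
    out = model(x)
    loss = sum((g * RNG.normal(size=g.shape)).sum() for g in out)
    model.zero_grad()
    loss.backward()
    missing = [n for n, p in model.named_parameters()
               if p.grad is None or not np.any(p.grad)]
    assert missing == []


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(input_size=100)
    with pytest.raises(ValueError):
        ModelConfig(num_classes=0)
    with pytest.raises(ValueError):
        ModelConfig(anchors=AnchorSet(((10, 10), (20, 20), (30, 30))))


def test_decode_empty_and_single_cell():
    anchors = AnchorSet(PAPER_ANCHORS)
    nc = 5
    grids = [np.full((1, 3, s, s, 5 + nc), -20.0) for s in (8, 4, 2)]
    assert decode(grids, anchors, conf_threshold=0.5) == []
    # one confident cell: stride 8 (first grid for a 64-px model), anchor 0
    grids[0][0, 0, 3, 5, :] = [0.0, 0.0, 0.0, 0.0, 10.0, 10.0, -10, -10, -10, -10]
    dets = decode(grids, anchors, conf_threshold=0.5,
                  class_names=["a", "b", "c", "d", "e"])
    assert len(dets) == 1
    d = dets[0]
    assert d.label == "a"
    # center = (sigmoid(0)*2-0.5 + cell)*stride = cell*stride + 4
    assert (d.box.xmin + d.box.xmax) / 2 == pytest.approx(5 * 8 + 4)
    assert (d.box.ymin + d.box.ymax) / 2 == pytest.approx(3 * 8 + 4)
    assert d.box.width == pytest.approx(60.0)    # (sigmoid(0)*2)^2 * anchor w
    # score = sigmoid(obj) * softmax-max; the class logit gap saturates softmax
    assert d.score == pytest.approx(1 / (1 + np.exp(-10.0)), rel=1e-6)
    sig = decode(grids, anchors, conf_threshold=0.5,
                 class_names=["a", "b", "c", "d", "e"], cls_activation="sigmoid")
    assert sig[0].score == pytest.approx(1 / (1 + np.exp(-10.0)) ** 2, rel=1e-6)


def test_decode_boxes_bounded_by_parameterization():
    anchors = AnchorSet(PAPER_ANCHORS)
    rng = np.random.default_rng(0)
    grids = [rng.normal(scale=4, size=(1, 3, s, s, 10)) for s in (20, 10, 5)]
    for d in decode(grids, anchors, conf_threshold=0.0):
        assert d.box.width <= 4 * 210 + 1e-6
        assert (d.box.xmin + d.box.xmax) / 2 >= -0.5 * 32


def test_checkpoint_roundtrip(tmp_path):
    model = build_model(tiny_cfg())
    x = RNG.random((1, 3, 64, 64))
    model.eval()
    with nd.no_grad():
        ref = [g.numpy().copy() for g in model(x)]
    path = save_checkpoint(model, tmp_path / "m.ckpt.npz")
    assert path.with_suffix(path.suffix + ".json").exists()
    back = load_checkpoint(path)
    back.eval()
    with nd.no_grad():
        out = [g.numpy() for g in back(x)]
    for a, b in zip(ref, out):
        np.testing.assert_allclose(a, b, rtol=1e-12)
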