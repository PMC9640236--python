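"""Architecture contracts: shapes, branch independence, attention behavior,
decoder wiring, gradient flow."""

import numpy as np
import pytest

from mmanet import (MMANet, NetConfig, build_encoders, build_label_pyramid,
                    encode_branches, head_sides, make_half_resolution,
                    total_loss)
from mmanet.autodiff import Tensor
from mmanet.mma import (AttentionFeatureSelection, AttentionGate,
                        FeatureFusion, MMADecoder)

RNG = np.random.default_rng(99)


def _slim(side=64, branches=2):
    return NetConfig(input_side=side, num_classes=3, width_multiplier=0.125,
                     num_branches=branches)


def _images(side, batch=1):
    full = RNG.uniform(size=(batch, 1, side, side)).astype(np.float32)
    half = make_half_resolution(full).astype(np.float32)
    return full, half


def test_config_validation_lists_violations():
    with pytest.raises(ValueError, match="divisible by 32"):
        NetConfig(input_side=100).validate()
    with pytest.raises(ValueError, match="num_branches"):
        NetConfig(num_branches=3).validate()
    with pytest.raises(ValueError, match="stage_channels"):
        NetConfig(stage_channels=(8, 8)).validate()


def test_width_multiplier_scales_stage_channels():
    assert _slim().channels == (8, 16, 32, 64, 64)
    assert NetConfig().channels == (64, 128, 256, 512, 512)


def test_encoder_stage_sides_dual_branch():
    cfg = _slim(64)
    model = MMANet(cfg, seed=0)
    full, half = _images(64)
    bf = model.encode(Tensor(full), Tensor(half))
    assert [bf.m[i].shape[-1] for i in range(1, 6)] == [64, 32, 16, 8, 4]
    assert [bf.n[j].shape[-1] for j in range(2, 7)] == [32, 16, 8, 4, 2]
    # aligned-index pairs share spatial side
    for i in range(2, 6):
        assert bf.m[i].shape[-2:] == bf.n[i].shape[-2:]


def test_single_branch_has_no_n_features_and_four_heads():
    cfg = _slim(64, branches=1)
    model = MMANet(cfg, seed=0)
    full, _ = _images(64)
    bf = model.encode(Tensor(full), None)
    assert bf.n is None
    pyr = model(full)
    assert len(pyr.heads) == 4
    assert pyr.sides == [64, 32, 16, 8]


def test_branches_share_no_parameters():
    enc1, enc2 = build_encoders(_slim(), seed=0)
    ids1 = {id(p) for p in enc1.parameters()}
    ids2 = {id(p) for p in enc2.parameters()}
    assert not ids1 & ids2
    # and their initial draws differ (independent streams)
    p1 = next(iter(enc1.parameters())).data
    p2 = next(iter(enc2.parameters())).data
    assert not np.array_equal(p1, p2)


def test_encode_rejects_mismatched_half_image():
    model = MMANet(_slim(64), seed=0)
    full, _ = _images(64)
    with pytest.raises(ValueError, match="half"):
        model.encode(Tensor(full), Tensor(full))


@pytest.mark.parametrize("side", [64, 96])
def test_seven_heads_at_contract_sides(side):
    cfg = _slim(side)
    model = MMANet(cfg, seed=0)
    pyr = model(*_images(side))
    assert len(pyr.heads) == 7
    s = side
    assert pyr.sides == [s, s // 2, s // 4, s // 8, s // 2, s // 4, s // 8]
    assert head_sides(cfg) == pyr.sides
    for h in pyr.heads:
        assert h.q.shape[1] == 3
        assert h.q.data.min() >= 0.0 and h.q.data.max() <= 1.0
    # all attention coefficients in [0, 1]
    maps = model.attention_maps()
    assert maps, "no attention maps recorded"
    for alpha in maps.values():
        assert alpha.min() >= 0.0 and alpha.max() <= 1.0


def test_attention_gate_forced_coefficients():
    rng = np.random.default_rng(0)
    ag = AttentionGate(4, 4, 2, rng)
    g = Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
    x = Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
    ones = np.ones((1, 1, 6, 6), dtype=np.float32)
    np.testing.assert_allclose(ag(g, x, alpha_override=ones).data, x.data)
    np.testing.assert_allclose(ag(g, x, alpha_override=0 * ones).data, 0.0)
    # monotone suppression: |output| at a location shrinks as alpha shrinks
    norms = [np.abs(ag(g, x, alpha_override=c * ones).data).sum()
             for c in (1.0, 0.5, 0.1, 0.0)]
    assert norms == sorted(norms, reverse=True)
    # real coefficients are sigmoid outputs
    ag(g, x)
    assert ag.last_alpha.min() >= 0.0 and ag.last_alpha.max() <= 1.0


def test_attention_gate_spatial_mismatch_rejected():
    rng = np.random.default_rng(0)
    ag = AttentionGate(2, 2, 2, rng)
    with pytest.raises(ValueError, match="spatial"):
        ag(Tensor(np.zeros((1, 2, 4, 4))), Tensor(np.zeros((1, 2, 8, 8))))


def test_attention_feature_selection_passthrough_hook():
    """alpha forced to 1 reduces A to concat-then-projection of its inputs."""
    rng = np.random.default_rng(1)
    afs = AttentionFeatureSelection(4, 4, rng)
    comp = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
    enc = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
    ones = np.ones((1, 1, 8, 8), dtype=np.float32)
    out = afs(comp, enc, alpha_override=ones)
    expected = afs.fuse([comp, enc])
    np.testing.assert_allclose(out.data, expected.data, rtol=1e-5)
    assert out.shape == (1, 4, 8, 8)
    afs(comp, enc)
    assert afs.last_alpha.min() >= 0.0 and afs.last_alpha.max() <= 1.0


@pytest.mark.parametrize("side", [28, 56])
def test_afs_output_side_matches_input_side(side):
    rng = np.random.default_rng(2)
    afs = AttentionFeatureSelection(2, 2, rng)
    comp = Tensor(np.zeros((1, 2, side, side), dtype=np.float32))
    enc = Tensor(np.zeros((1, 2, side, side), dtype=np.float32))
    assert afs(comp, enc).shape[-2:] == (side, side)


def test_feature_fusion_channel_contract():
    rng = np.random.default_rng(3)
    for n_inputs in (2, 3):
        fuse = FeatureFusion(8, n_inputs, rng)
        feats = [Tensor(rng.normal(size=(1, 8, 14, 14)).astype(np.float32))
                 for _ in range(n_inputs)]
        out = fuse(feats)
        assert out.shape == (1, 8, 14, 14)
    with pytest.raises(ValueError, match="channel"):
        fuse = FeatureFusion(8, 2, rng)
        fuse([Tensor(np.zeros((1, 8, 4, 4))), Tensor(np.zeros((1, 4, 4, 4)))])


def test_bottleneck_complementary_shared_between_branches(monkeypatch):
    """Up(B) feeds both branch-4 stages, and C_i is shared at stages 3, 2."""
    model = MMANet(_slim(64), seed=0)
    seen = {}
    original = AttentionFeatureSelection.forward

    def recorder(self, comp, enc, alpha_override=None):
        seen[id(self)] = comp
        return original(self, comp, enc, alpha_override)

    monkeypatch.setattr(AttentionFeatureSelection, "forward", recorder)
    model(*_images(64))
    dec = model.decoder
    assert seen[id(dec.a_m4)] is seen[id(dec.a_n4)]
    assert seen[id(dec.a_m3)] is seen[id(dec.a_n3)]
    assert seen[id(dec.a_m2)] is seen[id(dec.a_n2)]


def test_decoder_missing_stage_feature_named_in_error():
    model = MMANet(_slim(64), seed=0)
    full, half = _images(64)
    bf = model.encode(Tensor(full), Tensor(half))
    del bf.m[3]
    with pytest.raises(ValueError, match=r"M_E\[3\]"):
        model.decode(bf)


def test_every_parameter_gets_gradient_from_seven_head_loss():
    cfg = _slim(64)
    model = MMANet(cfg, seed=0)
    full, half = _images(64, batch=2)
    masks = RNG.integers(0, 4, size=(2, 64, 64))
    pyr = model(full, half)
    labels = build_label_pyramid(masks, 3, pyr.sides)
    loss = total_loss(pyr, labels)
    loss.backward()
    dead = [name for name, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad)]
    assert not dead, f"parameters without gradient: {dead}"


def test_forward_deterministic_given_seed():
    full, half = _images(64)
    a = MMANet(_slim(64), seed=5)(full, half)
    b = MMANet(_slim(64), seed=5)(full, half)
    for ha, hb in zip(a.heads, b.heads):
        np.testing.assert_array_equal(ha.q.data, hb.q.data)
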