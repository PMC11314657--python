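"""Architecture contracts: widths, attention arithmetic, parameter budget.

Hand-evaluated oracles: the frequency/spatial attention on tiny
hand-set weights, a single-step scalar LSTM, and a closed-form per-layer
parameter count computed independently of the builder.
"""

from dataclasses import replace

import numpy as np
import pytest

from catm import nn
from catm.model import CATM, CSAM, DCM, FSAM, FTM, ConfigError, ModelConfig, build, count_params, load_weights, save_weights

RNG = np.random.default_rng(7)


def _zero_params(module: nn.Module) -> None:
    for p in module.parameters():
        p.data[...] = 0.0


# ------------------------------------------------------------------- CSAM

def test_csam_default_concat_width_464():
    cfg = ModelConfig()
    block = CSAM(cfg, np.random.default_rng(0))
    x = nn.Tensor(RNG.standard_normal((2, 80, 8, 9)))
    out = block(x)
    assert out.shape == (2, 464, 8, 9)


def test_csam_width_arithmetic_toy():
    cfg = replace(ModelConfig(), stem_width=4, branch_width=8, attention_reduction=4)
    assert cfg.concat_width == 3 * 8 + 4 == 28
    block = CSAM(cfg, np.random.default_rng(0))
    out = block(nn.Tensor(RNG.standard_normal((3, 4, 8, 9))))
    assert out.shape == (3, 28, 8, 9)


def test_csam_rejects_wrong_input_width():
    block = CSAM(ModelConfig(), np.random.default_rng(0))
    with pytest.raises(ConfigError):
        block(nn.Tensor(np.zeros((1, 16, 8, 9))))


# ------------------------------------------------------------------- FSAM

def test_fsam_zero_weights_halve_each_stage():
    fsam = FSAM(4, 2, 3, np.random.default_rng(0))
    _zero_params(fsam)
    x = nn.Tensor(RNG.standard_normal((2, 4, 8, 9)))
    fw = fsam.frequency_weights(x)
    np.testing.assert_allclose(fw.data, 0.5)
    out = fsam(x)
    np.testing.assert_allclose(out.data, x.data / 4.0, atol=1e-6)


def test_fsam_frequency_invariant_to_spatial_permutation():
    fsam = FSAM(4, 2, 3, np.random.default_rng(1))
    x = RNG.standard_normal((2, 4, 8, 9))
    perm = np.random.default_rng(2).permutation(72)
    xp = x.reshape(2, 4, 72)[:, :, perm].reshape(2, 4, 8, 9)
    w1 = fsam.frequency_weights(nn.Tensor(x)).data
    w2 = fsam.frequency_weights(nn.Tensor(xp)).data
    np.testing.assert_allclose(w1, w2, atol=1e-6)


def test_fsam_frequency_matches_hand_arithmetic():
    """C=2, r=1 with hand-set weights vs an independent numpy evaluation
    of pool -> fc1 -> relu -> fc2 -> +b -> sigmoid."""
    fsam = FSAM(2, 1, 3, np.random.default_rng(0))
    w1 = np.array([[0.5, -1.0], [0.25, 0.75]])
    b1 = np.array([0.1, -0.2])
    w2 = np.array([[1.5, 0.0], [-0.5, 2.0]])
    b2 = np.array([0.3, 0.05])
    b_extra = np.array([-0.4, 0.2])
    fsam.fc1.weight.data[...] = w1
    fsam.fc1.bias.data[...] = b1
    fsam.fc2.weight.data[...] = w2
    fsam.fc2.bias.data[...] = b2
    fsam.bias.data[...] = b_extra
    x = RNG.standard_normal((3, 2, 4, 5))
    pooled = x.mean(axis=(2, 3))
    hidden = np.maximum(pooled @ w1 + b1, 0.0)
    expected = 1.0 / (1.0 + np.exp(-(hidden @ w2 + b2 + b_extra)))
    got = fsam.frequency_weights(nn.Tensor(x)).data
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_fsam_spatial_matches_hand_convolution():
    fsam = FSAM(2, 1, 3, np.random.default_rng(0))
    kernel = np.array([[0.0, 0.5, 0.0], [0.5, -1.0, 0.5], [0.0, 0.5, 0.0]])
    fsam.conv.weight.data[0, 0] = kernel
    fsam.conv.bias.data[...] = 0.25
    x = RNG.standard_normal((1, 2, 4, 5))
    mx = x.max(axis=1)  # (1, 4, 5)
    padded = np.pad(mx[0], 1)
    conv = np.zeros((4, 5))
    for i in range(4):
        for j in range(5):
            conv[i, j] = np.sum(padded[i : i + 3, j : j + 3] * kernel) + 0.25
    expected = 1.0 / (1.0 + np.exp(-np.maximum(conv, 0.0)))
    got = fsam.spatial_weights(nn.Tensor(x)).data[0, 0]
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_fsam_weights_lie_in_unit_interval():
    fsam = FSAM(8, 4, 3, np.random.default_rng(3))
    x = nn.Tensor(RNG.standard_normal((2, 8, 8, 9)) * 5)
    fsam(x)
    assert np.all((fsam.last_frequency > 0) & (fsam.last_frequency < 1))
    assert np.all((fsam.last_spatial > 0) & (fsam.last_spatial < 1))


# -------------------------------------------------------------------- FTM

def test_ftm_reduces_464_to_80_preserving_grid():
    ftm = FTM(464, 80, np.random.default_rng(0))
    out = ftm(nn.Tensor(RNG.standard_normal((2, 464, 8, 9))))
    assert out.shape == (2, 80, 8, 9)
    with pytest.raises(ConfigError):
        ftm(nn.Tensor(np.zeros((1, 128, 8, 9))))


def test_maxpool_constant_map_is_constant():
    pool = nn.MaxPool2dSame(3)
    out = pool(nn.Tensor(np.full((1, 2, 8, 9), 3.25)))
    np.testing.assert_allclose(out.data, 3.25)


# ----------------------------------------------------------------- Bi-LSTM

def test_bilstm_zero_weights_zero_output():
    lstm = nn.BiLSTM(3, 5, np.random.default_rng(0))
    _zero_params(lstm)
    xs = [nn.Tensor(RNG.standard_normal((2, 3))) for _ in range(4)]
    np.testing.assert_allclose(lstm(xs).data, 0.0)
    assert lstm(xs).shape == (2, 10)


def test_bilstm_single_step_scalar_hand_evaluation():
    """One timestep, one unit: gate-by-gate arithmetic done by hand."""
    lstm = nn.BiLSTM(1, 1, np.random.default_rng(0))
    for d in (lstm.fwd, lstm.bwd):
        d.w_ih.data[...] = np.array([[0.5, -0.3, 0.8, 1.1]])
        d.w_hh.data[...] = 0.0
        d.b_ih.data[...] = np.array([0.1, 0.2, -0.1, 0.0])
        d.b_hh.data[...] = 0.0
    x = 0.7

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    i = sig(0.5 * x + 0.1)
    f = sig(-0.3 * x + 0.2)
    g = np.tanh(0.8 * x - 0.1)
    o = sig(1.1 * x)
    h = o * np.tanh(i * g)  # c_prev = 0 so f drops out
    out = lstm([nn.Tensor(np.array([[x]]))])
    np.testing.assert_allclose(out.data, [[h, h]], atol=1e-6)


def test_bilstm_rejects_empty_sequence():
    lstm = nn.BiLSTM(2, 2, np.random.default_rng(0))
    with pytest.raises(ValueError):
        lstm([])


# -------------------------------------------------------------------- DCM

def test_dcm_widths_and_zero_weights():
    for n_classes in (2, 4):
        head = DCM((128, 64, 32), n_classes, 0.5, np.random.default_rng(0))
        head.eval()
        out = head(nn.Tensor(RNG.standard_normal((3, 128))))
        assert out.shape == (3, n_classes)
    _zero_params(head)
    np.testing.assert_allclose(head(nn.Tensor(np.ones((2, 128)))).data, 0.0)


def test_dcm_eval_forward_deterministic():
    head = DCM((128, 64, 32), 2, 0.5, np.random.default_rng(0))
    head.eval()
    v = nn.Tensor(RNG.standard_normal((4, 128)))
    np.testing.assert_array_equal(head(v).data, head(v).data)


# ------------------------------------------------------------ full network

def _closed_form_count(cfg: ModelConfig) -> int:
    """Independent per-layer parameter arithmetic from the config alone."""
    s, br, cat = cfg.stem_width, cfg.branch_width, cfg.concat_width
    rows, cols = cfg.grid

    def conv(ci, co, k):
        return ci * co * k * k + co

    def lin(ci, co):
        return ci * co + co

    def bn(c):
        return 2 * c

    total = conv(cfg.in_planes, s, 1)  # stem
    if cfg.use_csam:
        if cfg.single_scale is not None:
            per_block = conv(s, br, cfg.single_scale) + bn(br)
        else:
            per_block = (
                conv(s, br, 1) + conv(s, br, 3) + conv(s, br, 5) + 3 * bn(br) + bn(s)
            )
        per_block += bn(cat) + conv(cat, s, 1)  # FTM
        if cfg.use_fsam:
            c_mid = cat // cfg.attention_reduction
            per_block += (
                lin(cat, c_mid) + lin(c_mid, cat) + cat  # MLP + standalone bias
                + conv(1, 1, cfg.spatial_kernel)
            )
        total += cfg.n_blocks * per_block
    flat = s * rows * cols
    if cfg.use_bilstm:
        h = cfg.lstm_hidden
        total += lin(flat, cfg.proj_dim)
        total += 2 * (4 * h * cfg.proj_dim + 4 * h * h + 8 * h)
        total += lin(2 * h, cfg.classifier_widths[0])
    else:
        total += lin(flat, cfg.classifier_widths[0])
    if cfg.use_dcm:
        w0, w1, w2 = cfg.classifier_widths
        total += lin(w0, w1) + lin(w1, w2) + lin(w2, cfg.n_classes)
    else:
        total += lin(cfg.classifier_widths[0], cfg.n_classes)
    return total


def test_default_model_hits_published_parameter_budget():
    model = build()
    assert count_params(model) == 9478504
    assert _closed_form_count(ModelConfig()) == 9478504


@pytest.mark.parametrize(
    "cfg",
    [
        ModelConfig.toy(),
        replace(ModelConfig.toy(), single_scale=3),
        replace(ModelConfig.toy(), use_fsam=False),
        replace(ModelConfig.toy(), use_bilstm=False),
        replace(ModelConfig(), n_classes=4),
    ],
)
def test_count_params_matches_closed_form(cfg):
    assert count_params(build(cfg)) == _closed_form_count(cfg)


def test_ablations_build_and_are_smaller():
    full = count_params(build())
    for kw in ({"use_csam": False}, {"use_bilstm": False}, {"use_dcm": False},
               {"single_scale": 1}, {"single_scale": 3}, {"single_scale": 5}):
        assert count_params(build(replace(ModelConfig(), **kw))) < full


def test_toy_forward_shapes_and_finite_logits():
    cfg = ModelConfig.toy()
    model = build(cfg)
    model.eval()
    x = RNG.standard_normal((3, cfg.seq_len, cfg.in_planes, 8, 9))
    out = model(x)
    assert out.shape == (3, 2)
    assert np.all(np.isfinite(out.data))


def test_forward_rejects_wrong_seq_len_and_planes():
    model = build(ModelConfig.toy())
    with pytest.raises(ConfigError):
        model(np.zeros((1, 3, 16, 8, 9)))
    with pytest.raises(ConfigError):
        model(np.zeros((1, 6, 4, 8, 9)))


def test_removing_fsam_equals_fixing_multipliers_to_one():
    """Saturating every attention gate at 1 must reproduce the forward
    pass of the same network with the attention modules detached — the
    structural content of the no-FSAM ablation."""
    cfg = replace(ModelConfig.toy(), dropout=0.0)
    model = build(cfg, seed=5)
    model.eval()
    for block in model.blocks:
        if isinstance(block, CSAM) and block.attention is not None:
            att = block.attention
            for p in (att.fc1.weight, att.fc1.bias, att.fc2.weight, att.conv.weight):
                p.data[...] = 0.0
            att.fc2.bias.data[...] = 500.0  # sigmoid saturates to 1
            att.bias.data[...] = 0.0
            att.conv.bias.data[...] = 500.0
    x = RNG.standard_normal((2, cfg.seq_len, cfg.in_planes, 8, 9))
    out_gated = model(x).data.copy()
    for w in model.attention_weights():
        np.testing.assert_allclose(w["frequency"], 1.0, atol=1e-6)
        np.testing.assert_allclose(w["spatial"], 1.0, atol=1e-6)
    for block in model.blocks:
        if isinstance(block, CSAM):
            block.attention = None
    np.testing.assert_allclose(model(x).data, out_gated, atol=1e-5)


def test_one_training_step_decreases_loss():
    cfg = replace(ModelConfig.toy(), dropout=0.0)
    model = build(cfg, seed=2)
    x = RNG.standard_normal((16, cfg.seq_len, cfg.in_planes, 8, 9))
    y = np.array([0, 1] * 8)
    opt = nn.Adam(model.parameters(), lr=1e-3)
    model.train()
    loss0 = nn.softmax_cross_entropy(model(x), y)
    loss0.backward()
    opt.step()
    loss1 = nn.softmax_cross_entropy(model(x), y)
    assert float(loss1.data) < float(loss0.data)


def test_weight_save_load_round_trip(tmp_path):
    cfg = ModelConfig.toy()
    a = build(cfg, seed=1)
    b = build(cfg, seed=9)
    x = RNG.standard_normal((2, cfg.seq_len, cfg.in_planes, 8, 9))
    a.eval()
    b.eval()
    assert not np.allclose(a(x).data, b(x).data)
    save_weights(a, tmp_path / "w.npz")
    load_weights(b, tmp_path / "w.npz")
    np.testing.assert_array_equal(a(x).data, b(x).data)
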