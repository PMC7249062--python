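"""Layer-module calculus: output lengths, parameter counts, ROI, forward contract."""

import numpy as np
import pytest

from filternet import (
    FLM,
    FLMConfig,
    ROI_ENTIRE_INPUT,
    apply_flm,
    exact_receptive_field,
    flm_output_length,
    flm_param_count,
    roi_after_stack,
)


# ---------------------------------------------------------------------------
# output length
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "L_in, s, expected",
    [(512, 2, 256), (100, 1, 100), (513, 2, 257), (7, 4, 2), (1, 3, 1)],
)
def test_output_length_is_ceil_of_ratio(L_in, s, expected):
    assert flm_output_length(L_in, s) == expected


def test_output_length_matches_actual_pooled_output():
    # ceil convention verified against a real forward pass on length 513
    cfg = FLMConfig("cnn", 3, s=2, k=5, p_drop=0.0)
    x = np.random.default_rng(0).normal(size=(2, 513))
    y = apply_flm(x, cfg)
    assert y.shape == (3, 257) == (cfg.w_out, flm_output_length(513, 2))


@pytest.mark.parametrize("bad", [(0, 1), (5, 0), (-3, 2)])
def test_output_length_rejects_nonpositive_arguments(bad):
    with pytest.raises(ValueError):
        flm_output_length(*bad)


# ---------------------------------------------------------------------------
# parameter counts
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cfg, w_in, expected",
    [
        (FLMConfig("cnn", 100, k=5), 113, 56_700),
        (FLMConfig("cnn", 100, k=1), 195, 19_700),
        (FLMConfig("cnn", 18, k=1, use_bn=False, use_bias=True), 100, 1_818),
        (FLMConfig("cnn", 1, k=1, use_bn=False, use_bias=True), 1, 2),
        (FLMConfig("cnn", 100, s=2, k=5), 100, 50_200),
        (FLMConfig("cnn", 50, s=2, k=5), 100, 25_100),
        (FLMConfig("cnn", 25, s=2, k=5), 50, 6_300),
        (FLMConfig("cnn", 13, s=2, k=5), 25, 1_651),
        (FLMConfig("cnn", 7, s=1, k=5), 13, 469),
    ],
)
def test_cnn_param_count_formula(cfg, w_in, expected):
    assert flm_param_count(cfg, w_in) == expected


@pytest.mark.parametrize(
    "cfg, w_in",
    [
        (FLMConfig("cnn", 10, s=2, k=5), 7),
        (FLMConfig("cnn", 4, k=3, use_bn=False, use_bias=True), 5),
        (FLMConfig("cnn", 3, k=1, use_bn=True), 2),
        (FLMConfig("lstm", 8), 5),
        (FLMConfig("lstm", 100), 100),
    ],
)
def test_param_count_equals_enumerated_trainables(cfg, w_in):
    """The analytic count matches the instantiated module's parameter sizes."""
    flm = FLM(cfg, w_in, np.random.default_rng(0))
    assert flm.param_count == flm_param_count(cfg, w_in)


def test_lstm_width_must_be_even():
    with pytest.raises(ValueError):
        FLMConfig("lstm", 7)


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "stack, expected",
    [
        ([(1, 5)], 5),
        ([(1, 5), (2, 5)], 13),
        ([(1, 5), (2, 5), (2, 5)], 29),
        ([(1, 5), (2, 5), (2, 5), (2, 5)], 61),
        ([(1, 5), (2, 5), (2, 5), (2, 5), (2, 5)], 125),
        ([(1, 5), (2, 5), (2, 5), (2, 5), (2, 5), (2, 5), (2, 5), (1, 5)], 765),
        ([(1, 1)], 1),
    ],
)
def test_roi_recurrence(stack, expected):
    assert roi_after_stack(stack) == expected


def test_roi_of_lstm_stack_is_entire_input():
    stack = [FLMConfig("cnn", 4, s=2), FLMConfig("lstm", 4)]
    assert roi_after_stack(stack) == ROI_ENTIRE_INPUT


def test_roi_rejects_empty_stack():
    with pytest.raises(ValueError):
        roi_after_stack([])


def _probe_receptive_field(stack_cfgs, w_in=2, seed=0):
    """Empirical receptive field by single-sample perturbation.

    Weights are made strictly positive and the probe input strictly positive
    so every ReLU path is alive and no cancellation can hide an influence.
    Returns (max influencing inputs per output, per-output influence sets).
    """
    rng = np.random.default_rng(seed)
    flms = []
    w = w_in
    for cfg in stack_cfgs:
        flm = FLM(cfg, w, rng)
        flm.core.weight.value[...] = np.abs(flm.core.weight.value) + 0.05
        flms.append(flm)
        w = cfg.w_out

    def fwd(x):
        h = x[None]
        for f in flms:
            h = f.forward(h, train=False)
        return h[0]

    rf = exact_receptive_field([(c.s, c.k) for c in stack_cfgs])
    L = int(max(4 * rf, 64))
    sr = int(np.prod([c.s for c in stack_cfgs]))
    L = -(-L // sr) * sr
    x = rng.uniform(0.5, 1.5, size=(w_in, L))
    y0 = fwd(x)
    counts = np.zeros(y0.shape[1], dtype=int)
    for m in range(L):
        xp = x.copy()
        xp[:, m] += 1.0
        changed = np.flatnonzero(np.any(np.abs(fwd(xp) - y0) > 1e-9, axis=0))
        counts[changed] += 1
    return counts.max()


@pytest.mark.parametrize(
    "stack",
    [
        [FLMConfig("cnn", 3, s=1, k=5, p_drop=0.0, use_bn=False, use_bias=True)],
        [
            FLMConfig("cnn", 3, s=1, k=5, p_drop=0.0, use_bn=False, use_bias=True),
            FLMConfig("cnn", 3, s=1, k=3, p_drop=0.0, use_bn=False, use_bias=True),
        ],
        [
            FLMConfig("cnn", 2, s=1, k=5, p_drop=0.0, use_bn=False, use_bias=True),
            FLMConfig("cnn", 2, s=1, k=5, p_drop=0.0, use_bn=False, use_bias=True),
            FLMConfig("cnn", 2, s=1, k=3, p_drop=0.0, use_bn=False, use_bias=True),
            FLMConfig("cnn", 2, s=1, k=1, p_drop=0.0, use_bn=False, use_bias=True),
        ],
    ],
)
def test_empirical_rf_equals_roi_for_unstrided_stacks(stack):
    """For stride-1 stacks the ROI recurrence is the exact receptive field."""
    tuples = [(c.s, c.k) for c in stack]
    assert roi_after_stack(tuples) == exact_receptive_field(tuples)
    assert _probe_receptive_field(stack) == roi_after_stack(tuples)


@pytest.mark.parametrize(
    "stack",
    [
        [FLMConfig("cnn", 2, s=2, k=5, p_drop=0.0, use_bn=False, use_bias=True)],
        [
            FLMConfig("cnn", 2, s=1, k=5, p_drop=0.0, use_bn=False, use_bias=True),
            FLMConfig("cnn", 2, s=2, k=5, p_drop=0.0, use_bn=False, use_bias=True),
        ],
        [
            FLMConfig("cnn", 2, s=2, k=5, p_drop=0.0, use_bn=False, use_bias=True),
            FLMConfig("cnn", 2, s=2, k=3, p_drop=0.0, use_bn=False, use_bias=True),
            FLMConfig("cnn", 2, s=2, k=5, p_drop=0.0, use_bn=False, use_bias=True),
        ],
    ],
)
def test_empirical_rf_matches_exact_formula_and_is_bounded_by_roi(stack):
    """Strided stacks: the probe matches the exact pre-image composition and
    never exceeds the reported ROI metric (which is an upper bound there)."""
    tuples = [(c.s, c.k) for c in stack]
    probed = _probe_receptive_field(stack)
    assert probed == exact_receptive_field(tuples)
    assert probed <= roi_after_stack(tuples)


# ---------------------------------------------------------------------------
# forward contract
# ---------------------------------------------------------------------------


def test_identity_configuration_passes_input_through():
    # k=1 conv with identity weights, no bn/dropout/pool; non-negative input
    cfg = FLMConfig("cnn", 2, s=1, k=1, p_drop=0.0, use_bn=False, use_bias=True)
    flm = FLM(cfg, 2, np.random.default_rng(0))
    flm.core.weight.value[...] = np.eye(2)[:, :, None]
    flm.core.bias.value[...] = 0.0
    x = np.abs(np.random.default_rng(1).normal(size=(2, 20)))
    y = apply_flm(x, cfg, flm=flm)
    np.testing.assert_allclose(y, x)


def test_shape_contract_full_width_layer():
    cfg = FLMConfig("cnn", 100, s=2, k=5)
    x = np.random.default_rng(0).normal(size=(113, 512))
    assert apply_flm(x, cfg).shape == (100, 256)


def test_average_pooling_of_ramp():
    # identity conv then mean over stride-2 bins: 0,1,...,7 -> 0.5, 2.5, 4.5, 6.5
    cfg = FLMConfig("cnn", 1, s=2, k=1, p_drop=0.0, use_bn=False, use_bias=True)
    flm = FLM(cfg, 1, np.random.default_rng(0))
    flm.core.weight.value[...] = 1.0
    flm.core.bias.value[...] = 0.0
    y = apply_flm(np.arange(8.0)[None], cfg, flm=flm)
    np.testing.assert_allclose(y[0], [0.5, 2.5, 4.5, 6.5])


def test_lstm_flm_output_shape_and_even_split():
    cfg = FLMConfig("lstm", 6, p_drop=0.0)
    x = np.random.default_rng(0).normal(size=(3, 16))
    assert apply_flm(x, cfg).shape == (6, 16)


def test_eval_mode_is_deterministic_and_train_dropout_is_not_identity():
    cfg = FLMConfig("cnn", 4, s=2, k=3, p_drop=0.5)
    flm = FLM(cfg, 3, np.random.default_rng(0))
    x = np.random.default_rng(1).normal(size=(1, 3, 32))
    y1 = flm.forward(x, train=False)
    y2 = flm.forward(x, train=False)
    np.testing.assert_array_equal(y1, y2)  # bit-identical eval passes
    yt = flm.forward(x, train=True, rng=np.random.default_rng(2))
    assert not np.allclose(yt, y1)


def test_non_finite_input_is_rejected():
    cfg = FLMConfig("cnn", 2, s=1, k=3)
    x = np.zeros((2, 10))
    x[0, 3] = np.nan
    with pytest.raises(ValueError, match="finite"):
        apply_flm(x, cfg)


def test_coverage_preservation_via_index_bookkeeping():
    """Output sample j covers input [j*s, (j+1)*s); the union is the input span."""
    for L, s in [(96, 2), (128, 4), (60, 3)]:
        n_out = flm_output_length(L, s)
        spans = [(j * s, (j + 1) * s) for j in range(n_out)]
        assert spans[0][0] == 0
        assert spans[-1][1] >= L  # right edge reaches (or pads past) the input end
        assert all(a2 == b1 for (_, b1), (a2, _) in zip(spans, spans[1:]))


# ---------------------------------------------------------------------------
# config validation / serialization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(layer_type="cnn", w_out=0),
        dict(layer_type="cnn", w_out=4, s=0),
        dict(layer_type="cnn", w_out=4, k=4),
        dict(layer_type="cnn", w_out=4, p_drop=1.0),
        dict(layer_type="gru", w_out=4),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        FLMConfig(**kwargs)


def test_config_round_trips_through_plain_mapping():
    cfg = FLMConfig("cnn", 25, s=2, k=5, p_drop=0.2, use_bn=True)
    assert FLMConfig.from_dict(cfg.to_dict()) == cfg
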