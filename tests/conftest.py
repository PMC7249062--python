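"""Shared fixtures: small synthetic datasets and (session-cached) trained models."""

from __future__ import annotations

import numpy as np
import pytest

import filternet as fn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def synth3():
    """Preprocessed 3-class synthetic series split into train/val/test."""
    cfg = fn.SynthConfig(n_classes=3, n_channels=8, n_samples=40_000, seed=11)
    series, _ = fn.preprocess(fn.generate(cfg))
    tr, va, te = fn.split_series(series, (0.6, 0.2, 0.2))
    return tr, va, te


@pytest.fixture(scope="session")
def recovery_fit(synth3):
    """A tiny multi-scale CNN fitted to the 3-class synthetic data.

    Session-scoped: the parameter-recovery experiment is the suite's one
    genuinely expensive computation and several tests inspect it.
    """
    tr, va, te = synth3
    tcfg = fn.TrainConfig(max_epochs=20, patience=20)
    model = fn.FilterNet(tr, va, variant="ms_cnn", width_scale=0.25, train_config=tcfg)
    res = model.fit(seed=1)
    return res, res.evaluate(te)


@pytest.fixture(scope="session")
def shuffled_control_fit(synth3):
    """Same architecture trained on label-shuffled data (negative control)."""
    tr, va, te = synth3
    rs = np.random.default_rng(0)
    tr_sh = fn.LabeledSeries(tr.data, rs.permutation(tr.labels), tr.sampling_rate)
    va_sh = fn.LabeledSeries(va.data, rs.permutation(va.labels), va.sampling_rate)
    tcfg = fn.TrainConfig(max_epochs=8, patience=20)
    model = fn.FilterNet(tr_sh, va_sh, variant="ms_cnn", width_scale=0.25, train_config=tcfg)
    res = model.fit(seed=1)
    return res, res.evaluate(te)


@pytest.fixture(scope="session")
def ensemble_fit(synth3):
    """3-fold contiguous ensemble of the tiny multi-scale CNN."""
    tr, va, te = synth3
    tcfg = fn.TrainConfig(max_epochs=8, patience=20)
    model = fn.FilterNet(tr, va, variant="ms_cnn", width_scale=0.25, train_config=tcfg)
    ens = model.fit_ensemble(n_folds=3, seed=5)
    return ens, te
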