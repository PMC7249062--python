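"""Model/Results surface: build a FilterNet from data, fit it, inspect results.

``FilterNet`` is the model object: it holds the training and validation
series, the architecture specification (one of the five reference variants,
optionally width-scaled) and the training configuration.  ``fit`` runs the
training loop and returns a :class:`FilterNetResults` carrying the trained
network, the per-epoch history and evaluation helpers; ``fit_ensemble``
trains an n-fold contiguous ensemble on the pooled train+validation data.

Example
-------
>>> from filternet import FilterNet, SynthConfig, generate, split_series
>>> series = generate(SynthConfig(n_classes=3, seed=7))
>>> tr, va, te = split_series(series)
>>> res = FilterNet(tr, va, variant="ms_cnn", width_scale=0.25).fit(seed=7)
>>> scores = res.evaluate(te)
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architectures import ArchitectureSpec, Network, NetworkOutput, build_reference, total_param_count
from .data import LabeledSeries, preprocess
from .ensembling import EnsembleResult, ensemble_logits, predict_ensemble, train_ensemble
from .inference import predict_windowed
from .layers import ROI_ENTIRE_INPUT
from .metrics import extract_events, labels_to_events, sample_f1_scores, ward_categorize
from .training import TrainConfig, TrainHistory, labels_at_output_rate, train

__all__ = ["FilterNet", "FilterNetResults", "FilterNetEnsembleResults"]


class FilterNet:
    """A dense time-series classifier specified by variant and data.

    Parameters
    ----------
    train_data, val_data : LabeledSeries
        Preprocessed (interpolated, standardized) series.
    variant : str
        One of ``b_lstm, p_cnn, p_cl, ms_cnn, ms_cl``.
    width_scale : float
        Scales every layer width (0.5 and 2.0 give the half/double-size
        reference variants).
    n_classes : int, optional
        Inferred from the labels when omitted.
    train_config : TrainConfig, optional
    """

    def __init__(
        self,
        train_data: LabeledSeries,
        val_data: LabeledSeries,
        variant: str = "ms_cnn",
        width_scale: float = 1.0,
        n_classes: int | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.train_data = train_data
        self.val_data = val_data
        if n_classes is None:
            n_classes = int(max(train_data.labels.max(), val_data.labels.max())) + 1
        self.spec = build_reference(
            variant, train_data.n_channels, n_classes, width_scale=width_scale
        )
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        val_fraction: float = 0.2,
        sampling_rate: float = 30.0,
        standardize: bool = True,
        **kwargs,
    ) -> "FilterNet":
        """Build from a samples-by-channels frame with a label column.

        The trailing ``val_fraction`` of rows becomes the validation split;
        channels are standardized with training-split statistics.
        """
        labels = df[label_col].to_numpy(dtype=np.int64)
        data = df.drop(columns=[label_col]).to_numpy(dtype=np.float64).T
        series = LabeledSeries(data, labels, sampling_rate)
        cut = int(round(series.n_samples * (1.0 - val_fraction)))
        tr, va = series.slice(0, cut), series.slice(cut, series.n_samples)
        if standardize:
            tr, stats = preprocess(tr)
            va, _ = preprocess(va, stats)
        return cls(tr, va, **kwargs)

    def fit(self, seed: int = 0, log=None) -> "FilterNetResults":
        net, history = train(
            self.spec, self.train_data, self.val_data, self.train_config, seed=seed, log=log
        )
        return FilterNetResults(self, net, history)

    def fit_ensemble(self, n_folds: int, seed: int = 0, log=None) -> "FilterNetEnsembleResults":
        combined = LabeledSeries.concatenate([self.train_data, self.val_data])
        result = train_ensemble(
            self.spec, combined, n_folds, self.train_config, seed=seed, log=log
        )
        return FilterNetEnsembleResults(self, result)


class _ResultsBase:
    """Evaluation shared by single-model and ensemble results."""

    spec: ArchitectureSpec

    def predict(self, series, **window_kwargs) -> NetworkOutput:
        raise NotImplementedError

    def evaluate(self, series: LabeledSeries, **window_kwargs) -> dict:
        """Sample F1 summaries plus event-based scores on a labeled series."""
        out = self.predict(series, **window_kwargs)
        sr = self.spec.output_stride_ratio
        y_true = labels_at_output_rate(series.labels, sr)
        y_pred = out.probabilities.argmax(axis=0)[: len(y_true)]
        f1 = sample_f1_scores(y_true, y_pred[: len(y_true)])
        card = ward_categorize(
            labels_to_events(y_true), extract_events(out.probabilities[:, : len(y_true)])
        )
        return {
            "f1m": f1.f1m,
            "f1w": f1.f1w,
            "f1w_nn": f1.f1w_nn,
            "precision_e": card.precision_e,
            "recall_e": card.recall_e,
            "f1e": card.f1_e,
            "event_card": card,
        }


@dataclass
class FilterNetResults(_ResultsBase):
    """A fitted FilterNet: trained weights, history, and diagnostics."""

    model: FilterNet
    network: Network
    history: TrainHistory

    @property
    def spec(self) -> ArchitectureSpec:
        return self.network.spec

    def predict(self, series, **window_kwargs) -> NetworkOutput:
        x = series.data if isinstance(series, LabeledSeries) else np.asarray(series)
        return predict_windowed(self.network, x, **window_kwargs)

    def save(self, path) -> None:
        self.network.save(path)

    def summary(self) -> str:
        """Architecture/fit summary in a statsmodels-like text table."""
        spec = self.spec
        buf = io.StringIO()
        w = buf.write
        w("FilterNet Results\n")
        w("=" * 78 + "\n")
        w(f"Variant:            {spec.variant_name}\n")
        w(f"Input channels:     {spec.input_channels}\n")
        w(f"Classes:            {spec.n_classes}\n")
        w(f"Output stride:      {spec.output_stride_ratio}:1\n")
        roi = spec.roi
        w(f"ROI:                {'entire input' if roi == ROI_ENTIRE_INPUT else int(roi)} samples\n")
        w(f"Trainable params:   {self.network.total_param_count():,}\n")
        w("-" * 78 + "\n")
        w(f"{'comp':<5}{'type':<6}{'w_in':>6}{'w_out':>7}{'s':>4}{'k':>4}"
          f"{'params':>10}{'stride':>8}{'roi':>8}\n")
        for row in spec.layer_table():
            roi_s = "all" if row["roi"] == ROI_ENTIRE_INPUT else str(int(row["roi"]))
            k_s = "-" if row["k"] is None else str(row["k"])
            w(f"{row['component']:<5}{row['type']:<6}{row['w_in']:>6}{row['w_out']:>7}"
              f"{row['s']:>4}{k_s:>4}{row['params']:>10,}{row['stride_ratio']:>8}{roi_s:>8}\n")
        w("-" * 78 + "\n")
        h = self.history
        if h.n_epochs:
            w(f"Epochs trained:     {h.n_epochs}\n")
            w(f"Best epoch:         {h.best_epoch}\n")
            w(f"Val loss (best):    {h.val_loss[h.best_epoch - 1]:.4f}\n")
            w(f"Val F1w (best):     {h.val_f1w[h.best_epoch - 1]:.4f}\n")
            w(f"Checkpoint metric:  {h.metric[h.best_epoch - 1]:.4f}\n")
        return buf.getvalue()

    def plot_history(self, ax=None):
        """Validation loss, weighted F1, and the checkpoint metric per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        h = self.history
        epochs = range(1, h.n_epochs + 1)
        ax.plot(epochs, h.val_loss, label="val loss")
        ax.plot(epochs, h.val_f1w, label="val F1w")
        ax.plot(epochs, h.metric, label="checkpoint metric")
        for e in h.checkpoint_epochs:
            ax.axvline(e, color="0.85", zorder=0)
        ax.axvline(h.best_epoch, color="tab:red", ls="--", label="restored epoch")
        ax.set_xlabel("epoch")
        ax.legend(fontsize=8)
        return ax


@dataclass
class FilterNetEnsembleResults(_ResultsBase):
    """An n-fold ensemble: sub-models, fold plan, logit-mean prediction."""

    model: FilterNet
    result: EnsembleResult

    @property
    def spec(self) -> ArchitectureSpec:
        return self.result.networks[0].spec

    @property
    def networks(self) -> list[Network]:
        return self.result.networks

    def predict(self, series, **window_kwargs) -> NetworkOutput:
        x = series.data if isinstance(series, LabeledSeries) else np.asarray(series)
        return predict_ensemble(self.result, x, **window_kwargs)

    def save(self, path) -> None:
        self.result.save(path)

    def summary(self) -> str:
        lines = [
            "FilterNet Ensemble Results",
            "=" * 78,
            f"Variant:          {self.spec.variant_name}",
            f"Folds:            {self.result.fold_plan.n_folds}",
            f"Params (total):   {sum(n.total_param_count() for n in self.networks):,}",
        ]
        for i, (a, b) in enumerate(self.result.fold_plan.folds):
            h = self.result.histories[i] if i < len(self.result.histories) else None
            tail = f"  best epoch {h.best_epoch}" if h and h.n_epochs else ""
            lines.append(f"  fold {i}: val [{a}, {b}){tail}")
        return "\n".join(lines) + "\n"
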