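"""Sample- and event-based evaluation for dense activity predictions.

Sample-based scores are the usual per-class precision/recall/F1 summaries:

- ``F1m``: unweighted mean F1 over the non-null classes;
- ``F1w``: support-weighted F1 over *all* classes (null included), weights
  proportional to each class's share of the ground-truth samples;
- ``F1w_nn``: support-weighted F1 over the non-null classes only.

Event-based scores first segment the dense output into events (maximal runs
where a non-null class probability exceeds 0.5) and then categorize actual
vs detected events by their overlap structure, following Ward's taxonomy:
actual events are Correct (C), Deleted (D), Fragmented (F), Merged (M) or
Fragmented-and-Merged (FM); detected events are Correct (C'), Insertions
(I'), Fragmenting (F'), Merging (M') or both (FM').  True positives are the
correct events, false negatives the incorrect actual events, false positives
the incorrect detected events, and

    F1e = 2*TP / (2*TP + FP + FN)

summed over classes.  Events count once each regardless of duration, so long
events have the same influence as short events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "SampleF1",
    "EventScoreCard",
    "sample_f1_scores",
    "extract_events",
    "labels_to_events",
    "ward_categorize",
    "f1e",
]

ACTUAL_CATEGORIES = ("C", "D", "F", "M", "FM")
DETECTED_CATEGORIES = ("C'", "I'", "F'", "M'", "FM'")


class Event(NamedTuple):
    """A (class, start, end) half-open interval on the output-sample axis."""

    class_id: int
    start: int
    end: int


class SampleF1(NamedTuple):
    f1m: float
    f1w: float
    f1w_nn: float


def sample_f1_scores(y_true, y_pred, null_class: int = 0) -> SampleF1:
    """Per-sample F1 summaries (F1m, F1w, F1w_nn).

    Per-class F1 comes from per-class precision and recall on the confusion
    counts.  A class absent from both truth and prediction has F1 defined as
    0 and is excluded from the F1m average; if no non-null class is present
    at all, F1m (and F1w_nn) are 0 by convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    classes = np.union1d(np.unique(y_true), np.unique(y_pred))
    f1 = {}
    support = {}
    for c in classes:
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        f1[c] = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        support[c] = np.sum(y_true == c)
    nn = [c for c in classes if c != null_class and (support[c] > 0 or np.any(y_pred == c))]
    f1m = float(np.mean([f1[c] for c in nn])) if nn else 0.0
    total = sum(support.values())
    f1w = float(sum(f1[c] * support[c] for c in classes) / total) if total else 0.0
    nn_total = sum(support[c] for c in classes if c != null_class)
    f1w_nn = (
        float(sum(f1[c] * support[c] for c in classes if c != null_class) / nn_total)
        if nn_total
        else 0.0
    )
    return SampleF1(f1m, f1w, f1w_nn)


def extract_events(
    prob_series: np.ndarray, threshold: float = 0.5, null_class: int = 0
) -> list[Event]:
    """Threshold per-class probabilities and enumerate contiguous regions.

    ``prob_series`` is (n_classes, L).  For every non-null class, maximal
    runs where p > threshold (strictly) become events.  Events are returned
    sorted by (class, start).
    """
    prob_series = np.asarray(prob_series)
    if prob_series.ndim != 2:
        raise ValueError(f"expected (n_classes, length), got shape {prob_series.shape}")
    events: list[Event] = []
    for c in range(prob_series.shape[0]):
        if c == null_class:
            continue
        above = prob_series[c] > threshold
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        events.extend(Event(c, int(a), int(b)) for a, b in zip(run_starts, run_ends))
    events.sort(key=lambda e: (e.class_id, e.start))
    return events


def labels_to_events(labels, null_class: int = 0) -> list[Event]:
    """Ground-truth events: maximal runs of each non-null label."""
    labels = np.asarray(labels)
    events: list[Event] = []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    edges = np.concatenate([[0], boundaries, [len(labels)]])
    for a, b in zip(edges[:-1], edges[1:]):
        c = int(labels[a])
        if c != null_class:
            events.append(Event(c, int(a), int(b)))
    events.sort(key=lambda e: (e.class_id, e.start))
    return events


def _overlaps(a: Event, b: Event) -> bool:
    # half-open intervals: touching events do not overlap
    return a.start < b.end and b.start < a.end


def _check_disjoint(events: Iterable[Event], side: str) -> None:
    by_class: dict[int, list[Event]] = {}
    for e in events:
        if e.end <= e.start:
            raise ValueError(f"{side} event {e} has non-positive duration")
        by_class.setdefault(e.class_id, []).append(e)
    for c, evs in by_class.items():
        evs.sort(key=lambda e: e.start)
        for prev, nxt in zip(evs, evs[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"overlapping {side} events within class {c}: {prev}, {nxt}")


@dataclass
class EventScoreCard:
    """Ward-style event categorization counts and the derived event F1.

    ``actual``/``detected`` map each class to its category counts; the
    totals, TP/FP/FN and precision/recall/F1e aggregate across classes.
    """

    actual: dict[int, dict[str, int]]
    detected: dict[int, dict[str, int]]

    def _total(self, side: str, cat: str) -> int:
        table = self.actual if side == "actual" else self.detected
        return sum(counts.get(cat, 0) for counts in table.values())

    @property
    def tp(self) -> int:
        return self._total("actual", "C")

    @property
    def fn(self) -> int:
        return sum(self._total("actual", c) for c in ("D", "F", "M", "FM"))

    @property
    def fp(self) -> int:
        return sum(self._total("detected", c) for c in ("I'", "F'", "M'", "FM'"))

    @property
    def n_actual(self) -> int:
        return sum(self._total("actual", c) for c in ACTUAL_CATEGORIES)

    @property
    def n_detected(self) -> int:
        return sum(self._total("detected", c) for c in DETECTED_CATEGORIES)

    @property
    def precision_e(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall_e(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def f1_e(self) -> float:
        return f1e(self.tp, self.fp, self.fn)

    def to_frame(self) -> pd.DataFrame:
        """Per-class category counts as a tidy table."""
        rows = []
        for c in sorted(set(self.actual) | set(self.detected)):
            row = {"class": c}
            row.update({cat: self.actual.get(c, {}).get(cat, 0) for cat in ACTUAL_CATEGORIES})
            row.update(
                {cat: self.detected.get(c, {}).get(cat, 0) for cat in DETECTED_CATEGORIES}
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Event-summary bar chart: actual vs detected category totals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        cats = list(ACTUAL_CATEGORIES) + list(DETECTED_CATEGORIES)
        totals = [self._total("actual", c) for c in ACTUAL_CATEGORIES] + [
            self._total("detected", c) for c in DETECTED_CATEGORIES
        ]
        colors = ["tab:blue"] * 5 + ["tab:orange"] * 5
        ax.bar(range(len(cats)), totals, color=colors)
        ax.set_xticks(range(len(cats)), cats)
        ax.set_ylabel("events")
        ax.set_title(f"F1e = {self.f1_e:.3f}  (TP {self.tp}, FP {self.fp}, FN {self.fn})")
        return ax


def ward_categorize(actual: list[Event], detected: list[Event]) -> EventScoreCard:
    """Categorize actual and detected events by their overlap structure.

    Matching is per class; cross-class overlaps never match.  For an actual
    event a with overlapping detections D(a) and a detection d with
    overlapping actuals A(d):

    - a is D (deleted) if |D(a)| = 0; F (fragmented) if |D(a)| > 1, promoted
      to FM if any of its fragments also merges other actuals; M (merged) if
      its single detection spans > 1 actuals; otherwise C (correct).
    - d is I' (insertion) if |A(d)| = 0; M' (merging) if |A(d)| > 1, promoted
      to FM' if it also fragments an actual; F' (fragmenting) if its single
      actual is fragmented; otherwise C' (correct).
    """
    _check_disjoint(actual, "actual")
    _check_disjoint(detected, "detected")
    classes = sorted({e.class_id for e in actual} | {e.class_id for e in detected})
    card = EventScoreCard(actual={}, detected={})
    for c in classes:
        acts = [e for e in actual if e.class_id == c]
        dets = [e for e in detected if e.class_id == c]
        d_of_a = [[j for j, d in enumerate(dets) if _overlaps(a, d)] for a in acts]
        a_of_d = [[i for i, a in enumerate(acts) if _overlaps(a, d)] for d in dets]
        a_counts = dict.fromkeys(ACTUAL_CATEGORIES, 0)
        d_counts = dict.fromkeys(DETECTED_CATEGORIES, 0)
        for i, _a in enumerate(acts):
            ds = d_of_a[i]
            if not ds:
                a_counts["D"] += 1
            elif len(ds) > 1:
                if any(len(a_of_d[j]) > 1 for j in ds):
                    a_counts["FM"] += 1
                else:
                    a_counts["F"] += 1
            elif len(a_of_d[ds[0]]) > 1:
                a_counts["M"] += 1
            else:
                a_counts["C"] += 1
        for j, _d in enumerate(dets):
            asq = a_of_d[j]
            if not asq:
                d_counts["I'"] += 1
            elif len(asq) > 1:
                if any(len(d_of_a[i]) > 1 for i in asq):
                    d_counts["FM'"] += 1
                else:
                    d_counts["M'"] += 1
            elif len(d_of_a[asq[0]]) > 1:
                d_counts["F'"] += 1
            else:
                d_counts["C'"] += 1
        card.actual[c] = a_counts
        card.detected[c] = d_counts
    return card


def f1e(tp: int, fp: int, fn: int) -> float:
    """Event F1 = 2*TP / (2*TP + FP + FN); 0 when there is nothing to score."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0
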