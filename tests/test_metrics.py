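"""Sample F1 conventions, event extraction, Ward categorization, event F1."""

import numpy as np
import pytest

from filternet import (
    Event,
    extract_events,
    f1e,
    labels_to_events,
    sample_f1_scores,
    ward_categorize,
)


# ---------------------------------------------------------------------------
# sample-based F1
# ---------------------------------------------------------------------------


def test_perfect_prediction_scores_one():
    y = np.array([0, 0, 1, 2, 1, 0])
    assert sample_f1_scores(y, y) == (1.0, 1.0, 1.0)


def test_hand_computed_confusion_example():
    f1 = sample_f1_scores([0, 0, 1, 1], [0, 0, 1, 0], null_class=0)
    assert f1.f1m == pytest.approx(2 / 3)
    assert f1.f1w == pytest.approx(0.5 * 0.8 + 0.5 * (2 / 3))
    assert f1.f1w_nn == pytest.approx(2 / 3)


def test_all_null_degenerate_case():
    f1 = sample_f1_scores([0, 0, 0], [0, 0, 0])
    assert f1.f1w == 1.0
    assert f1.f1m == 0.0  # no non-null class to average over


def test_sample_f1_agrees_with_sklearn_on_random_labels():
    """Independent cross-check against sklearn's weighted/macro averaging
    when every class is present (where conventions coincide)."""
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(0)
    y_true = rng.integers(0, 4, size=500)
    y_pred = rng.integers(0, 4, size=500)
    got = sample_f1_scores(y_true, y_pred, null_class=0)
    f1w_ref = sklearn_metrics.f1_score(y_true, y_pred, average="weighted")
    f1m_ref = sklearn_metrics.f1_score(
        y_true, y_pred, labels=[1, 2, 3], average="macro"
    )
    assert got.f1w == pytest.approx(f1w_ref, abs=1e-12)
    assert got.f1m == pytest.approx(f1m_ref, abs=1e-12)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        sample_f1_scores([0, 1], [0, 1, 2])


# ---------------------------------------------------------------------------
# event extraction
# ---------------------------------------------------------------------------


def test_thresholding_enumerates_contiguous_regions():
    p = np.array([[0.8, 0.2, 0.1, 0.7], [0.2, 0.8, 0.9, 0.3]])
    assert extract_events(p) == [Event(1, 1, 3)]


def test_all_below_threshold_yields_no_events():
    p = np.vstack([np.full(10, 0.6), np.full(10, 0.4)])
    assert extract_events(p) == []


def test_all_above_threshold_yields_one_spanning_event():
    p = np.vstack([np.full(10, 0.2), np.full(10, 0.8)])
    assert extract_events(p) == [Event(1, 0, 10)]


def test_exactly_half_probability_is_not_an_event():
    p = np.vstack([np.full(4, 0.5), np.full(4, 0.5)])
    assert extract_events(p) == []


def test_one_hot_labels_round_trip_through_extraction():
    rng = np.random.default_rng(2)
    labels = np.zeros(200, dtype=int)
    for _ in range(12):
        a = rng.integers(0, 190)
        labels[a : a + rng.integers(2, 9)] = rng.integers(1, 4)
    onehot = np.eye(4)[labels].T
    assert extract_events(onehot) == labels_to_events(labels)


# ---------------------------------------------------------------------------
# Ward categorization
# ---------------------------------------------------------------------------


def test_one_to_one_overlap_is_correct_event():
    card = ward_categorize([Event(1, 0, 10)], [Event(1, 2, 8)])
    assert card.actual[1]["C"] == 1
    assert card.tp == 1 and card.fp == 0 and card.fn == 0
    assert card.f1_e == 1.0


def test_fragmented_actual_event():
    card = ward_categorize([Event(1, 0, 10)], [Event(1, 0, 4), Event(1, 6, 10)])
    assert card.actual[1]["F"] == 1
    assert card.detected[1]["F'"] == 2
    assert (card.tp, card.fn, card.fp) == (0, 1, 2)


def test_merged_actual_events():
    card = ward_categorize(
        [Event(1, 0, 4), Event(1, 6, 10)], [Event(1, 0, 10)]
    )
    assert card.actual[1]["M"] == 2
    assert card.detected[1]["M'"] == 1


def test_deleted_and_inserted_events():
    card = ward_categorize([Event(1, 0, 4)], [Event(1, 20, 24)])
    assert card.actual[1]["D"] == 1
    assert card.detected[1]["I'"] == 1


def test_touching_half_open_intervals_do_not_overlap():
    card = ward_categorize([Event(1, 0, 5)], [Event(1, 5, 9)])
    assert card.actual[1]["D"] == 1
    assert card.detected[1]["I'"] == 1


def test_cross_class_overlaps_never_match():
    card = ward_categorize([Event(1, 0, 10)], [Event(2, 0, 10)])
    assert card.actual[1]["D"] == 1
    assert card.detected[2]["I'"] == 1


def test_overlapping_events_within_one_class_rejected():
    with pytest.raises(ValueError, match="overlapping"):
        ward_categorize([Event(1, 0, 5), Event(1, 3, 8)], [])


def _random_disjoint_events(rng, n_classes=3, n=12, horizon=300):
    events = []
    for c in range(1, n_classes + 1):
        cuts = np.sort(rng.choice(horizon, size=2 * n, replace=False))
        for a, b in zip(cuts[::2], cuts[1::2]):
            if b > a and rng.random() < 0.7:
                events.append(Event(c, int(a), int(b)))
    return events


def _brute_force_counts(actual, detected):
    """Independent matcher: set-theoretic category assignment per event."""
    from collections import Counter

    a_cats, d_cats = Counter(), Counter()
    for a in actual:
        ds = [d for d in detected if d.class_id == a.class_id
              and a.start < d.end and d.start < a.end]
        if not ds:
            a_cats["D"] += 1
        elif len(ds) == 1:
            other = [x for x in actual if x is not a and x.class_id == a.class_id
                     and x.start < ds[0].end and ds[0].start < x.end]
            a_cats["M" if other else "C"] += 1
        else:
            merging = any(
                [x for x in actual if x is not a and x.class_id == a.class_id
                 and x.start < d.end and d.start < x.end]
                for d in ds
            )
            a_cats["FM" if merging else "F"] += 1
    for d in detected:
        asq = [a for a in actual if a.class_id == d.class_id
               and a.start < d.end and d.start < a.end]
        if not asq:
            d_cats["I'"] += 1
        elif len(asq) == 1:
            other = [x for x in detected if x is not d and x.class_id == d.class_id
                     and x.start < asq[0].end and asq[0].start < x.end]
            d_cats["F'" if other else "C'"] += 1
        else:
            fragmenting = any(
                [x for x in detected if x is not d and x.class_id == d.class_id
                 and x.start < a.end and a.start < x.end]
                for a in asq
            )
            d_cats["FM'" if fragmenting else "M'"] += 1
    return a_cats, d_cats


@pytest.mark.parametrize("seed", range(8))
def test_categorization_matches_brute_force_and_conserves_counts(seed):
    rng = np.random.default_rng(seed)
    actual = _random_disjoint_events(rng)
    detected = _random_disjoint_events(rng)
    card = ward_categorize(actual, detected)
    # conservation: categories partition each side, and C = C'
    assert card.n_actual == len(actual)
    assert card.n_detected == len(detected)
    assert card.tp == card._total("detected", "C'")
    a_ref, d_ref = _brute_force_counts(actual, detected)
    got_a = {
        k: card._total("actual", k) for k in ("C", "D", "F", "M", "FM")
    }
    got_d = {
        k: card._total("detected", k) for k in ("C'", "I'", "F'", "M'", "FM'")
    }
    assert got_a == {k: a_ref.get(k, 0) for k in got_a}
    assert got_d == {k: d_ref.get(k, 0) for k in got_d}


def test_event_scores_are_not_length_weighted():
    """Doubling every event's duration leaves the score card unchanged."""
    rng = np.random.default_rng(3)
    actual = _random_disjoint_events(rng)
    detected = _random_disjoint_events(rng)
    card1 = ward_categorize(actual, detected)
    stretch = lambda evs: [Event(e.class_id, 2 * e.start, 2 * e.end) for e in evs]
    card2 = ward_categorize(stretch(actual), stretch(detected))
    assert card1.actual == card2.actual
    assert card1.detected == card2.detected


# ---------------------------------------------------------------------------
# event F1
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "tp, fp, fn, expected",
    [
        (1, 0, 0, 1.0),
        (0, 5, 3, 0.0),
        (0, 0, 0, 0.0),
        (117, 448, 87, 2 * 117 / (2 * 117 + 448 + 87)),
    ],
)
def test_f1e_formula(tp, fp, fn, expected):
    assert f1e(tp, fp, fn) == pytest.approx(expected)


def test_f1e_is_harmonic_mean_of_precision_and_recall():
    rng = np.random.default_rng(0)
    for _ in range(50):
        tp, fp, fn = rng.integers(1, 100, size=3)
        p = tp / (tp + fp)
        r = tp / (tp + fn)
        assert f1e(tp, fp, fn) == pytest.approx(2 * p * r / (p + r))


def test_published_event_counts_give_f1e_of_0p304():
    # 117 of 204 events detected correctly with 448 spurious/fragmented detections
    assert f1e(117, 448, 204 - 117) == pytest.approx(0.304, abs=5e-4)


def test_f1e_rejects_negative_counts():
    with pytest.raises(ValueError):
        f1e(-1, 0, 0)
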