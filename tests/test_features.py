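"""Feature extraction, filtering and selection against closed-form oracles."""

import dataclasses

import numpy as np
import pytest

from fvepnet import features as ft
from fvepnet.records import FvepRecord
from fvepnet.synth import WaveformParams, generate_dataset


def _rec(signal, age=40, label="normal", pid="p0"):
    return FvepRecord(
        signal=np.asarray(signal, dtype=float),
        patient_id=pid,
        eye="left",
        repeat_index=1,
        age=age,
        label=label,
    )


def test_constant_signal_statistics():
    table = ft.extract_features([_rec(np.full(320, 5.0))])
    assert table.column("max")[0] == 5.0
    assert table.column("min")[0] == 5.0
    assert table.column("peak_to_peak")[0] == 0.0
    assert table.column("std")[0] == 0.0
    assert np.all(np.isfinite(table.values))


def test_unit_spike_peak_to_peak():
    x = np.zeros(320)
    x[100] = 1.0
    table = ft.extract_features([_rec(x)])
    assert table.column("max")[0] == 1.0
    assert table.column("min")[0] == 0.0
    assert table.column("peak_to_peak")[0] == 1.0


def test_ramp_median():
    table = ft.extract_features([_rec(np.arange(320, dtype=float))])
    assert table.column("median")[0] == 159.5


def test_wrong_length_named_error():
    rec = _rec(np.zeros(320))
    bad = dataclasses.replace(rec)
    object.__setattr__(bad, "signal", np.zeros(100))
    with pytest.raises(ft.FeatureError, match="p0"):
        ft.extract_features([bad])


def test_extraction_row_order_follows_input(small_dataset):
    sub = small_dataset[:8]
    t1 = ft.extract_features(sub)
    t2 = ft.extract_features(sub[::-1])
    np.testing.assert_allclose(t1.values, t2.values[::-1])


# ---------------------------------------------------------------- selection


def _table(cols: dict) -> ft.FeatureTable:
    names = list(cols)
    return ft.FeatureTable(
        np.column_stack([cols[n] for n in names]).astype(float),
        names,
        {n: "statistical" for n in names},
    )


def test_variance_filter_drops_constant_column():
    t = _table({"const": [1, 1, 1, 1], "var": [1, 2, 3, 4]})
    out = ft.variance_filter(t)
    assert out.feature_names == ["var"]


def test_variance_filter_identity_without_constants():
    t = _table({"a": [1, 2, 3, 4], "b": [0, 1, 0, 1]})
    out = ft.variance_filter(t, 0.0)
    np.testing.assert_array_equal(out.values, t.values)


def test_variance_filter_threshold():
    t = _table({"zero": [2, 2, 2, 2], "four": [0, 4, 0, 4]})
    out = ft.variance_filter(t, threshold=1.0)
    assert out.feature_names == ["four"]


def test_variance_filter_idempotent(small_dataset):
    t = ft.extract_features(small_dataset[:40])
    once = ft.variance_filter(t, 0.0)
    twice = ft.variance_filter(once, 0.0)
    assert once.feature_names == twice.feature_names
    np.testing.assert_array_equal(once.values, twice.values)


def test_variance_filter_degenerate_error():
    with pytest.raises(ft.FeatureError, match="degenerate"):
        ft.variance_filter(_table({"c": [1, 1, 1]}))


def test_pearson_exact_example():
    t = _table({"x": [1, 2, 3, 4]})
    r = ft.pearson_correlations(t, [0, 0, 1, 1])
    assert r[0] == pytest.approx(2.0 / np.sqrt(5.0), abs=1e-12)


def test_pearson_self_and_anti_correlation():
    labels = np.array([0, 1, 0, 1, 1, 0])
    t = _table({"same": labels, "anti": 1 - labels})
    r = ft.pearson_correlations(t, labels)
    assert r[0] == pytest.approx(1.0)
    assert r[1] == pytest.approx(-1.0)
    out = ft.pearson_select(t, labels, min_abs_r=0.9)
    assert out.feature_names == ["same", "anti"]


def test_pearson_zero_variance_column_scores_zero():
    t = _table({"const": [3, 3, 3, 3]})
    assert ft.pearson_correlations(t, [0, 1, 0, 1])[0] == 0.0


def test_pearson_identical_labels_error():
    with pytest.raises(ft.FeatureError, match="identical"):
        ft.pearson_correlations(_table({"x": [1, 2, 3]}), [1, 1, 1])


def test_pearson_matches_bruteforce(rng):
    """Vectorised Pearson equals the covariance/sigma-sigma formula to 1e-12."""
    labels = rng.integers(0, 2, 60)
    while len(set(labels)) < 2:
        labels = rng.integers(0, 2, 60)
    cols = {f"f{i}": rng.normal(size=60) for i in range(100)}
    t = _table(cols)
    r = ft.pearson_correlations(t, labels)
    y = labels.astype(float)
    for i, name in enumerate(t.feature_names):
        x = t.values[:, i]
        expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r[i] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- manual


def test_manual_features_constant_signal():
    v = ft.manual_features(_rec(np.full(320, 2.5), age=40))
    # ptp, window max, window-start latency (argmax tie -> first), std, median, mad, age
    np.testing.assert_allclose(v, [0.0, 2.5, 100.0, 0.0, 2.5, 0.0, 40.0])


def test_manual_features_rp_pair(zero_noise_pair):
    normal, rp = zero_noise_pair
    vn = ft.manual_features(normal)
    vr = ft.manual_features(rp)
    assert vn[2] == vr[2]  # identical P2 latency
    assert vr[0] < vn[0]  # strictly smaller peak-to-peak
    np.testing.assert_array_equal(ft.manual_features(normal), vn)  # deterministic


def test_peak_to_peak_dominates_label_correlation():
    """Among the six signal-derived manual features, peak-to-peak amplitude
    carries the strongest |Pearson r| with the normal/RP label."""
    recs = generate_dataset({"normal": 30, "rp": 30}, WaveformParams(), rng_seed=5)
    assert len(recs) >= 200
    m = ft.manual_feature_matrix(recs)
    labels = np.array([1 if r.label == "normal" else 0 for r in recs])
    t = ft.FeatureTable(m, list(ft.MANUAL_FEATURE_NAMES), dict.fromkeys(ft.MANUAL_FEATURE_NAMES, "x"))
    r = np.abs(ft.pearson_correlations(t, labels))
    signal_feats = [n for n in ft.MANUAL_FEATURE_NAMES if n != "age"]
    best = signal_feats[int(np.argmax([r[t.feature_names.index(n)] for n in signal_feats]))]
    assert best == "peak_to_peak"
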