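"""Marker-based decoder: modality gate, nearest-centroid rule, leakage
guards, chance-level behavior and noise monotonicity."""

import numpy as np
import pandas as pd
import pytest

from erpmark.classify import evaluate_loso, feature_vectors, fit, predict
from erpmark.features import (
    AUDITORY_CATEGORIES,
    CATEGORIES,
    VISUAL_CATEGORIES,
    extract_feature_table,
    marker_registry,
)
from erpmark.simulate import SimulationConfig, noiseless_evokeds


def _noiseless_table(n_subjects=4, gains=None, registry=None):
    """Feature table from the deterministic ground truth, optionally with a
    per-subject multiplicative gain."""
    registry = registry or marker_registry()
    truth = noiseless_evokeds()
    gains = gains or {s: 1.0 for s in range(n_subjects)}
    base = extract_feature_table({0: truth}, registry)
    frames = []
    for s in range(n_subjects):
        f = base.copy()
        f["subject"] = s
        f["amplitude_uv"] = f["amplitude_uv"] * gains[s]
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def test_fit_centroids_equal_template_features_in_noiseless_limit():
    table = _noiseless_table(3)
    model = fit(table)
    wide = feature_vectors(table)
    for cat in CATEGORIES:
        mod = "visual" if cat in VISUAL_CATEGORIES else "auditory"
        raw = wide.xs(cat, level="category")[model.markers[mod]].iloc[0]
        z = (raw.to_numpy() - model.mean[mod]) / model.scale[mod]
        assert np.allclose(model.centroids[mod][cat], z, atol=1e-9)


def test_fit_invariant_to_subject_order():
    gains = {0: 0.8, 1: 1.0, 2: 1.3}
    table = _noiseless_table(3, gains)
    shuffled = table.sort_values(
        ["marker", "subject"], ascending=False).reset_index(drop=True)
    a, b = fit(table), fit(shuffled)
    for mod in ("visual", "auditory"):
        assert np.allclose(a.mean[mod], b.mean[mod])
        for cat in a.centroids[mod]:
            assert np.allclose(a.centroids[mod][cat],
                               b.centroids[mod][cat])


def test_fit_requires_all_categories():
    table = _noiseless_table(3)
    with pytest.raises(ValueError, match="music"):
        fit(table[table.category != "music"])


def test_standardization_uses_training_statistics_only():
    train = _noiseless_table(3, {0: 1.0, 1: 1.0, 2: 1.0})
    biased = _noiseless_table(2, {0: 10.0, 1: 10.0})
    model_train = fit(train)
    model_all = fit(pd.concat([train, biased.assign(
        subject=biased.subject + 10)], ignore_index=True))
    # adding wildly scaled extra subjects changes the fitted statistics,
    # proving they come from the provided table and nothing else
    assert not np.allclose(model_train.mean["visual"],
                           model_all.mean["visual"])


def test_pn300_gate_routes_by_sign():
    table = _noiseless_table(3)
    model = fit(table)
    wide = feature_vectors(table)
    # a complete 16-marker vector: visual markers from a picture evoked,
    # auditory markers from a sound evoked
    vis = wide.xs("body", level="category").iloc[0]
    aud = wide.xs("music", level="category").iloc[0]
    vec = aud.combine_first(vis)
    vec["PN300"] = 3.0
    _, dists, _ = predict(model, vec)
    assert set(dists.index) == set(AUDITORY_CATEGORIES)
    vec["PN300"] = -3.0
    _, dists2, _ = predict(model, vec)
    assert set(dists2.index) == set(VISUAL_CATEGORIES)


def test_misrouted_single_modality_vector_falls_back_deterministically():
    """A picture evoked whose modality signature is flipped positive gets
    gated to the (featureless) auditory branch: the prediction is the
    branch's first category, logged, and necessarily wrong."""
    table = _noiseless_table(3)
    model = fit(table)
    wide = feature_vectors(table)
    vec = wide.xs("body", level="category").iloc[0].copy()
    vec["PN300"] = +2.0
    pred, dists, log = predict(model, vec)
    assert pred == sorted(AUDITORY_CATEGORIES)[0]
    assert log and log[0][0] == "gate_fallback"


def test_exact_tie_breaks_lexicographically_and_is_logged():
    table = _noiseless_table(3)
    model = fit(table)
    # test point equidistant from two centroids by construction
    mod = "auditory"
    c1 = model.centroids[mod]["music"]
    c2 = model.centroids[mod]["vocalization"]
    mid = (c1 + c2) / 2
    feats = pd.Series(mid * model.scale[mod] + model.mean[mod],
                      index=model.markers[mod])
    feats["PN300"] = abs(feats["PN300"]) + 1.0  # force auditory gate
    # re-zscore shifts PN300 slightly; rebuild midpoint exactly in z-space
    x = (feats[model.markers[mod]].to_numpy() - model.mean[mod]) \
        / model.scale[mod]
    d1 = np.linalg.norm(x - c1)
    d2 = np.linalg.norm(x - c2)
    if not np.isclose(d1, d2):
        # project onto the perpendicular bisector hyperplane
        u = (c2 - c1) / np.linalg.norm(c2 - c1)
        x = x - ((x - (c1 + c2) / 2) @ u) * u
        feats = pd.Series(x * model.scale[mod] + model.mean[mod],
                          index=model.markers[mod])
    pred, dists, ties = predict(model, feats)
    near = dists.nsmallest(2)
    if np.isclose(near.iloc[0], near.iloc[1]):
        assert pred == sorted(near.index[:2])[0]


def test_incomplete_features_raise():
    table = _noiseless_table(3)
    model = fit(table)
    wide = feature_vectors(table)
    full = wide.xs("music", level="category").iloc[0]
    with pytest.raises(ValueError, match="P300_aud"):
        predict(model, full.drop("P300_aud"))
    with pytest.raises(ValueError, match="PN300"):
        predict(model, full.drop("PN300"))


def test_noiseless_loso_is_perfect():
    """Zero-variance limit: every held-out vector coincides with its
    category centroid, so decoding is exact."""
    table = _noiseless_table(5)
    report = evaluate_loso(table)
    assert report.accuracy == 1.0
    assert report.modality_accuracy == 1.0
    assert int(np.trace(report.confusion.to_numpy())) == 50


def test_confusion_rows_sum_to_trial_counts():
    table = _noiseless_table(4)
    report = evaluate_loso(table)
    assert (report.confusion.sum(axis=1) == 4).all()
    assert 0.0 <= report.accuracy <= 1.0


def test_modality_accuracy_at_least_overall(default_cohort):
    report = evaluate_loso(default_cohort["table"])
    assert report.modality_accuracy >= report.accuracy


def test_null_features_decode_at_chance():
    """With fully category-uninformative features (including a sign-random
    PN300 gate), 10-class LOSO accuracy sits at the 10% chance level: the
    gate is right half the time, then 1/7 or 1/3 within the branch."""
    rng = np.random.default_rng(0)
    registry = marker_registry()
    rows = []
    for s in range(20):
        for mk in registry:
            for cat in mk.applicable_categories:
                for el in mk.electrodes:
                    rows.append((s, cat, mk.name, el, "x",
                                 rng.normal(0, 1)))
    table = pd.DataFrame(rows, columns=[
        "subject", "category", "marker", "electrode", "hemisphere",
        "amplitude_uv"])
    report = evaluate_loso(table)
    # E[acc] = 0.7 * 0.5/7 + 0.3 * 0.5/3 = 0.10; 200 predictions
    se = np.sqrt(0.1 * 0.9 / 200)
    assert abs(report.accuracy - 0.10) < 3.5 * se + 0.02


def test_accuracy_degrades_with_noise(montage):
    """Decoding accuracy is monotone non-increasing in background noise
    (with Monte-Carlo slack) across a 3-point noise ladder."""
    from erpmark.pipeline import PipelineConfig, process_subject

    accs = []
    for noise_sd in (2.0, 7.0, 30.0):
        sim = SimulationConfig(n_subjects=5, trials_per_category=8,
                               noise_sd=noise_sd, blink_rate_per_min=0.0,
                               seed=21)
        # rejection disabled: at the top of the ladder the background alone
        # would exceed the 50 uV criterion and empty the categories
        cfg = PipelineConfig(simulation=sim, seed=21, reject_uv=1e6)
        evokeds = {}
        for s in range(sim.n_subjects):
            ev, _, _ = process_subject(cfg, s, montage)
            evokeds[s] = ev
        table = extract_feature_table(evokeds, marker_registry())
        accs.append(evaluate_loso(table).accuracy)
    assert accs[0] >= accs[1] - 0.1
    assert accs[1] >= accs[2] - 0.1
    assert accs[0] >= accs[2]
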