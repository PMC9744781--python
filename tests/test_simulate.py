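"""Synthetic-data generator: paradigm schedule, noise model, templates,
artifacts, determinism, and the additive-model identity."""

import dataclasses

import numpy as np
import pytest
import scipy.signal

from erpmark.features import (
    AUDITORY_CATEGORIES,
    VISUAL_CATEGORIES,
    marker_registry,
    mean_amplitude,
)
from erpmark.preprocess import extract_epochs, ms_to_sample
from erpmark.simulate import (
    SimulationConfig,
    _blink_waveform,
    _subject_rngs,
    default_templates,
    generate_schedule,
    inject_blinks,
    noiseless_evokeds,
    null_templates,
    render_component,
    simulate_subject,
    synthesize_noise,
    validate_template_orderings,
)


# --------------------------------------------------------------------- design

def test_default_config_matches_paradigm():
    cfg = SimulationConfig()
    assert cfg.events_per_subject == 400
    assert len(cfg.visual_categories) == 7
    assert len(cfg.auditory_categories) == 3
    assert cfg.fs == 512.0


def test_schedule_counts_and_runs():
    cfg = SimulationConfig()
    sched = generate_schedule(cfg, np.random.default_rng(0))
    cats = [e.category for e in sched.entries]
    assert len(sched) == 400
    n_visual = sum(c in VISUAL_CATEGORIES for c in cats)
    n_auditory = sum(c in AUDITORY_CATEGORIES for c in cats)
    assert (n_visual, n_auditory) == (280, 120)
    runs = {}
    for e in sched.entries:
        runs.setdefault(e.run, []).append(e.category)
    assert len(runs) == 12
    for r in range(8):
        assert len(runs[r]) == 35  # 5 per visual category
        assert all(c in VISUAL_CATEGORIES for c in runs[r])
    for r in range(8, 12):
        assert len(runs[r]) == 30  # 10 per auditory category
        assert all(c in AUDITORY_CATEGORIES for c in runs[r])


def test_inter_onset_intervals_within_isi_bounds():
    cfg = SimulationConfig()
    sched = generate_schedule(cfg, np.random.default_rng(1))
    onsets = np.array([e.onset for e in sched.entries])
    gaps_ms = np.diff(onsets) / cfg.fs * 1000.0
    assert gaps_ms.min() >= 1900 - 1.0  # sample rounding slack
    assert gaps_ms.max() <= 2100 + 1.0


def test_schedule_deterministic_given_seed():
    cfg = SimulationConfig()
    a = generate_schedule(cfg, np.random.default_rng(7))
    b = generate_schedule(cfg, np.random.default_rng(7))
    assert a.entries == b.entries


# ---------------------------------------------------------------------- noise

def test_zero_noise_is_all_zero():
    cfg = SimulationConfig(noise_sd=0.0, alpha_amplitude=0.0)
    x = synthesize_noise(4, 1000, cfg, np.random.default_rng(0))
    assert not x.any()


def test_noise_sd_matches_configuration():
    cfg = SimulationConfig(noise_sd=7.0, alpha_amplitude=0.0)
    x = synthesize_noise(8, int(512 * 60), cfg, np.random.default_rng(2))
    sds = x.std(axis=1)
    assert np.allclose(sds, 7.0, rtol=0.05)


def test_powerlaw_slope_recovers_exponent():
    """Welch log-periodogram regression over 1-30 Hz recovers the
    configured spectral exponent of the 1/f part within +/-0.3."""
    cfg = SimulationConfig(noise_sd=5.0, white_fraction=0.0,
                           alpha_amplitude=0.0, one_over_f_exponent=1.0)
    x = synthesize_noise(4, int(512 * 400), cfg, np.random.default_rng(3))
    f, p = scipy.signal.welch(x, fs=512.0, nperseg=8192)
    band = (f >= 1.0) & (f <= 30.0)
    slope = np.polyfit(np.log(f[band]), np.log(p[:, band].mean(0)), 1)[0]
    assert -slope == pytest.approx(cfg.one_over_f_exponent, abs=0.3)


# ------------------------------------------------------------------ templates

def test_sixteen_templates_with_expected_anchors(montage):
    templates = {t.name: t for t in default_templates()}
    assert len(templates) == 16
    n170 = templates["N170_left"]
    assert n170.peak_ms == 170
    assert 150 <= n170.peak_ms <= 190
    assert abs(n170.amplitude["adult_face"]) > abs(
        n170.amplitude["animal_face"])
    n80 = templates["N80"]
    assert n80.amplitude["checkerboard"] < n80.amplitude["word_visual"]
    assert n80.amplitude["checkerboard"] < n80.amplitude["object"]
    pn = templates["PN300"]
    assert all(pn.amplitude[c] < 0 for c in VISUAL_CATEGORIES)
    assert all(pn.amplitude[c] > 0 for c in AUDITORY_CATEGORIES)


def test_component_polarities_match_names():
    for t in default_templates():
        amps = np.array(list(t.amplitude.values()))
        if t.name == "PN300":
            continue
        if t.name.startswith(("N", "AN")):
            assert (amps < 0).all(), t.name
        else:
            assert (amps > 0).all(), t.name


def test_render_component_geometry(montage):
    tpl = [t for t in default_templates() if t.name == "N170_left"][0]
    n = 768
    pat = render_component(tpl, "adult_face", montage, 512.0, n,
                           subject_gain=1.3)
    peak_idx = ms_to_sample(tpl.peak_ms, 512.0)
    center = montage.index("P7")
    assert pat[center, peak_idx] == pytest.approx(
        tpl.amplitude["adult_face"] * 1.3, rel=1e-3)
    # beyond 4 temporal sd the Gaussian course is negligible
    far = peak_idx + int(4.5 * tpl.sd_ms / 1000 * 512)
    assert abs(pat[center, far]) < 0.01 * abs(pat[center, peak_idx])
    # absent category renders as silence
    assert not render_component(tpl, "music", montage, 512.0, n).any()


def test_noiseless_orderings_hold():
    """Every registry contrast holds on the noiseless evoked responses,
    cross-talk between overlapping components included."""
    assert validate_template_orderings() == []


def test_null_templates_remove_category_structure():
    reg = [m for m in marker_registry() if m.polarity != "modality"]
    ev = noiseless_evokeds(templates=null_templates())
    for mk in reg:
        pooled = [mean_amplitude(ev[c], mk)[1]
                  for c in mk.analysis_categories]
        assert np.ptp(pooled) < 1e-9, mk.name


# ------------------------------------------------------------------ artifacts

def test_blink_waveform_peak_to_peak_is_unit():
    w = _blink_waveform(512.0)
    assert w.max() - w.min() == pytest.approx(1.0)


def test_zero_blink_rate_leaves_recording_unchanged(montage):
    cfg = SimulationConfig(blink_rate_per_min=0.0)
    rec, _ = simulate_subject(
        dataclasses.replace(cfg, trials_per_category=2), 0, montage)
    out = inject_blinks(rec, cfg, np.random.default_rng(0))
    assert out.data is rec.data


def test_blinks_drive_veog_over_rejection_threshold(montage):
    cfg = SimulationConfig(trials_per_category=4, noise_sd=0.0,
                           alpha_amplitude=0.0, blink_rate_per_min=6.0)
    rec, sched = simulate_subject(cfg, 0, montage)
    epochs = extract_epochs(rec, sched)
    veog_row = montage.all_channels.index("VEOG")
    veog = epochs.tensor[:, veog_row, :]
    ptp = veog.max(axis=1) - veog.min(axis=1)
    assert (ptp > 50.0).sum() >= 1


# ------------------------------------------------------- additivity/identity

def test_additive_model_decomposition(montage):
    """Record minus the noise stream (same seeds) equals the deterministic
    template-plus-blink sum, sample-exact."""
    cfg = SimulationConfig(trials_per_category=2, seed=11)
    rec, sched = simulate_subject(cfg, 0, montage)
    _, rng_noise, _, _ = _subject_rngs(cfg, 0)
    noise = synthesize_noise(montage.n_all, rec.n_samples, cfg, rng_noise)

    zero_cfg = dataclasses.replace(cfg, noise_sd=0.0, alpha_amplitude=0.0)
    det, _ = simulate_subject(zero_cfg, 0, montage)
    assert np.allclose(rec.data - noise, det.data, atol=1e-4)


def test_noiseless_pipeline_recovers_templates_exactly(montage):
    """In the zero-noise limit, epoching + averaging returns the injected
    template sum."""
    from erpmark.average import average_by_category
    from erpmark.preprocess import baseline_correct, reject_artifacts

    cfg = SimulationConfig(trials_per_category=3, noise_sd=0.0,
                           alpha_amplitude=0.0, blink_rate_per_min=0.0,
                           subject_gain_sd=0.0, seed=5)
    rec, sched = simulate_subject(cfg, 0, montage)
    epochs = baseline_correct(reject_artifacts(extract_epochs(rec, sched)))
    evokeds = average_by_category(epochs)
    truth = noiseless_evokeds(config=cfg, montage=montage)
    for cat, ev in evokeds.items():
        assert np.allclose(ev.data, truth[cat].data, atol=1e-4), cat


def test_simulation_is_bit_deterministic(montage):
    cfg = SimulationConfig(trials_per_category=2, seed=9)
    rec_a, sched_a = simulate_subject(cfg, 3, montage)
    rec_b, sched_b = simulate_subject(cfg, 3, montage)
    assert sched_a.entries == sched_b.entries
    assert np.array_equal(rec_a.data, rec_b.data)
    rec_c, _ = simulate_subject(cfg, 4, montage)
    assert not np.array_equal(rec_a.data, rec_c.data)
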